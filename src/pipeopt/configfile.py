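"""YAML configuration files declaring the search space and optimiser settings.

Schema (all sections except ``parameters`` optional)::

    parameters:
      - {name: Size of adaptive window, kind: integer, min: 11, max: 99, interval: 2}
      - {name: Threshold correction factor I, kind: float, min: 0.6, max: 1.5, interval: 0.05}
    criteria:                      # automated evaluation (<= 4 entries)
      object: nucleus
      measurements:
        - {measurement: solidity, min: 0.9}
        - {measurement: area, min: 40, max: 2000}
    optimiser:
      target_qs: 8
      max_iterations: 30
      bootstrap: 2
      xi: 0.01
      candidate_count: 2048
      seed: 0
      gp:
        sigma_n: 0.1
        sigma_f: 1.0
        sigma_l: 1.0
        bounds: {sigma_n: [1.0e-6, 4.0], sigma_f: [1.0e-3, 100.0], sigma_l: [1.0e-3, 10.0]}
      weights: {automated: 0.5, manual: 0.5}
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import yaml

from .acquisition import AcquisitionSettings
from .evaluation import AutomatedCriteria, MeasurementCriterion
from .optimise import OptimiserSettings
from .space import ParameterSpec, SearchSpace

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Parsed configuration file."""

    space: SearchSpace
    settings: OptimiserSettings
    criteria: Optional[AutomatedCriteria]
    weights: dict  # evaluator-name -> weight (composite mode)


def load_config(path: str) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "parameters" not in raw:
        raise ValueError("configuration must contain a 'parameters' section")

    specs = []
    for entry in raw["parameters"]:
        try:
            specs.append(
                ParameterSpec(
                    name=str(entry["name"]),
                    kind=str(entry.get("kind", "float")),
                    minimum=float(entry["min"]),
                    maximum=float(entry["max"]),
                    interval=float(entry["interval"]),
                )
            )
        except KeyError as exc:
            raise ValueError(f"parameter entry {entry!r} is missing key {exc}") from exc
    space = SearchSpace(specs)

    criteria = None
    if raw.get("criteria"):
        c = raw["criteria"]
        measurements = [
            MeasurementCriterion(
                measurement=str(m["measurement"]),
                lower=float(m["min"]) if "min" in m else None,
                upper=float(m["max"]) if "max" in m else None,
            )
            for m in c.get("measurements", [])
        ]
        criteria = AutomatedCriteria(measurements, target_object=c.get("object", "nucleus"))

    opt = raw.get("optimiser", {}) or {}
    gp = opt.get("gp", {}) or {}
    bounds = None
    if "bounds" in gp:
        bounds = {k: tuple(v) for k, v in gp["bounds"].items()}
    settings = OptimiserSettings(
        target_qs=float(opt.get("target_qs", 8.0)),
        max_iterations=int(opt.get("max_iterations", 30)),
        bootstrap_count=int(opt.get("bootstrap", 2)),
        acquisition=AcquisitionSettings(
            xi=float(opt.get("xi", 0.3)),
            candidate_count=int(opt.get("candidate_count", 2048)),
        ),
        sigma_n=float(gp.get("sigma_n", 0.1)),
        sigma_f=float(gp.get("sigma_f", 1.0)),
        sigma_l=float(gp.get("sigma_l", 1.0)),
        gp_bounds=bounds,
        seed=int(opt.get("seed", 0)),
    )
    weights = dict(opt.get("weights", {"automated": 0.5, "manual": 0.5}))
    return RunConfig(space=space, settings=settings, criteria=criteria, weights=weights)
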
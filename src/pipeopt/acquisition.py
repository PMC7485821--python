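"""Expected-Improvement acquisition over a finite candidate set.

The next configuration to evaluate is chosen by scoring candidates with
Expected Improvement (maximisation convention: the optimiser maximises the
quality score).  The candidate set is a seeded scrambled-Sobol sample of the
unit hypercube plus the grid neighbours of every configuration evaluated so
far, which keeps the proposal step deterministic given a seed while still
allowing fine local moves on the interval grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .gp import GPSurrogate
from .space import Configuration, SearchSpace, encode, grid_values

__all__ = [
    "AcquisitionSettings",
    "expected_improvement",
    "candidate_points",
    "propose_next",
]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Settings of the acquisition step.

    xi : exploration offset (>= 0) on the quality-score scale.
    candidate_count : number of quasi-random candidates scored per iteration.
    """

    xi: float = 0.3
    candidate_count: int = 2048

    def __post_init__(self):
        if self.xi < 0:
            raise ValueError("xi must be >= 0")
        if self.candidate_count < 1:
            raise ValueError("candidate_count must be >= 1")


def expected_improvement(
    mean: "float | np.ndarray",
    variance: "float | np.ndarray",
    y_best: float,
    xi: float = 0.0,
) -> "float | np.ndarray":
    """Closed-form EI for maximisation: E[max(Y - y_best - xi, 0)].

    With ``s = sqrt(variance)`` and ``delta = mean - y_best - xi`` this is
    ``delta * Phi(delta/s) + s * phi(delta/s)``; at ``s = 0`` it degenerates
    to ``max(delta, 0)``.  Always non-negative.
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(variance < 0):
        raise ValueError("variance must be >= 0")
    s = np.sqrt(variance)
    delta = mean - y_best - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, delta / np.where(s > 0, s, 1.0), 0.0)
        z = np.clip(z, -38.0, 38.0)  # beyond this Phi/phi underflow anyway
        ei = np.where(
            s > 0,
            delta * stats.norm.cdf(z) + s * stats.norm.pdf(z),
            np.maximum(delta, 0.0),
        )
    ei = np.maximum(ei, 0.0)
    return float(ei) if ei.ndim == 0 else ei


def _grid_neighbours(
    configs: Iterable[Configuration], space: SearchSpace
) -> List[np.ndarray]:
    """Encoded one-step grid neighbours (and the points themselves)."""
    grids = {s.name: grid_values(s) for s in space.specs}
    points = []
    for config in configs:
        points.append(encode(config, space))
        for spec in space.specs:
            g = grids[spec.name]
            idx = int(np.argmin(np.abs(g - config[spec.name])))
            for j in (idx - 1, idx + 1):
                if 0 <= j < len(g):
                    nb = dict(config)
                    nb[spec.name] = float(g[j])
                    points.append(encode(nb, space))
    return points


def candidate_points(
    space: SearchSpace,
    evaluated: Iterable[Configuration],
    settings: AcquisitionSettings,
    seed: int,
) -> np.ndarray:
    """Candidate set: scrambled Sobol points plus grid neighbours of
    previously evaluated configurations."""
    d = space.dimension
    sobol = qmc.Sobol(d, scramble=True, seed=seed)
    pts = sobol.random(settings.candidate_count)
    extra = _grid_neighbours(evaluated, space)
    if extra:
        pts = np.vstack([pts, np.clip(np.array(extra), 0.0, 1.0)])
    return pts


def propose_next(
    gp: GPSurrogate,
    candidates: np.ndarray,
    y_best: float,
    settings: Optional[AcquisitionSettings] = None,
) -> np.ndarray:
    """Return the candidate maximising EI; ties break on the lowest index."""
    settings = settings or AcquisitionSettings()
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if candidates.shape[0] == 0:
        raise ValueError("candidate set must be non-empty")
    mean, var = gp.predict(candidates, return_var=True)
    ei = expected_improvement(mean, var, y_best, settings.xi)
    return candidates[int(np.argmax(ei))]
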
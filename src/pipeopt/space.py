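"""Search-space declaration, validation, discretisation and encoding.

A pipeline *configuration* is one assignment of values to every tunable
image-processing setting.  Each setting is declared with a name, a kind
(integer or float), a minimum, a maximum and an interval (grid step).
Because settings have wildly different scales (an adaptive window of a few
hundred pixels versus a threshold correction factor near 1), configurations
are mapped to the unit hypercube ``[0, 1]^d`` before any kernel distance is
computed; the optimiser proposes points on the hypercube and snaps them back
onto the declared interval grid before the pipeline is executed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np

__all__ = [
    "ParameterSpec",
    "SearchSpace",
    "Configuration",
    "validate_space",
    "grid_values",
    "encode",
    "decode",
    "sample_random",
]

#: A configuration is simply a mapping from setting name to value.
Configuration = Dict[str, float]

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class ParameterSpec:
    """Declaration of one tunable pipeline setting.

    Parameters
    ----------
    name : str
        Unique identifier of the setting (e.g. ``"Size of adaptive window"``).
    kind : {"integer", "float"}
        Value type.  Integer specs must have whole-valued bounds and interval.
    minimum, maximum : float
        Inclusive range; ``minimum < maximum``.
    interval : float
        Positive grid step; must not exceed ``maximum - minimum``.
    """

    name: str
    kind: str
    minimum: float
    maximum: float
    interval: float

    def validate(self) -> None:
        if self.kind not in ("integer", "float"):
            raise ValueError(
                f"spec {self.name!r}: kind must be 'integer' or 'float', got {self.kind!r}"
            )
        if not (np.isfinite(self.minimum) and np.isfinite(self.maximum)):
            raise ValueError(f"spec {self.name!r}: bounds must be finite")
        if not self.minimum < self.maximum:
            raise ValueError(
                f"spec {self.name!r}: minimum ({self.minimum}) must be < maximum ({self.maximum})"
            )
        if not self.interval > 0:
            raise ValueError(f"spec {self.name!r}: interval must be positive")
        if self.interval > (self.maximum - self.minimum) + _GRID_TOL:
            raise ValueError(
                f"spec {self.name!r}: interval ({self.interval}) exceeds range "
                f"({self.maximum - self.minimum})"
            )
        if self.kind == "integer":
            for label, v in (
                ("minimum", self.minimum),
                ("maximum", self.maximum),
                ("interval", self.interval),
            ):
                if abs(v - round(v)) > _GRID_TOL:
                    raise ValueError(
                        f"spec {self.name!r}: integer kind requires whole-valued {label}, got {v}"
                    )


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of :class:`ParameterSpec`; dimensionality ``d = len(specs)``."""

    specs: tuple = field(default_factory=tuple)

    def __init__(self, specs: Iterable[ParameterSpec]):
        object.__setattr__(self, "specs", tuple(specs))
        validate_space(self)

    @property
    def dimension(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> List[str]:
        return [s.name for s in self.specs]

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def grid(self) -> List[np.ndarray]:
        """Per-spec grid values, in declaration order."""
        return [grid_values(s) for s in self.specs]


def validate_space(space: "SearchSpace | Sequence[ParameterSpec]") -> "SearchSpace | Sequence[ParameterSpec]":
    """Validate every spec invariant; returns the space unchanged on success.

    Raises ``ValueError`` naming the offending spec on the first violation.
    """
    specs = tuple(space.specs) if isinstance(space, SearchSpace) else tuple(space)
    if len(specs) == 0:
        raise ValueError("at least one parameter required")
    seen = set()
    for spec in specs:
        spec.validate()
        if spec.name in seen:
            raise ValueError(f"duplicate parameter name {spec.name!r}")
        seen.add(spec.name)
    return space


def grid_values(spec: ParameterSpec) -> np.ndarray:
    """All admissible values of one setting: minimum, minimum+interval, ...

    The maximum is always a member: it is appended if the stride does not land
    on it within a tolerance of 1e-9.
    """
    spec.validate()
    n_steps = int(np.floor((spec.maximum - spec.minimum) / spec.interval + _GRID_TOL))
    pts = spec.minimum + spec.interval * np.arange(n_steps + 1, dtype=float)
    if spec.maximum - pts[-1] > _GRID_TOL:
        pts = np.append(pts, spec.maximum)
    if spec.kind == "integer":
        pts = np.round(pts)
    return pts


def _check_config(config: Configuration, space: SearchSpace) -> None:
    names = set(space.names)
    extra = set(config) - names
    missing = names - set(config)
    if missing:
        raise ValueError(f"configuration missing setting(s): {sorted(missing)}")
    if extra:
        raise ValueError(f"configuration has unknown setting(s): {sorted(extra)}")


def encode(config: Configuration, space: SearchSpace) -> np.ndarray:
    """Map a configuration onto the unit hypercube.

    Component ``i`` is ``(value_i - min_i) / (max_i - min_i)``, ordered as
    ``space.specs``.
    """
    _check_config(config, space)
    out = np.empty(space.dimension)
    for i, spec in enumerate(space.specs):
        out[i] = (config[spec.name] - spec.minimum) / (spec.maximum - spec.minimum)
    return out


def decode(point: np.ndarray, space: SearchSpace) -> Configuration:
    """Map a hypercube point back to a grid configuration.

    De-normalises each coordinate and snaps to the nearest grid value;
    exact midpoints between two grid values break toward the lower one.
    """
    point = np.asarray(point, dtype=float)
    if point.shape != (space.dimension,):
        raise ValueError(
            f"point has shape {point.shape}, expected ({space.dimension},)"
        )
    if np.any(point < -_GRID_TOL) or np.any(point > 1 + _GRID_TOL):
        raise ValueError("encoded coordinates must lie in [0, 1]")
    config: Configuration = {}
    for i, spec in enumerate(space.specs):
        value = spec.minimum + float(point[i]) * (spec.maximum - spec.minimum)
        grid = grid_values(spec)
        d = np.abs(grid - value)
        # tie toward the lower grid value: first index attaining the minimum
        idx = int(np.flatnonzero(d <= d.min() + 1e-12)[0])
        snapped = float(grid[idx])
        if spec.kind == "integer":
            snapped = float(int(round(snapped)))
        config[spec.name] = snapped
    return config


def decode_continuous(point: np.ndarray, space: SearchSpace) -> Configuration:
    """De-normalise without snapping (the raw continuous proposal)."""
    point = np.asarray(point, dtype=float)
    return {
        spec.name: spec.minimum + float(point[i]) * (spec.maximum - spec.minimum)
        for i, spec in enumerate(space.specs)
    }


def sample_random(
    space: SearchSpace, n: int, seed: "int | np.random.Generator"
) -> List[Configuration]:
    """Draw ``n`` configurations uniformly and independently from the full grid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grids = space.grid()
    out = []
    for _ in range(n):
        config = {
            spec.name: float(g[rng.integers(len(g))])
            for spec, g in zip(space.specs, grids)
        }
        out.append(config)
    return out
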
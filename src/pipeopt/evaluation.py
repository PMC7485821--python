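"""Quality-score evaluators and the quality gap.

Every evaluator maps one pipeline run onto the 1-10 quality-score (QS)
scale:

* *automated*: per-object measurements are judged against user-declared
  tolerance ranges (at most four criteria); the per-criterion pass fractions
  are averaged and mapped linearly onto [1, 10].
* *manual*: a rating callback (the user at an interactive prompt, or a
  simulated rater in tests) returns an integer 1-10 after being shown an
  outline overlay of the segmentation.
* *composite*: a weighted arithmetic mean of the other two.

The optimisation stops when the *quality gap* ``max(target - current, 0)``
reaches zero, i.e. the current QS meets or exceeds the user's target QS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MAX_CRITERIA",
    "QS_MIN",
    "QS_MAX",
    "MeasurementCriterion",
    "AutomatedCriteria",
    "automated_qs",
    "manual_qs",
    "composite_qs",
    "quality_gap",
    "make_overlay",
    "AutomatedEvaluator",
    "ManualEvaluator",
    "CompositeEvaluator",
]

QS_MIN = 1.0
QS_MAX = 10.0
#: At most four object measurements may be combined into the automated QS.
MAX_CRITERIA = 4
#: Number of additional queries allowed after an invalid manual rating.
_MANUAL_RETRIES = 3


def _check_qs(value: float, label: str = "quality score") -> float:
    value = float(value)
    if not QS_MIN <= value <= QS_MAX:
        raise ValueError(f"{label} must lie in [{QS_MIN}, {QS_MAX}], got {value}")
    return value


@dataclass(frozen=True)
class MeasurementCriterion:
    """Tolerance range for one object measurement; at least one bound."""

    measurement: str
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self):
        if self.lower is None and self.upper is None:
            raise ValueError(
                f"criterion on {self.measurement!r}: at least one bound required"
            )
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError(
                f"criterion on {self.measurement!r}: lower bound must be < upper bound"
            )

    def passes(self, values: np.ndarray) -> np.ndarray:
        ok = np.ones(len(values), dtype=bool)
        if self.lower is not None:
            ok &= values >= self.lower
        if self.upper is not None:
            ok &= values <= self.upper
        return ok


@dataclass(frozen=True)
class AutomatedCriteria:
    """1-4 measurement criteria judged on one object class."""

    criteria: tuple
    target_object: str = "nucleus"

    def __init__(self, criteria: Sequence[MeasurementCriterion], target_object: str = "nucleus"):
        criteria = tuple(criteria)
        if not 1 <= len(criteria) <= MAX_CRITERIA:
            raise ValueError(
                f"between 1 and {MAX_CRITERIA} criteria required, got {len(criteria)}"
            )
        object.__setattr__(self, "criteria", criteria)
        object.__setattr__(self, "target_object", target_object)


def automated_qs(measurements: pd.DataFrame, criteria: AutomatedCriteria) -> float:
    """Aggregate tolerance-range criteria into a QS on the 1-10 scale.

    Per criterion the pass fraction is (#objects within bounds)/(#objects);
    the QS is ``1 + 9 * mean(pass fractions)``.  A segmentation with zero
    objects scores 1 (worst) with a warning rather than erroring, so the
    optimiser can learn away from configurations that detect nothing.
    """
    for crit in criteria.criteria:
        if crit.measurement not in measurements.columns:
            raise ValueError(
                f"measurement table lacks column {crit.measurement!r} "
                f"(have {list(measurements.columns)})"
            )
    if len(measurements) == 0:
        warnings.warn("zero objects segmented; scoring worst QS 1", stacklevel=2)
        return QS_MIN
    fractions = [
        float(np.mean(crit.passes(measurements[crit.measurement].to_numpy())))
        for crit in criteria.criteria
    ]
    return QS_MIN + 9.0 * float(np.mean(fractions))


def manual_qs(rating_provider: Callable[[object], object], display_payload: object) -> float:
    """Obtain an integer 1-10 rating from a callback.

    The payload (an outline overlay of the current segmentation) is passed to
    the provider before each query.  Non-integer or out-of-scale answers are
    rejected and the provider re-queried up to three times before aborting.
    """
    attempts = 1 + _MANUAL_RETRIES
    last = None
    for _ in range(attempts):
        rating = rating_provider(display_payload)
        last = rating
        if isinstance(rating, bool) or not isinstance(rating, (int, np.integer)):
            continue
        if QS_MIN <= rating <= QS_MAX:
            return float(rating)
    raise ValueError(
        f"no valid integer rating in [1, 10] after {attempts} attempts (last: {last!r})"
    )


def composite_qs(scores: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted arithmetic mean of evaluator scores with normalised weights."""
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if scores.shape != weights.shape:
        raise ValueError(
            f"{scores.size} scores but {weights.size} weights"
        )
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    for s in scores:
        _check_qs(s)
    return float(np.dot(scores, weights) / total)


def quality_gap(target: float, current: float) -> float:
    """max(target - current, 0); zero exactly when the stopping condition holds."""
    return max(float(target) - float(current), 0.0)


def make_overlay(image: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """RGB uint8 overlay: object outlines (green) on the grayscale input."""
    from skimage.segmentation import find_boundaries

    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.stack([norm] * 3, axis=-1)
    edges = find_boundaries(labels, mode="outer")
    rgb[edges] = (0.0, 1.0, 0.0)
    return (rgb * 255).astype(np.uint8)


# ----------------------------------------------------------------------
# Evaluator objects: callables PipelineResult -> QS, bound to an image.


class AutomatedEvaluator:
    """Scores a pipeline run from its measurement table."""

    def __init__(self, criteria: AutomatedCriteria):
        self.criteria = criteria

    def __call__(self, result) -> float:
        table = result.measurements.get(self.criteria.target_object)
        if table is None:
            raise ValueError(
                f"pipeline result has no measurements for object "
                f"{self.criteria.target_object!r}"
            )
        return automated_qs(table, self.criteria)


class ManualEvaluator:
    """Scores a pipeline run by querying a rating callback with an overlay.

    ``rating_provider`` receives the RGB overlay array and returns an integer
    1-10.  ``object_class`` selects which mask is outlined ('nucleus' = the
    primary mask, 'cell' = the secondary mask).  ``save_payload_to`` writes
    each overlay to a PNG for interactive review.
    """

    def __init__(
        self,
        rating_provider: Callable[[np.ndarray], int],
        image: np.ndarray,
        object_class: str = "nucleus",
        save_payload_to: Optional[str] = None,
    ):
        self.rating_provider = rating_provider
        self.image = image
        self.object_class = object_class
        self.save_payload_to = save_payload_to
        self._count = 0

    def _mask_for(self, result) -> np.ndarray:
        if self.object_class == "cell":
            return result.secondary
        return result.primary

    def __call__(self, result) -> float:
        payload = make_overlay(self.image, self._mask_for(result))
        if self.save_payload_to:
            import imageio.v3 as iio
            import os

            os.makedirs(self.save_payload_to, exist_ok=True)
            iio.imwrite(
                f"{self.save_payload_to}/overlay_{self._count:03d}.png", payload
            )
        self._count += 1
        return manual_qs(self.rating_provider, payload)


class CompositeEvaluator:
    """Weighted combination of evaluators into one joint QS."""

    def __init__(self, evaluators: Sequence[Callable], weights: Sequence[float]):
        if len(evaluators) != len(weights):
            raise ValueError("one weight per evaluator required")
        self.evaluators = list(evaluators)
        self.weights = list(weights)

    def __call__(self, result) -> float:
        scores = [ev(result) for ev in self.evaluators]
        return composite_qs(scores, self.weights)
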
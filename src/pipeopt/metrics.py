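"""Segmentation-quality metrics: intersection over union and test-set scoring."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .segmentation import run_pipeline
from .space import Configuration

__all__ = ["iou", "BenchmarkResult", "evaluate_on_testset"]


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Pixel-wise intersection over union |A n B| / |A u B| of binary masks.

    Symmetric and bounded in [0, 1].  Two empty masks agree perfectly and
    score 1.0 (the 0/0 case), with a warning.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("both masks empty; defining IoU = 1.0", stacklevel=2)
        return 1.0
    return float(np.count_nonzero(a & b) / union)


@dataclass
class BenchmarkResult:
    """Per-image IoU scores of one configuration on a test set."""

    scores: List[float]
    mean: float
    sd: float


def evaluate_on_testset(
    config: Configuration,
    samples: Sequence,
    object_class: str = "nucleus",
) -> BenchmarkResult:
    """Run the pipeline at a fixed configuration on every test image and
    score the binarised predicted mask against the ground truth.

    ``object_class`` selects both the ground-truth mask and the predicted
    mask ('nucleus' = primary stage, 'cell' = secondary stage).
    """
    if len(samples) == 0:
        raise ValueError("test set must be non-empty")
    scores = []
    for sample in samples:
        truth = sample.ground_truth.get(object_class)
        if truth is None:
            raise ValueError(
                f"sample lacks ground truth for object class {object_class!r}"
            )
        result = run_pipeline(sample.image, config)
        predicted = result.secondary if object_class == "cell" else result.primary
        scores.append(iou(predicted > 0, truth))
    arr = np.asarray(scores)
    return BenchmarkResult(scores=scores, mean=float(arr.mean()), sd=float(arr.std(ddof=1)) if len(scores) > 1 else 0.0)
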
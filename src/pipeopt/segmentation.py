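"""Reference two-stage segmentation pipeline (nuclei, then cells).

This is the image-processing pipeline whose settings the optimiser tunes.
It mirrors the semantics of the CellProfiler primary/secondary object
identification steps without depending on CellProfiler:

1. *Primary* (nuclei): Gaussian smoothing, local-mean adaptive threshold over
   a square window scaled by a correction factor, hole filling, removal of
   components smaller than a typical artifact diameter, labelling.
2. *Secondary* (cells): global Otsu threshold scaled by a second correction
   factor defines the cell foreground; a watershed seeded from the primary
   labels grows each nucleus into its cell, so each cell inherits its
   nucleus' label and contains it pixelwise.

The four tunable settings carry the names used throughout the tool:
"Size of adaptive window", "Threshold correction factor I",
"Typical artifact diameter", "Threshold correction factor II".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation
from sklearn.base import BaseEstimator

__all__ = [
    "SETTING_NAMES",
    "PipelineResult",
    "SegmentationPipeline",
    "measure_objects",
    "run_pipeline",
    "load_image",
]

#: Mapping from the public setting names to estimator parameters.
SETTING_NAMES: Dict[str, str] = {
    "Size of adaptive window": "adaptive_window",
    "Threshold correction factor I": "threshold_correction_1",
    "Typical artifact diameter": "artifact_diameter",
    "Threshold correction factor II": "threshold_correction_2",
}

_MEASUREMENT_COLUMNS = ["label", "area", "perimeter", "solidity", "eccentricity"]


@dataclass
class PipelineResult:
    """Output of one pipeline execution: labelled masks plus measurements."""

    primary: np.ndarray
    secondary: np.ndarray
    measurements: Dict[str, pd.DataFrame] = field(default_factory=dict)


def _as_float_image(image: np.ndarray) -> np.ndarray:
    """Normalise an input image to float64 in [0, 1]."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return image.astype(float) / float(info.max)
    img = image.astype(float)
    if img.max() > 1.0 or img.min() < 0.0:
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return img


def measure_objects(mask: np.ndarray) -> pd.DataFrame:
    """Per-object shape measurements: area, perimeter, solidity, eccentricity."""
    mask = np.asarray(mask)
    if mask.max() == 0:
        return pd.DataFrame(columns=_MEASUREMENT_COLUMNS)
    props = measure.regionprops_table(
        mask, properties=("label", "area", "perimeter", "solidity", "eccentricity")
    )
    df = pd.DataFrame(props)
    df["area"] = df["area"].astype(float)
    return df[_MEASUREMENT_COLUMNS]


def _relabel_raster(binary: np.ndarray) -> np.ndarray:
    """8-connected labelling; label order follows the raster scan of first pixels."""
    return measure.label(binary, connectivity=2)


class SegmentationPipeline(BaseEstimator):
    """Two-stage nucleus/cell segmenter with the four tunable settings.

    Parameters
    ----------
    adaptive_window : int
        Side (pixels) of the square neighbourhood for the local-mean adaptive
        threshold; must be >= 3 and no larger than the image.
    threshold_correction_1 : float
        Multiplier on the local mean; > 1 demands pixels brighter than their
        surroundings, < 1 admits more foreground.
    artifact_diameter : float
        Components with equivalent diameter (diameter of the equal-area
        circle) below this are discarded as artifacts.
    threshold_correction_2 : float
        Multiplier on the global Otsu threshold defining the cell foreground.
    smoothing_sigma : float
        Gaussian pre-smoothing scale in pixels (fixed, not optimised by
        default).
    min_threshold : float
        Absolute floor on the adaptive threshold.  Without it, regions of
        near-zero background would pass any multiplicative threshold (the
        local mean there is ~0), producing halo artifacts around bright
        objects.
    """

    def __init__(
        self,
        adaptive_window: int = 51,
        threshold_correction_1: float = 1.1,
        artifact_diameter: float = 5.0,
        threshold_correction_2: float = 1.0,
        smoothing_sigma: float = 1.0,
        min_threshold: float = 0.05,
    ):
        self.adaptive_window = adaptive_window
        self.threshold_correction_1 = threshold_correction_1
        self.artifact_diameter = artifact_diameter
        self.threshold_correction_2 = threshold_correction_2
        self.smoothing_sigma = smoothing_sigma
        self.min_threshold = min_threshold

    # -- sklearn compatibility: the pipeline is stateless ---------------
    def fit(self, X=None, y=None) -> "SegmentationPipeline":
        return self

    def _validate(self, image: np.ndarray) -> int:
        window = int(round(self.adaptive_window))
        if window < 3:
            raise ValueError(f"adaptive_window must be >= 3, got {self.adaptive_window}")
        if self.threshold_correction_1 <= 0 or self.threshold_correction_2 <= 0:
            raise ValueError("threshold correction factors must be > 0")
        if self.artifact_diameter < 0:
            raise ValueError("artifact_diameter must be >= 0")
        if min(image.shape) < window:
            raise ValueError(
                f"image {image.shape} is smaller than the adaptive window ({window})"
            )
        return window

    def segment_primary(self, image: np.ndarray) -> np.ndarray:
        """Label nuclei via smoothed local-mean adaptive thresholding."""
        img = _as_float_image(image)
        window = self._validate(img)
        smoothed = filters.gaussian(img, sigma=self.smoothing_sigma, preserve_range=True)
        local_mean = ndi.uniform_filter(smoothed, size=window, mode="reflect")
        threshold = np.maximum(local_mean * self.threshold_correction_1, self.min_threshold)
        binary = smoothed > threshold
        binary = ndi.binary_fill_holes(binary)
        labels = _relabel_raster(binary)
        if labels.max() and self.artifact_diameter > 0:
            keep = np.zeros_like(binary)
            for region in measure.regionprops(labels):
                if region.equivalent_diameter_area >= self.artifact_diameter:
                    keep[labels == region.label] = True
            labels = _relabel_raster(keep)
        return labels.astype(np.int32)

    def segment_secondary(self, image: np.ndarray, primary: np.ndarray) -> np.ndarray:
        """Grow cells from nucleus seeds by watershed within the Otsu foreground.

        Each secondary label equals its seed's primary label, and every
        primary pixel is contained in its secondary object.
        """
        img = _as_float_image(image)
        primary = np.asarray(primary)
        if primary.shape != img.shape:
            raise ValueError(
                f"primary mask shape {primary.shape} != image shape {img.shape}"
            )
        if primary.max() == 0:
            return np.zeros_like(primary, dtype=np.int32)
        smoothed = filters.gaussian(img, sigma=self.smoothing_sigma, preserve_range=True)
        if np.ptp(smoothed) > 0:
            thresh = filters.threshold_otsu(smoothed) * self.threshold_correction_2
            foreground = smoothed > thresh
        else:
            foreground = np.zeros_like(smoothed, dtype=bool)
        foreground |= primary > 0  # seeds always belong to their cell
        labels = segmentation.watershed(-smoothed, markers=primary, mask=foreground)
        return labels.astype(np.int32)

    def segment(self, image: np.ndarray) -> PipelineResult:
        """Run both stages and measure both object classes."""
        primary = self.segment_primary(image)
        secondary = self.segment_secondary(image, primary)
        return PipelineResult(
            primary=primary,
            secondary=secondary,
            measurements={
                "nucleus": measure_objects(primary),
                "cell": measure_objects(secondary),
            },
        )

    # alias so the estimator composes with sklearn-style call sites
    def transform(self, image: np.ndarray) -> PipelineResult:
        return self.segment(image)


def run_pipeline(image: np.ndarray, config: Mapping[str, float], **fixed) -> PipelineResult:
    """Execute the pipeline at a named configuration (the Table-style names).

    ``config`` must supply all four tunable settings; ``fixed`` may override
    non-optimised parameters such as ``smoothing_sigma``.
    """
    unknown = set(config) - set(SETTING_NAMES)
    if unknown:
        raise ValueError(
            f"unknown setting(s) {sorted(unknown)}; expected {sorted(SETTING_NAMES)}"
        )
    missing = set(SETTING_NAMES) - set(config)
    if missing:
        raise ValueError(
            f"missing setting(s) {sorted(missing)}; expected {sorted(SETTING_NAMES)}"
        )
    params = {attr: config[name] for name, attr in SETTING_NAMES.items()}
    params["adaptive_window"] = int(round(params["adaptive_window"]))
    params.update(fixed)
    return SegmentationPipeline(**params).segment(image)


def load_image(path: str) -> np.ndarray:
    """Read a single-channel TIFF/PNG image and normalise to float [0, 1]."""
    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.ndim == 3:  # collapse trivial channel axes
        if raw.shape[-1] in (3, 4):
            raw = raw[..., 0]
        else:
            raw = raw[0]
    return _as_float_image(raw)
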
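"""Per-micrograph membrane area fraction and between-condition yield comparison.

The membrane area of a negative-stain micrograph is the fraction of pixels
occupied by membrane features after background flattening and thresholding.
Each micrograph is one sampling unit; condition comparisons use the
per-micrograph fractions (Mann-Whitney for significance) and report the
fold difference of condition means, optionally after subtracting the mean
fraction of a mock-transfection background condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology

from .detect import _flatten_background, _remove_small
from .io import Micrograph
from .stats import TestResult, mann_whitney_u


@dataclass
class AreaFractionResult:
    source_id: str
    membrane_pixels: int
    total_pixels: int
    fraction: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.total_pixels <= 0:
            raise ValueError("total_pixels must be positive")
        expected = self.membrane_pixels / self.total_pixels
        if abs(self.fraction - expected) > 1e-12:
            raise ValueError("fraction must equal membrane_pixels / total_pixels")
        if not (0 <= self.fraction <= 1):
            raise ValueError("fraction must lie in [0, 1]")


@dataclass
class MembraneParams:
    threshold_method: str = "otsu"  # "otsu" | "mad"
    mad_k: float = 5.0
    smooth_sigma_px: float = 2.0
    min_feature_px: int = 20
    flatten_block_px: int = 8
    flatten_kernel_px: int = 31


def segment_membrane(m: Micrograph, params: MembraneParams | None = None) -> np.ndarray:
    """Binary mask (True = membrane) of stain-excluding features.

    Background-flattened (decimated rolling median) image, smoothed, then
    thresholded; features are dark, so the flattened image is negated before
    thresholding. Components below ``min_feature_px`` are dropped. A constant
    image yields an empty mask. The mask is invariant to intensity gain and
    offset.
    """
    params = params or MembraneParams()
    pixels = m.pixels
    if np.ptp(pixels) == 0:
        return np.zeros(pixels.shape, dtype=bool)
    flat = _flatten_background(pixels, params.flatten_block_px, params.flatten_kernel_px)
    feature = ndimage.gaussian_filter(-flat, params.smooth_sigma_px)
    if params.threshold_method == "otsu":
        thresh = filters.threshold_otsu(feature)
    elif params.threshold_method == "mad":
        med = np.median(feature)
        mad = np.median(np.abs(feature - med)) * 1.4826
        thresh = med + params.mad_k * mad
    else:
        raise ValueError(f"unknown threshold method {params.threshold_method!r}")
    mask = feature > thresh
    if params.min_feature_px > 0:
        mask = _remove_small(mask, params.min_feature_px)
    return mask


def area_fraction(
    mask: np.ndarray, source_id: str = "", condition: str = ""
) -> AreaFractionResult:
    """Exact pixel-count fraction of a boolean membrane mask."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("zero-size mask")
    if mask.dtype != bool:
        raise ValueError("area_fraction expects a boolean mask")
    membrane = int(mask.sum())
    total = int(mask.size)
    return AreaFractionResult(
        source_id=source_id,
        membrane_pixels=membrane,
        total_pixels=total,
        fraction=membrane / total,
        condition=condition,
    )


def measure_area_fraction(
    m: Micrograph, params: MembraneParams | None = None, condition: str = ""
) -> AreaFractionResult:
    return area_fraction(segment_membrane(m, params), source_id=m.source_id, condition=condition)


@dataclass
class MembraneYieldComparison:
    fold: float | None  # background-subtracted fold of condition means
    fold_sd: float | None  # first-order propagation from the SEs of the means
    fold_raw: float  # fold without background subtraction
    fold_raw_sd: float
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    flagged: str = ""


def _fold_with_sd(
    mean_a: float, se_a: float, mean_b: float, se_b: float
) -> tuple[float, float]:
    fold = mean_a / mean_b
    rel = math.sqrt((se_a / mean_a) ** 2 + (se_b / mean_b) ** 2)
    return fold, abs(fold) * rel


def compare_membrane_yield(
    a: list[AreaFractionResult],
    b: list[AreaFractionResult],
    background: list[AreaFractionResult] | None = None,
) -> MembraneYieldComparison:
    """Fold difference in membrane yield between two conditions.

    fold = (mean_a - mean_bg) / (mean_b - mean_bg), with the uncertainty
    propagated to first order from the standard errors of the group means.
    Significance is an unpaired two-sided Mann-Whitney test on the
    per-micrograph fractions. The un-subtracted fold is always reported
    alongside. A denominator at or below background is flagged and the
    subtracted fold left undefined.
    """
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each condition needs at least 3 micrographs")
    fa = np.array([r.fraction for r in a])
    fb = np.array([r.fraction for r in b])
    se_a = fa.std(ddof=1) / math.sqrt(len(fa))
    se_b = fb.std(ddof=1) / math.sqrt(len(fb))
    fold_raw, fold_raw_sd = _fold_with_sd(fa.mean(), se_a, fb.mean(), se_b)

    bg_mean, bg_se = 0.0, 0.0
    if background:
        fbg = np.array([r.fraction for r in background])
        bg_mean = float(fbg.mean())
        bg_se = fbg.std(ddof=1) / math.sqrt(len(fbg)) if len(fbg) > 1 else 0.0

    flagged = ""
    if fb.mean() - bg_mean <= 0:
        fold, fold_sd = None, None
        flagged = "denominator at or below background"
    else:
        num_se = math.sqrt(se_a**2 + bg_se**2)
        den_se = math.sqrt(se_b**2 + bg_se**2)
        fold, fold_sd = _fold_with_sd(fa.mean() - bg_mean, num_se, fb.mean() - bg_mean, den_se)

    test = mann_whitney_u(fa, fb)
    return MembraneYieldComparison(
        fold=fold,
        fold_sd=fold_sd,
        fold_raw=fold_raw,
        fold_raw_sd=fold_raw_sd,
        statistic=test.statistic,
        p_value=test.p_value,
        n_a=len(fa),
        n_b=len(fb),
        flagged=flagged,
    )


def fractions_to_frame(results: list[AreaFractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_id": r.source_id,
                "condition": r.condition,
                "membrane_pixels": r.membrane_pixels,
                "total_pixels": r.total_pixels,
                "fraction": r.fraction,
            }
            for r in results
        ],
        columns=["source_id", "condition", "membrane_pixels", "total_pixels", "fraction"],
    )
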
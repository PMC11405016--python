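"""Shared fixtures: rasterized shapes and the (expensive) benchmark run."""

from __future__ import annotations

import math

import numpy as np
import pytest
from skimage import draw, measure

from evquant.detect import VesicleDetection


def mask_to_detection(
    mask: np.ndarray, pixel_size_nm: float = 1.0, complete: bool = True
) -> VesicleDetection:
    """Sub-pixel marching-squares contour of a boolean mask as a detection."""
    padded = np.pad(mask, 1).astype(np.float64)
    contours = measure.find_contours(padded, 0.5)
    contour_rc = max(contours, key=len)
    xy = np.empty_like(contour_rc)
    xy[:, 0] = contour_rc[:, 1] - 1
    xy[:, 1] = contour_rc[:, 0] - 1
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return VesicleDetection(
        contour=xy,
        complete=complete,
        source_id="fixture",
        area_px=float(mask.sum()),
        pixel_size_nm=pixel_size_nm,
    )


def disk_mask(radius_px: float, size: int | None = None) -> np.ndarray:
    size = size or int(2 * radius_px + 10)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((size / 2, size / 2), radius_px, shape=mask.shape)
    mask[rr, cc] = True
    return mask


def ellipse_mask(a_px: float, b_px: float, angle_deg: float = 0.0) -> np.ndarray:
    size = int(2 * max(a_px, b_px) + 10)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.ellipse(
        size / 2, size / 2, b_px, a_px, shape=mask.shape, rotation=math.radians(angle_deg)
    )
    mask[rr, cc] = True
    return mask


def capsule_mask(width_px: float, length_px: float, angle_deg: float = 0.0) -> np.ndarray:
    """Filled capsule (rectangle plus semicircular caps), tip-to-tip length."""
    size = int(length_px + 10)
    ys, xs = np.mgrid[0:size, 0:size].astype(np.float64)
    c = size / 2
    theta = math.radians(angle_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    half_spine = (length_px - width_px) / 2
    px, py = xs - c, ys - c
    t = np.clip(px * ux + py * uy, -half_spine, half_spine)
    dist = np.hypot(px - t * ux, py - t * uy)
    return dist <= width_px / 2


def regular_polygon(n: int, radius: float = 1.0) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def random_convex_polygon(rng: np.random.Generator, n_max: int = 12) -> np.ndarray:
    """Convex hull of random points; at least a triangle, unit scale."""
    from scipy.spatial import ConvexHull

    while True:
        pts = rng.uniform(-1, 1, size=(rng.integers(4, n_max + 1), 2))
        try:
            hull = ConvexHull(pts)
        except Exception:
            continue
        return pts[hull.vertices]


@pytest.fixture(scope="session")
def benchmark_recovery_result():
    """Standard benchmark scene rendered, detected, and measured once."""
    from evquant.validation import benchmark_recovery

    return benchmark_recovery(seed=11)
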
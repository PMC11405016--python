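"""Per-vesicle shape descriptors and condition-level summaries.

Definitions
-----------
diameter
    Equivalent-circle diameter ``2 * sqrt(area / pi)`` from the exact
    polygon (shoelace) area. Stable against the rough edges and internal
    depressions of negatively stained vesicles.
major/minor axis
    Axes of the ellipse with the same normalized second central moments as
    the filled contour polygon (moments computed exactly by Green's
    theorem, no rasterization).
Feret (caliper) diameters
    Maximum and minimum width between parallel supporting lines, computed
    on the convex hull. The minimum caliper width of a tubule is its
    physical width.
roundness
    ``4 * area / (pi * major_axis**2)``; equals minor/major for ellipses,
    1 for circles, and decreases with elongation. A vesicle is classified
    tubular when its roundness is strictly below the threshold
    (default 0.6). The alternative "circularity" ``4*pi*area/perimeter**2``
    is selectable.

Roundness/tubularity is only evaluated for vesicles completely visible in
the micrograph; diameters are reported for all vesicles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial import ConvexHull

from .detect import VesicleDetection

TUBULAR_ROUNDNESS_THRESHOLD = 0.6


@dataclass
class VesicleMetrics:
    vesicle_id: str
    source_id: str
    complete: bool
    diameter_nm: float
    major_axis_nm: float
    minor_axis_nm: float
    feret_max_nm: float
    feret_min_nm: float
    roundness: float
    tubular: bool | None  # None when the vesicle is not completely visible
    condition: str = ""

    def __post_init__(self) -> None:
        if not (self.feret_min_nm <= self.feret_max_nm + 1e-9):
            raise ValueError("feret_min must not exceed feret_max")
        if not (0 < self.roundness <= 1 + 1e-9):
            raise ValueError("roundness must lie in (0, 1]")


@dataclass
class ConditionSummary:
    condition: str
    n: int
    n_complete: int
    mean_diameter_nm: float
    sd_diameter_nm: float | None  # None when n == 1 (sample SD undefined)
    tubular_fraction: float | None  # over complete vesicles; None if none complete
    tubular_count: int
    mode_positions_nm: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# polygon primitives


def polygon_area(contour: np.ndarray) -> float:
    """Shoelace area of a closed (x, y) polygon (absolute value, px^2)."""
    x, y = contour[:, 0], contour[:, 1]
    return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))) / 2.0


def polygon_perimeter(contour: np.ndarray) -> float:
    diff = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(diff[:, 0], diff[:, 1]).sum())


def _polygon_moments(contour: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Signed raw moments (m00, m10, m01, m20, m11, m02) of the filled polygon."""
    x = contour[:, 0]
    y = contour[:, 1]
    x1 = np.roll(x, -1)
    y1 = np.roll(y, -1)
    cross = x * y1 - x1 * y
    m00 = cross.sum() / 2.0
    m10 = (cross * (x + x1)).sum() / 6.0
    m01 = (cross * (y + y1)).sum() / 6.0
    m20 = (cross * (x**2 + x * x1 + x1**2)).sum() / 12.0
    m02 = (cross * (y**2 + y * y1 + y1**2)).sum() / 12.0
    m11 = (cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)).sum() / 24.0
    return m00, m10, m01, m20, m11, m02


def equivalent_diameter(d: VesicleDetection, pixel_size_nm: float | None = None) -> float:
    """Equivalent-circle diameter in nm from the exact polygon area."""
    px = d.pixel_size_nm if pixel_size_nm is None else pixel_size_nm
    area = polygon_area(d.contour)
    if area <= 0:
        raise ValueError("degenerate polygon with zero area")
    return 2.0 * math.sqrt(area / math.pi) * px


def fit_ellipse(d: VesicleDetection) -> tuple[float, float, float]:
    """Moments-equivalent ellipse of the filled contour polygon.

    Returns (major_axis, minor_axis, orientation) with full axis lengths in
    pixels and the major-axis orientation in radians (x toward +y).
    """
    contour = d.contour
    if len(contour) < 5:
        raise ValueError("fit_ellipse needs at least 5 contour vertices")
    m00, m10, m01, m20, m11, m02 = _polygon_moments(contour)
    if abs(m00) < 1e-12:
        raise ValueError("collinear or degenerate contour")
    xc, yc = m10 / m00, m01 / m00
    u20 = m20 / m00 - xc**2
    u02 = m02 / m00 - yc**2
    u11 = m11 / m00 - xc * yc
    common = math.sqrt(max((u20 - u02) ** 2 / 4.0 + u11**2, 0.0))
    lam1 = (u20 + u02) / 2.0 + common
    lam2 = (u20 + u02) / 2.0 - common
    if lam1 <= 0 or lam2 < 0:
        raise ValueError("degenerate second moments (collinear contour?)")
    major = 4.0 * math.sqrt(lam1)
    minor = 4.0 * math.sqrt(max(lam2, 0.0))
    orientation = 0.5 * math.atan2(2.0 * u11, u20 - u02)
    return major, minor, orientation


def feret_diameters(
    d: VesicleDetection, pixel_size_nm: float | None = None
) -> tuple[float, float]:
    """(feret_min, feret_max) caliper diameters in nm via the convex hull.

    The maximum is the largest vertex-pair distance (attained at an
    antipodal pair); the minimum width is attained perpendicular to a hull
    edge, so it is the smallest over edges of the farthest vertex distance
    from the edge's supporting line. Both are exact for the polygon.
    """
    px = d.pixel_size_nm if pixel_size_nm is None else pixel_size_nm
    pts = d.contour
    if len(pts) < 3:
        raise ValueError("need at least 3 vertices")
    if np.ptp(pts, axis=0).max() == 0:
        raise ValueError("degenerate contour: all points identical")
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except Exception as exc:  # collinear input
        raise ValueError(f"degenerate contour for Feret computation: {exc}") from exc
    diffs = hp[None, :, :] - hp[:, None, :]
    feret_max = float(np.sqrt((diffs**2).sum(-1)).max())
    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    valid = lengths > 1e-12
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1)[valid] / lengths[valid, None]
    # distance of every hull vertex from each edge's line; width = max |distance|
    rel = hp[None, :, :] - hp[valid][:, None, :]
    widths = np.abs((rel * normals[:, None, :]).sum(-1)).max(axis=1)
    feret_min = float(widths.min())
    return feret_min * px, feret_max * px


def roundness(d: VesicleDetection, formula: str = "area_major") -> float:
    """Scale-invariant shape descriptor in (0, 1]; 1 for a circle."""
    area = polygon_area(d.contour)
    if formula == "area_major":
        major, _, _ = fit_ellipse(d)
        value = 4.0 * area / (math.pi * major**2)
    elif formula == "circularity":
        perim = polygon_perimeter(d.contour)
        value = 4.0 * math.pi * area / perim**2
    else:
        raise ValueError(f"unknown roundness formula {formula!r}")
    return float(min(value, 1.0))


def classify_tubular(r: float, threshold: float = TUBULAR_ROUNDNESS_THRESHOLD) -> bool:
    """Tubular iff roundness is strictly below the threshold."""
    if not (0 < r <= 1):
        raise ValueError("roundness must lie in (0, 1]")
    return r < threshold


def measure_detection(
    d: VesicleDetection,
    pixel_size_nm: float | None = None,
    roundness_threshold: float = TUBULAR_ROUNDNESS_THRESHOLD,
    roundness_formula: str = "area_major",
    condition: str = "",
) -> VesicleMetrics:
    """All shape descriptors for one detection."""
    px = d.pixel_size_nm if pixel_size_nm is None else pixel_size_nm
    diameter = equivalent_diameter(d, px)
    major, minor, _ = fit_ellipse(d)
    fmin, fmax = feret_diameters(d, px)
    r = roundness(d, roundness_formula)
    return VesicleMetrics(
        vesicle_id=d.vesicle_id,
        source_id=d.source_id,
        complete=d.complete,
        diameter_nm=diameter,
        major_axis_nm=major * px,
        minor_axis_nm=minor * px,
        feret_max_nm=fmax,
        feret_min_nm=fmin,
        roundness=r,
        tubular=classify_tubular(r, roundness_threshold) if d.complete else None,
        condition=condition,
    )


def summarize_condition(
    metrics: list[VesicleMetrics], label: str, mode_bandwidth: float | None = None
) -> ConditionSummary:
    """Condition-level summary: diameters over all vesicles, tubular fraction
    over completely visible ones (the two denominators are reported)."""
    if not metrics:
        raise ValueError("cannot summarize an empty metrics list")
    diameters = np.array([m.diameter_nm for m in metrics])
    complete = [m for m in metrics if m.complete]
    tubular_count = sum(1 for m in complete if m.tubular)
    sd = float(diameters.std(ddof=1)) if len(diameters) > 1 else None
    modes: list[float] = []
    if len(diameters) >= 10:
        modes = size_distribution_modes(diameters, bandwidth=mode_bandwidth)
    return ConditionSummary(
        condition=label,
        n=len(metrics),
        n_complete=len(complete),
        mean_diameter_nm=float(diameters.mean()),
        sd_diameter_nm=sd,
        tubular_fraction=(tubular_count / len(complete)) if complete else None,
        tubular_count=tubular_count,
        mode_positions_nm=modes,
    )


def size_distribution_modes(
    diameters: np.ndarray | list[float], bandwidth: float | None = None
) -> list[float]:
    """Local maxima of a Gaussian kernel-density estimate, sorted ascending.

    Uses the Silverman bandwidth by default. Requires n >= 10; with fewer
    points inspect a histogram instead. A constant sample degenerates to a
    single mode at that value.
    """
    x = np.asarray(diameters, dtype=np.float64)
    if len(x) < 10:
        raise ValueError(
            "size_distribution_modes needs n >= 10; inspect a histogram for smaller samples"
        )
    if np.ptp(x) == 0:
        return [float(x[0])]
    kde = sstats.gaussian_kde(x, bw_method=bandwidth if bandwidth else "silverman")
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, 2048)
    y = kde(grid)
    rising = y[1:-1] > y[:-2]
    falling = y[1:-1] > y[2:]
    idx = np.where(rising & falling)[0] + 1
    return sorted(float(grid[i]) for i in idx)


def metrics_to_frame(metrics: list[VesicleMetrics]) -> pd.DataFrame:
    columns = [
        "vesicle_id", "source_id", "condition", "complete", "diameter_nm",
        "major_axis_nm", "minor_axis_nm", "feret_min_nm", "feret_max_nm",
        "roundness", "tubular",
    ]
    rows = [
        {
            "vesicle_id": m.vesicle_id,
            "source_id": m.source_id,
            "condition": m.condition,
            "complete": m.complete,
            "diameter_nm": m.diameter_nm,
            "major_axis_nm": m.major_axis_nm,
            "minor_axis_nm": m.minor_axis_nm,
            "feret_min_nm": m.feret_min_nm,
            "feret_max_nm": m.feret_max_nm,
            "roundness": m.roundness,
            "tubular": m.tubular,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=columns)
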
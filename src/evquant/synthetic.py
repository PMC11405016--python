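"""Ground-truth synthetic micrographs and bead montages.

Emulates the two EM modalities the quantification pipeline must handle:

* ``cryo``  — projected spherical vesicles appear as dark bilayer *rim*
  annuli over a bright background (vitrified sample, low contrast);
* ``nstem`` — vesicles appear as uniformly dark stain-excluding bodies
  with rough, irregular edges.

Tubular vesicles are rendered as capsules (a rectangle with semicircular
caps), optionally bent along a circular arc, which gives a two-parameter
analytic ground truth for width and length. Noise is additive Gaussian plus
signal-dependent (shot-like) noise over a slowly varying background.

Every stochastic choice is driven by explicit integer seeds carried in the
scene spec; identical specs render bit-identical images. Anti-aliasing is
done by 4x supersampling of each shape's bounding patch followed by box
down-sampling, which keeps rendered diameters accurate to a fraction of a
pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import Micrograph

SUPERSAMPLE = 4
CONTRAST_DEPTH = 1.0  # feature depth below background, arbitrary intensity units
BACKGROUND = 1.0


@dataclass
class ShapeTruth:
    """Ground truth for one rendered vesicle."""

    shape_id: str
    kind: str  # "sphere" | "tubule"
    center_nm: tuple[float, float]  # (x, y)
    diameter_nm: float | None = None  # spheres
    width_nm: float | None = None  # tubules
    length_nm: float | None = None  # tubules: total tip-to-tip length
    bend_radius_nm: float | None = None  # tubules: None = straight
    orientation_deg: float = 0.0
    true_roundness: float = 1.0
    touches_border: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "tubule"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind == "sphere":
            if self.diameter_nm is None or self.diameter_nm <= 0:
                raise ValueError("sphere requires diameter_nm > 0")
            self.true_roundness = 1.0
        else:
            if self.width_nm is None or self.length_nm is None:
                raise ValueError("tubule requires width_nm and length_nm")
            if self.width_nm <= 0 or self.length_nm < self.width_nm:
                raise ValueError("tubule requires length_nm >= width_nm > 0")


@dataclass
class NoiseSpec:
    gaussian_sd: float = 0.0
    shot_scale: float = 0.0
    background_gradient_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if min(self.gaussian_sd, self.shot_scale, self.background_gradient_amplitude) < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SceneSpec:
    """Full description of one synthetic micrograph."""

    image_size_px: tuple[int, int]  # (w, h)
    pixel_size_nm: float
    modality: str  # "cryo" | "nstem"
    shapes: list[ShapeTruth] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    rim_thickness_nm: float = 5.0
    roughness_nm: float | None = None  # NS-TEM edge roughness sd; default = 1 px
    border_margin_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.rim_thickness_nm <= 0:
            raise ValueError("rim_thickness_nm must be positive")
        if self.modality not in ("cryo", "nstem"):
            raise ValueError("modality must be 'cryo' or 'nstem'")
        if isinstance(self.noise, dict):
            self.noise = NoiseSpec(**self.noise)

    def roughness_px_nm(self, pixel_nm: float) -> float:
        """NS-TEM edge-roughness sd in nm (defaults to one pixel)."""
        return self.roughness_nm if self.roughness_nm is not None else pixel_nm


@dataclass
class RenderedScene:
    micrograph: Micrograph
    truths: list[ShapeTruth]
    body_coverage: np.ndarray | None = None  # union filled-shape coverage in [0, 1]

    @property
    def true_area_fraction(self) -> float:
        if self.body_coverage is None:
            raise ValueError("scene was rendered without coverage tracking")
        return float(self.body_coverage.mean())


# ---------------------------------------------------------------------------
# geometry helpers


def _subpixel_grid(x0: int, x1: int, y0: int, y1: int, pixel_nm: float):
    """Supersampled sample coordinates (nm) for the pixel box [x0,x1] x [y0,y1]."""
    ss = SUPERSAMPLE
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    xs = (np.arange(x0, x1 + 1)[:, None] + offs[None, :]).ravel() * pixel_nm
    ys = (np.arange(y0, y1 + 1)[:, None] + offs[None, :]).ravel() * pixel_nm
    return np.meshgrid(xs, ys)  # (H*ss, W*ss)


def _downsample(mask: np.ndarray) -> np.ndarray:
    ss = SUPERSAMPLE
    h, w = mask.shape[0] // ss, mask.shape[1] // ss
    return mask.reshape(h, ss, w, ss).mean(axis=(1, 3))


def _capsule_distance(
    gx: np.ndarray, gy: np.ndarray, truth: ShapeTruth
) -> np.ndarray:
    """Distance (nm) from sample points to the capsule spine (segment or arc)."""
    cx, cy = truth.center_nm
    theta = math.radians(truth.orientation_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    spine = truth.length_nm - truth.width_nm  # tip-to-tip length minus the two caps
    if truth.bend_radius_nm is None or not np.isfinite(truth.bend_radius_nm):
        # straight segment center +- (spine/2) u
        px, py = gx - cx, gy - cy
        t = np.clip(px * ux + py * uy, -spine / 2, spine / 2)
        return np.hypot(px - t * ux, py - t * uy)
    rb = float(truth.bend_radius_nm)
    half_arc = spine / (2 * rb)  # half the subtended angle
    # arc center offset along the normal; the spine midpoint stays at `center`
    nx, ny = -uy, ux
    ax, ay = cx + rb * nx, cy + rb * ny
    px, py = gx - ax, gy - ay
    r = np.hypot(px, py)
    # angle of each point about the arc center, relative to the mid-arc direction
    mid = math.atan2(cy - ay, cx - ax)
    ang = np.arctan2(py, px) - mid
    ang = (ang + np.pi) % (2 * np.pi) - np.pi
    dist = np.abs(r - rb)
    outside = np.abs(ang) > half_arc
    if np.any(outside):
        for sgn in (-1.0, 1.0):
            ex = ax + rb * math.cos(mid + sgn * half_arc)
            ey = ay + rb * math.sin(mid + sgn * half_arc)
            d_end = np.hypot(gx - ex, gy - ey)
            sel = outside & (sgn * ang > 0)
            dist[sel] = d_end[sel]
    return dist


def _shape_extent_nm(truth: ShapeTruth) -> float:
    """Radius (nm) of a circle around the center guaranteed to contain the shape."""
    if truth.kind == "sphere":
        return truth.diameter_nm / 2
    return truth.length_nm / 2 + truth.width_nm  # loose bound, covers bent capsules


def _rough_radius(
    theta: np.ndarray, radius_nm: float, roughness_nm: float, rng: np.random.Generator
) -> np.ndarray:
    """Seeded smooth radial perturbation emulating NS-TEM edge roughness."""
    harmonics = np.arange(5, 17)
    a = rng.normal(0.0, roughness_nm / math.sqrt(len(harmonics)), len(harmonics))
    b = rng.normal(0.0, roughness_nm / math.sqrt(len(harmonics)), len(harmonics))
    pert = np.zeros_like(theta)
    for k, ak, bk in zip(harmonics, a, b):
        pert += ak * np.cos(k * theta) + bk * np.sin(k * theta)
    return radius_nm + pert


def coverage_roundness(coverage: np.ndarray) -> float:
    """Roundness 4A / (pi * major_axis^2) of a coverage-weighted mask.

    Moments are taken over the pixel grid with the anti-aliased coverage as
    weights, so the value is the analytic ground truth the morphometry stage
    should recover.
    """
    w = np.asarray(coverage, dtype=np.float64)
    m00 = w.sum()
    if m00 <= 0:
        raise ValueError("empty coverage mask")
    ys, xs = np.mgrid[0 : w.shape[0], 0 : w.shape[1]]
    xc = (w * xs).sum() / m00
    yc = (w * ys).sum() / m00
    u20 = (w * (xs - xc) ** 2).sum() / m00
    u02 = (w * (ys - yc) ** 2).sum() / m00
    u11 = (w * (xs - xc) * (ys - yc)).sum() / m00
    common = math.sqrt(max((u20 - u02) ** 2 / 4 + u11**2, 0.0))
    lam1 = (u20 + u02) / 2 + common
    major = 4.0 * math.sqrt(max(lam1, 0.0))
    return float(4.0 * m00 / (math.pi * major**2))


# ---------------------------------------------------------------------------
# rendering


def render_scene(spec: SceneSpec, track_coverage: bool = False) -> RenderedScene:
    """Render a synthetic micrograph and return it with its shape truths.

    ``track_coverage=True`` additionally accumulates the union filled-shape
    coverage (the exact membrane-area-fraction ground truth).
    """
    w, h = spec.image_size_px
    px = spec.pixel_size_nm
    ss = SUPERSAMPLE
    img = np.full((h, w), BACKGROUND, dtype=np.float64)
    union = np.zeros((h * ss, w * ss), dtype=bool) if track_coverage else None

    truths: list[ShapeTruth] = []
    for i, shape in enumerate(spec.shapes):
        shape_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 1, i])
        cx, cy = shape.center_nm
        ext = _shape_extent_nm(shape) + spec.roughness_px_nm(px) * 4 + 2 * px
        x0 = max(int(math.floor((cx - ext) / px)), 0)
        x1 = min(int(math.ceil((cx + ext) / px)), w - 1)
        y0 = max(int(math.floor((cy - ext) / px)), 0)
        y1 = min(int(math.ceil((cy + ext) / px)), h - 1)
        if x1 < x0 or y1 < y0:
            truths.append(_with_border_flag(shape, spec, ext))
            continue
        gx, gy = _subpixel_grid(x0, x1, y0, y1, px)

        if shape.kind == "sphere":
            r = np.hypot(gx - cx, gy - cy)
            radius = shape.diameter_nm / 2
            if spec.modality == "nstem":
                theta = np.arctan2(gy - cy, gx - cx)
                r_edge = _rough_radius(theta, radius, spec.roughness_px_nm(px), shape_rng)
                body = r <= r_edge
                dark = body
            else:
                body = r <= radius
                dark = (r >= radius - spec.rim_thickness_nm) & body
            true_roundness = 1.0
        else:
            dist = _capsule_distance(gx, gy, shape)
            half_w = shape.width_nm / 2
            body = dist <= half_w
            if spec.modality == "nstem":
                dark = body
            else:
                dark = (dist >= half_w - spec.rim_thickness_nm) & body
            true_roundness = coverage_roundness(_downsample(body))

        img[y0 : y1 + 1, x0 : x1 + 1] -= CONTRAST_DEPTH * _downsample(dark)
        if union is not None:
            union[y0 * ss : (y1 + 1) * ss, x0 * ss : (x1 + 1) * ss] |= body

        truth = _with_border_flag(shape, spec, _shape_extent_nm(shape))
        truth.true_roundness = true_roundness
        truths.append(truth)

    # slowly varying background: tilted plane plus one broad sinusoid
    amp = spec.noise.background_gradient_amplitude
    if amp > 0:
        grad_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0])
        ys, xs = np.mgrid[0:h, 0:w]
        ang = grad_rng.uniform(0, 2 * np.pi)
        phase = grad_rng.uniform(0, 2 * np.pi)
        u = (xs * math.cos(ang) + ys * math.sin(ang)) / max(w, h)
        img += amp * (0.5 * u + 0.5 * np.sin(2 * np.pi * 0.7 * u + phase))

    noise_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 2])
    if spec.noise.shot_scale > 0:
        img = img + noise_rng.normal(size=img.shape) * np.sqrt(np.clip(img, 0, None)) * spec.noise.shot_scale
    if spec.noise.gaussian_sd > 0:
        img = img + noise_rng.normal(0.0, spec.noise.gaussian_sd, img.shape)

    micrograph = Micrograph(
        pixels=img, pixel_size_nm=px, modality=spec.modality, source_id=f"synthetic-{spec.seed}"
    )
    coverage = _downsample(union.astype(np.float64)) if union is not None else None
    return RenderedScene(micrograph=micrograph, truths=truths, body_coverage=coverage)


def render_micrograph(spec: SceneSpec) -> tuple[Micrograph, list[ShapeTruth]]:
    scene = render_scene(spec)
    return scene.micrograph, scene.truths


def _with_border_flag(shape: ShapeTruth, spec: SceneSpec, extent_nm: float) -> ShapeTruth:
    w, h = spec.image_size_px
    px = spec.pixel_size_nm
    cx, cy = shape.center_nm
    margin = spec.border_margin_px * px
    touches = (
        cx - extent_nm < margin
        or cy - extent_nm < margin
        or cx + extent_nm > (w - 1) * px - margin
        or cy + extent_nm > (h - 1) * px - margin
    )
    out = ShapeTruth(**{**asdict(shape), "touches_border": touches})
    return out


# ---------------------------------------------------------------------------
# truth tables and spec serialization


def truths_to_frame(truths: list[ShapeTruth], source_id: str = "") -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append(
            {
                "shape_id": t.shape_id,
                "source_id": source_id,
                "kind": t.kind,
                "center_x_nm": t.center_nm[0],
                "center_y_nm": t.center_nm[1],
                "diameter_nm": t.diameter_nm,
                "width_nm": t.width_nm,
                "length_nm": t.length_nm,
                "bend_radius_nm": t.bend_radius_nm,
                "orientation_deg": t.orientation_deg,
                "true_roundness": t.true_roundness,
                "touches_border": t.touches_border,
            }
        )
    columns = [
        "shape_id", "source_id", "kind", "center_x_nm", "center_y_nm", "diameter_nm",
        "width_nm", "length_nm", "bend_radius_nm", "orientation_deg", "true_roundness",
        "touches_border",
    ]
    return pd.DataFrame(rows, columns=columns)


def spec_to_yaml(spec: SceneSpec, path: str | Path) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)
    return Path(path)


def spec_from_yaml(path: str | Path) -> SceneSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["shapes"] = [
        ShapeTruth(**{**s, "center_nm": tuple(s["center_nm"])}) for s in raw.get("shapes", [])
    ]
    raw["image_size_px"] = tuple(raw["image_size_px"])
    raw["noise"] = NoiseSpec(**raw.get("noise", {}))
    return SceneSpec(**raw)


# ---------------------------------------------------------------------------
# standard scenes


def standard_benchmark(seed: int = 11) -> SceneSpec:
    """The standard mixed sphere/tubule recovery benchmark.

    One 3072 x 3072 px cryo-style micrograph at 2 nm/px: 200 spheres with
    diameters uniform in 40-250 nm and 20 capsules of width 42 nm with
    tip-to-tip lengths uniform in 120-280 nm (every fourth one bent along an
    arc of radius 150-400 nm), placed on a jittered 15 x 15 grid so that no
    two shapes touch and none touches the border. Noise is Gaussian with
    sd 0.2 (signal-to-noise 5 against the unit feature depth), shot scale
    0.02, and a 0.1-amplitude slowly varying background.
    """
    rng = np.random.default_rng(seed)
    size = 3072
    px = 2.0
    cells = 15
    cell_px = size / cells
    order = rng.permutation(cells * cells)
    shapes: list[ShapeTruth] = []
    n_spheres, n_tubules = 200, 20
    kinds = ["sphere"] * n_spheres + ["tubule"] * n_tubules
    for j, kind in enumerate(kinds):
        cell = order[j]
        row, col = divmod(int(cell), cells)
        cx = (col + 0.5) * cell_px + rng.uniform(-20, 20)
        cy = (row + 0.5) * cell_px + rng.uniform(-20, 20)
        center = (cx * px, cy * px)
        if kind == "sphere":
            shapes.append(
                ShapeTruth(
                    shape_id=f"s{j:03d}",
                    kind="sphere",
                    center_nm=center,
                    diameter_nm=float(rng.uniform(40, 250)),
                )
            )
        else:
            bent = (j - n_spheres) % 4 == 3
            shapes.append(
                ShapeTruth(
                    shape_id=f"t{j:03d}",
                    kind="tubule",
                    center_nm=center,
                    width_nm=42.0,
                    length_nm=float(rng.uniform(120, 280)),
                    bend_radius_nm=float(rng.uniform(150, 400)) if bent else None,
                    orientation_deg=float(rng.uniform(0, 180)),
                )
            )
    return SceneSpec(
        image_size_px=(size, size),
        pixel_size_nm=px,
        modality="cryo",
        shapes=shapes,
        noise=NoiseSpec(gaussian_sd=0.2, shot_scale=0.02, background_gradient_amplitude=0.1),
        rim_thickness_nm=5.0,
        seed=int(seed),
    )


def membrane_scene(
    target_fraction: float,
    seed: int,
    image_size_px: int = 1024,
    pixel_size_nm: float = 4.0,
    gaussian_sd: float = 0.2,
) -> RenderedScene:
    """An NS-TEM-style montage whose filled-shape area fraction is known exactly.

    Spheres (diameters uniform in 60-200 nm) are dropped at uniform random
    positions, overlaps allowed, until the union coverage reaches the target
    fraction; the realized fraction (returned via ``true_area_fraction``) is
    computed from the rendered anti-aliased union mask.
    """
    if not 0 <= target_fraction < 0.9:
        raise ValueError("target_fraction must be in [0, 0.9)")
    rng = np.random.default_rng(seed)
    size_nm = image_size_px * pixel_size_nm
    shapes: list[ShapeTruth] = []
    # occupancy grid at pixel resolution tracks the realized union coverage so
    # the scene lands on the target fraction to within a fraction of one sphere
    occupied = np.zeros((image_size_px, image_size_px), dtype=bool)
    total_px = occupied.size
    margin = 110.0  # keep shapes fully inside (max radius 100 nm + border)
    i = 0
    while occupied.mean() < target_fraction and i < 10000:
        d = float(rng.uniform(60, 200))
        cx = float(rng.uniform(margin, size_nm - margin))
        cy = float(rng.uniform(margin, size_nm - margin))
        r_px = d / 2 / pixel_size_nm
        cx_px, cy_px = cx / pixel_size_nm, cy / pixel_size_nm
        x0, x1 = int(cx_px - r_px) - 1, int(cx_px + r_px) + 2
        y0, y1 = int(cy_px - r_px) - 1, int(cy_px + r_px) + 2
        ys, xs = np.mgrid[y0:y1, x0:x1]
        disk = (xs - cx_px) ** 2 + (ys - cy_px) ** 2 <= r_px**2
        before = int(occupied.sum())
        candidate = occupied[y0:y1, x0:x1] | disk
        gain = int(candidate.sum()) - int(occupied[y0:y1, x0:x1].sum())
        # keep the final sphere only if it brings the coverage closer to target
        after_frac = (before + gain) / total_px
        if after_frac >= target_fraction and (
            after_frac - target_fraction > target_fraction - before / total_px
        ):
            break
        occupied[y0:y1, x0:x1] = candidate
        shapes.append(
            ShapeTruth(shape_id=f"m{i:04d}", kind="sphere", center_nm=(cx, cy), diameter_nm=d)
        )
        i += 1
    spec = SceneSpec(
        image_size_px=(image_size_px, image_size_px),
        pixel_size_nm=pixel_size_nm,
        modality="nstem",
        shapes=shapes,
        noise=NoiseSpec(gaussian_sd=gaussian_sd, background_gradient_amplitude=0.05),
        seed=int(seed),
    )
    return render_scene(spec, track_coverage=True)


# ---------------------------------------------------------------------------
# bead montages


@dataclass
class BeadSceneSpec:
    """Two-channel (reference, target) fluorescence bead montage description."""

    n_beads: int
    image_size_px: tuple[int, int] = (768, 768)
    bead_diameter_px: tuple[float, float] = (24.0, 40.0)
    reference_intensities: list[float] | float = 1000.0
    target_intensities: list[float] | float = 2000.0
    n_artifacts: int = 0
    artifact_intensity: float = 3000.0
    background_level: float = 100.0
    noise_sd: float = 5.0
    saturation_level: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 0 or self.n_artifacts < 0:
            raise ValueError("counts must be >= 0")
        for name in ("reference_intensities", "target_intensities"):
            val = getattr(self, name)
            if np.isscalar(val):
                setattr(self, name, [float(val)] * self.n_beads)
            elif len(val) != self.n_beads:
                raise ValueError(f"{name} must be scalar or length n_beads")
        if any(v <= 0 for v in self.reference_intensities):
            raise ValueError("reference intensities must be positive")


def render_bead_montage(spec: BeadSceneSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render (2, H, W) [reference, target] channels plus a truth table.

    Beads are anti-aliased disks present in both channels; artifacts are
    elongated blobs present in the target channel only (zero reference
    signal above background). Overlaps between beads are permitted and the
    overlapped area fraction is recorded per bead.
    """
    w, h = spec.image_size_px
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0])
    channels = np.zeros((2, h, w), dtype=np.float64)
    occupied = np.zeros((h, w), dtype=bool)
    rows = []
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)

    margin = spec.bead_diameter_px[1] / 2 + 4
    for i in range(spec.n_beads):
        d = float(rng.uniform(*spec.bead_diameter_px))
        cx = float(rng.uniform(margin, w - margin))
        cy = float(rng.uniform(margin, h - margin))
        r = np.hypot(xs - cx, ys - cy)
        cov = np.clip(d / 2 - r + 0.5, 0.0, 1.0)  # 1-px anti-aliased edge
        ref_i = spec.reference_intensities[i]
        tgt_i = spec.target_intensities[i]
        channels[0] += ref_i * cov
        channels[1] += tgt_i * cov
        inside = cov > 0.5
        overlap = float((inside & occupied).sum() / max(inside.sum(), 1))
        occupied |= inside
        rows.append(
            {
                "object_id": f"bead{i:03d}",
                "kind": "bead",
                "center_x_px": cx,
                "center_y_px": cy,
                "diameter_px": d,
                "reference_intensity": ref_i,
                "target_intensity": tgt_i,
                "ratio": tgt_i / ref_i,
                "overlap_fraction": overlap,
            }
        )

    art_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 1])
    for i in range(spec.n_artifacts):
        a = float(art_rng.uniform(10, 25))  # semi-major, px
        b = a / float(art_rng.uniform(2.5, 4.0))  # elongated -> low circularity
        ang = float(art_rng.uniform(0, np.pi))
        cx = float(art_rng.uniform(margin, w - margin))
        cy = float(art_rng.uniform(margin, h - margin))
        xr = (xs - cx) * math.cos(ang) + (ys - cy) * math.sin(ang)
        yr = -(xs - cx) * math.sin(ang) + (ys - cy) * math.cos(ang)
        rr = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
        cov = np.clip((1.0 - rr) * b + 0.5, 0.0, 1.0)
        channels[1] += spec.artifact_intensity * cov
        rows.append(
            {
                "object_id": f"artifact{i:03d}",
                "kind": "artifact",
                "center_x_px": cx,
                "center_y_px": cy,
                "diameter_px": 2 * a,
                "reference_intensity": 0.0,
                "target_intensity": spec.artifact_intensity,
                "ratio": np.nan,
                "overlap_fraction": 0.0,
            }
        )

    channels += spec.background_level
    noise_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 2])
    if spec.noise_sd > 0:
        channels = channels + noise_rng.normal(0.0, spec.noise_sd, channels.shape)
    if spec.saturation_level is not None:
        channels = np.clip(channels, None, spec.saturation_level)

    truth = pd.DataFrame(
        rows,
        columns=[
            "object_id", "kind", "center_x_px", "center_y_px", "diameter_px",
            "reference_intensity", "target_intensity", "ratio", "overlap_fraction",
        ],
    )
    return channels, truth


def bead_scene(
    n_beads: int = 50,
    ratio_mean: float = 2.0,
    ratio_sd: float = 0.1,
    reference_intensity: float = 1000.0,
    reference_span: float = 1.5,
    n_artifacts: int = 0,
    noise_sd: float = 5.0,
    seed: int = 0,
    **kwargs,
) -> BeadSceneSpec:
    """Convenience constructor drawing per-bead intensities around a truth ratio.

    Reference intensities are spread log-uniformly over ``reference_span``-fold
    around ``reference_intensity``; target intensities follow per-bead ratios
    drawn from N(ratio_mean, ratio_sd^2).
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7])
    logspan = math.log(reference_span)
    refs = reference_intensity * np.exp(rng.uniform(-logspan / 2, logspan / 2, n_beads))
    ratios = rng.normal(ratio_mean, ratio_sd, n_beads)
    ratios = np.clip(ratios, 0.05, None)
    return BeadSceneSpec(
        n_beads=n_beads,
        reference_intensities=list(refs),
        target_intensities=list(refs * ratios),
        n_artifacts=n_artifacts,
        noise_sd=noise_sd,
        seed=int(seed),
        **kwargs,
    )
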
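"""Vesicle segmentation: closed contours with a completeness flag.

The detection chain is: background flattening (large-kernel median
subtraction) -> polarity normalization (vesicle features are dark in both
cryo and negative-stain images) -> isotropic Fourier lowpass (cryo only by
default) -> threshold (Otsu by default) -> morphological closing and hole
filling (cryo rims enclose bright lumens) -> connected components ->
distance-transform watershed to split touching objects -> sub-pixel contour
extraction by marching squares.

A detection is "complete" only when its contour stays clear of the border
margin; roundness-based statistics downstream are restricted to complete
vesicles while diameters use all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .io import A_PER_NM, Micrograph


@dataclass
class VesicleDetection:
    """One segmented vesicle: a closed simple polygon plus provenance."""

    contour: np.ndarray  # (N, 2) array of (x, y) pixel coordinates, implicitly closed
    complete: bool
    source_id: str
    area_px: float
    detection_score: float = 1.0
    pixel_size_nm: float = 1.0
    vesicle_id: str = ""

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=np.float64)
        if self.contour.ndim != 2 or self.contour.shape[1] != 2 or len(self.contour) < 3:
            raise ValueError("contour must be an (N>=3, 2) array of (x, y) vertices")


@dataclass
class DetectionParams:
    """Configuration for ``segment_vesicles`` (YAML-friendly)."""

    threshold_method: str = "otsu"  # "otsu" | "mad"
    mad_k: float = 5.0
    min_diameter_nm: float = 20.0  # below the smallest reported EV class
    max_diameter_nm: float = 2000.0
    border_margin_px: int = 2
    lowpass_cutoff_a: float | None = None  # None = auto: max(5 A, 6 px)
    closing_radius_px: int = 2
    split_touching: bool = True
    watershed_h: float = 2.0  # h-maxima depth (px) for marker extraction
    marker_smooth_px: float = 3.0  # distance-map smoothing before h-maxima
    refine_contours: bool = True
    refine_level: float = 0.5  # half-maximum edge refinement
    refine_smooth_px: float = 1.0
    flatten_block_px: int = 8
    flatten_kernel_px: int = 31

    def __post_init__(self) -> None:
        if self.min_diameter_nm >= self.max_diameter_nm:
            raise ValueError("min_diameter_nm must be below max_diameter_nm")


def lowpass_filter(m: Micrograph, cutoff_angstrom: float, soft: bool = True) -> Micrograph:
    """Isotropic Fourier lowpass with a cosine-edge rolloff at the cutoff.

    ``cutoff_angstrom`` is the real-space cutoff wavelength; it must be at
    least twice the pixel size (Nyquist). The zero-frequency term always
    passes, so the image mean is preserved.
    """
    pixel_a = m.pixel_size_a
    if cutoff_angstrom < 2 * pixel_a:
        raise ValueError(
            f"cutoff {cutoff_angstrom} A is below Nyquist ({2 * pixel_a:.3g} A)"
        )
    filtered = _lowpass_array(m.pixels, pixel_a, cutoff_angstrom, soft)
    return Micrograph(
        pixels=filtered,
        pixel_size_nm=m.pixel_size_nm,
        modality=m.modality,
        source_id=m.source_id,
    )


def _lowpass_array(
    pixels: np.ndarray, pixel_a: float, cutoff_angstrom: float, soft: bool = True
) -> np.ndarray:
    h, w = pixels.shape
    fy = np.fft.fftfreq(h, d=pixel_a)[:, None]
    fx = np.fft.rfftfreq(w, d=pixel_a)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    fc = 1.0 / cutoff_angstrom
    if soft:
        # raised cosine from passband edge (0.9 fc) to stopband edge (1.1 fc)
        lo, hi = 0.9 * fc, 1.1 * fc
        mask = np.clip((hi - f) / (hi - lo), 0.0, 1.0)
        mask = 0.5 - 0.5 * np.cos(np.pi * mask)
    else:
        mask = (f <= fc).astype(np.float64)
    spec = np.fft.rfft2(pixels)
    return np.fft.irfft2(spec * mask, s=pixels.shape)


def _remove_small(binary: np.ndarray, min_area_px: float) -> np.ndarray:
    """Drop connected components with area strictly below ``min_area_px``."""
    labels, n = ndimage.label(binary)
    if n == 0:
        return binary
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area_px
    keep[0] = False
    return keep[labels]


def _flatten_background(pixels: np.ndarray, block: int, kernel: int) -> np.ndarray:
    """Subtract a large-scale median background estimated on a decimated grid."""
    small = pixels[::block, ::block]
    bg_small = ndimage.median_filter(small, size=max(kernel, 3))
    zoom = (pixels.shape[0] / bg_small.shape[0], pixels.shape[1] / bg_small.shape[1])
    bg = ndimage.zoom(bg_small, zoom, order=1, grid_mode=True, mode="nearest")
    bg = bg[: pixels.shape[0], : pixels.shape[1]]
    return pixels - bg


def segment_vesicles(
    m: Micrograph, params: DetectionParams | None = None
) -> list[VesicleDetection]:
    """Segment vesicles in a cryo or negative-stain micrograph.

    Returns one detection per object, never silently merging touching
    vesicles: connected regions are split by watershed on the distance
    transform (one marker per regional maximum deeper than ``watershed_h``).
    Detections whose pixels reach the border margin are flagged
    ``complete=False``. A blank or constant image yields an empty list.
    """
    if m.modality not in ("cryo", "nstem"):
        raise ValueError("segment_vesicles expects a cryo or nstem micrograph")
    params = params or DetectionParams()
    pixels = m.pixels
    if np.ptp(pixels) == 0:
        return []

    flat = _flatten_background(pixels, params.flatten_block_px, params.flatten_kernel_px)
    feature = -flat  # vesicle features are dark in both modalities

    if m.modality == "cryo":
        cutoff = params.lowpass_cutoff_a
        if cutoff is None:
            # ~5 A at real cryo pixel sizes; scales with pixel size so the
            # passband always resolves a bilayer-rim-thick ridge
            cutoff = max(5.0, 6.0 * m.pixel_size_a)
        feature = _lowpass_array(feature, m.pixel_size_a, cutoff)
    else:
        feature = ndimage.gaussian_filter(feature, 1.0)

    if params.threshold_method == "otsu":
        thresh = filters.threshold_otsu(feature)
    elif params.threshold_method == "mad":
        med = np.median(feature)
        mad = np.median(np.abs(feature - med)) * 1.4826
        thresh = med + params.mad_k * mad
    else:
        raise ValueError(f"unknown threshold method {params.threshold_method!r}")
    binary = feature > thresh

    if params.closing_radius_px > 0:
        binary = ndimage.binary_closing(
            binary, structure=morphology.disk(params.closing_radius_px)
        )
    binary = ndimage.binary_fill_holes(binary)

    min_d_px = params.min_diameter_nm / m.pixel_size_nm
    max_d_px = params.max_diameter_nm / m.pixel_size_nm
    min_area_px = math.pi * (min_d_px / 2) ** 2
    max_area_px = math.pi * (max_d_px / 2) ** 2
    binary = _remove_small(binary, min_area_px)
    if not binary.any():
        return []

    if params.split_touching:
        dist = ndimage.distance_transform_edt(binary)
        smooth = ndimage.gaussian_filter(dist, params.marker_smooth_px)
        smooth[~binary] = 0.0
        peaks = morphology.h_maxima(smooth, params.watershed_h)
        markers, n_markers = ndimage.label(peaks)
        if n_markers > 0:
            labels = segmentation.watershed(-dist, markers, mask=binary)
        else:
            labels, _ = ndimage.label(binary)
    else:
        labels, _ = ndimage.label(binary)

    # edge refinement works on a lightly smoothed image so that the strong
    # detection lowpass does not displace the half-maximum boundary
    feature_fine = (
        ndimage.gaussian_filter(-flat, params.refine_smooth_px)
        if params.refine_contours
        else feature
    )

    h, w = binary.shape
    margin = params.border_margin_px
    feature_max = float(feature.max())
    detections: list[VesicleDetection] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px or region.area > max_area_px:
            continue
        minr, minc, maxr, maxc = region.bbox
        pad = 4
        r0, c0 = max(minr - pad, 0), max(minc - pad, 0)
        r1, c1 = min(maxr + pad, h), min(maxc + pad, w)
        region_mask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        region_mask[minr - r0 : maxr - r0, minc - c0 : maxc - c0] = region.image

        mask = region_mask
        if params.refine_contours:
            local = feature_fine[r0:r1, c0:c1]
            peak = float(np.percentile(local[region_mask], 99))
            level = params.refine_level * peak
            allowed = ndimage.binary_dilation(region_mask, morphology.disk(2))
            refined = (local > level) & allowed
            refined = ndimage.binary_fill_holes(refined)
            lab_loc, n_loc = ndimage.label(refined)
            if n_loc:
                overlaps = np.bincount(lab_loc[region_mask].ravel(), minlength=n_loc + 1)
                overlaps[0] = 0
                best = int(overlaps.argmax())
                if overlaps[best] > 0:
                    mask = lab_loc == best
        area_px = float(mask.sum())
        if area_px < min_area_px or area_px > max_area_px:
            continue

        rows, cols = np.nonzero(mask)
        complete = not (
            rows.min() + r0 <= margin
            or cols.min() + c0 <= margin
            or rows.max() + r0 >= h - 1 - margin
            or cols.max() + c0 >= w - 1 - margin
        )
        padded = np.pad(mask, 1).astype(np.float64)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        contour_rc = max(contours, key=len)
        # (row, col) in padded patch frame -> global (x, y)
        xy = np.empty_like(contour_rc)
        xy[:, 0] = contour_rc[:, 1] - 1 + c0
        xy[:, 1] = contour_rc[:, 0] - 1 + r0
        if np.allclose(xy[0], xy[-1]):
            xy = xy[:-1]
        if len(xy) < 3:
            continue
        mean_feature = float(feature[labels == region.label].mean())
        denom = feature_max - thresh
        score = (mean_feature - thresh) / denom if denom > 0 else 1.0
        detections.append(
            VesicleDetection(
                contour=xy,
                complete=bool(complete),
                source_id=m.source_id,
                area_px=area_px,
                detection_score=float(np.clip(score, 0.0, 1.0)),
                pixel_size_nm=m.pixel_size_nm,
                vesicle_id=f"{m.source_id}:{region.label}",
            )
        )
    return detections
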
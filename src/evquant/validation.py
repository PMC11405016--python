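"""Recovery benchmarks against synthetic ground truth.

Each function renders a documented synthetic condition, runs the matching
pipeline stage, and reports recovery metrics against the generator's truth.
These are the package's primary correctness checks and are reused by the
test suite and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np

from . import beads, detect, membrane, morphometry, stats, synthetic


def true_equivalent_diameter(truth: synthetic.ShapeTruth) -> float:
    """Analytic area-equivalent diameter (nm) of a generated shape."""
    if truth.kind == "sphere":
        return float(truth.diameter_nm)
    w, length = truth.width_nm, truth.length_nm
    area = w * (length - w) + math.pi * (w / 2) ** 2  # capsule: rect + two half-disks
    return 2.0 * math.sqrt(area / math.pi)


def match_to_truth(
    truths: list[synthetic.ShapeTruth],
    detections: list[detect.VesicleDetection],
    pixel_size_nm: float,
) -> list[tuple[int, int]]:
    """Greedy 1:1 matching of detections to truth shapes.

    A detection matches a truth shape when its contour centroid lies within
    the shape's bounding radius of the true center; each detection is used
    at most once.
    """
    if not truths or not detections:
        return []
    tc = np.array([t.center_nm for t in truths])
    radius = np.array(
        [t.diameter_nm / 2 if t.kind == "sphere" else t.length_nm / 2 for t in truths]
    )
    dc = np.array([d.contour.mean(axis=0) * pixel_size_nm for d in detections])
    dist = np.linalg.norm(tc[:, None, :] - dc[None, :, :], axis=2)
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for ti in range(len(truths)):
        for di in np.argsort(dist[ti]):
            if dist[ti, di] > radius[ti]:
                break
            if int(di) not in used:
                used.add(int(di))
                pairs.append((ti, int(di)))
                break
    return pairs


def benchmark_recovery(seed: int = 11) -> dict:
    """Detection + morphometry recovery on the standard mixed benchmark scene."""
    spec = synthetic.standard_benchmark(seed)
    mic, truths = synthetic.render_micrograph(spec)
    detections = detect.segment_vesicles(mic)
    metrics = [morphometry.measure_detection(d) for d in detections]
    pairs = match_to_truth(truths, detections, mic.pixel_size_nm)

    tp = len(pairs)
    recall = tp / len(truths)
    precision = tp / len(detections) if detections else 0.0

    errors = []
    tub_correct = 0
    n_complete_matched = 0
    for ti, di in pairs:
        t, m = truths[ti], metrics[di]
        d_true = true_equivalent_diameter(t)
        errors.append(abs(m.diameter_nm - d_true) / d_true)
        if m.complete:
            n_complete_matched += 1
            if m.tubular == (t.true_roundness < morphometry.TUBULAR_ROUNDNESS_THRESHOLD):
                tub_correct += 1
    complete_metrics = [m for m in metrics if m.complete]
    est_tubular = (
        sum(1 for m in complete_metrics if m.tubular) / len(complete_metrics)
        if complete_metrics
        else float("nan")
    )
    truth_tubular = sum(
        1 for t in truths if t.true_roundness < morphometry.TUBULAR_ROUNDNESS_THRESHOLD
    ) / len(truths)
    return {
        "n_truth": len(truths),
        "n_detected": len(detections),
        "precision": precision,
        "recall": recall,
        "mean_abs_diameter_error_pct": 100.0 * float(np.mean(errors)) if errors else float("nan"),
        "tubular_accuracy": tub_correct / n_complete_matched if n_complete_matched else float("nan"),
        "tubular_fraction_pct": 100.0 * est_tubular,
        "tubular_fraction_truth_pct": 100.0 * truth_tubular,
    }


def membrane_recovery(
    seed: int = 5,
    fractions: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20),
    image_size_px: int = 1024,
) -> dict:
    """Absolute area-fraction error at several ground-truth coverage levels."""
    errors = {}
    for i, f in enumerate(fractions):
        scene = synthetic.membrane_scene(f, seed=seed + i, image_size_px=image_size_px)
        res = membrane.measure_area_fraction(scene.micrograph)
        errors[f] = abs(res.fraction - scene.true_area_fraction)
    return {
        "abs_errors": errors,
        "max_abs_error": max(errors.values()),
    }


def membrane_fold_recovery(
    seed: int = 17,
    n_per_group: int = 24,
    mean_a: float = 0.056,
    sd_a: float = 0.005,
    mean_b: float = 0.010,
    sd_b: float = 0.002,
    image_size_px: int = 768,
    n_mc: int = 100_000,
) -> dict:
    """Fold-difference recovery between two membrane-coverage conditions.

    Group A montages have coverage ~ N(mean_a, sd_a^2) and group B
    ~ N(mean_b, sd_b^2) (truth ratio 5.6 at the defaults). Returns the
    estimated fold, the truth fold of the realized coverages, the
    first-order propagated SD, and a Monte-Carlo ratio-distribution SD for
    cross-checking the propagation.
    """
    rng = np.random.default_rng(seed)
    results_a, results_b, truth_a, truth_b = [], [], [], []
    for i in range(n_per_group):
        fa = float(np.clip(rng.normal(mean_a, sd_a), 1e-4, 0.5))
        fb = float(np.clip(rng.normal(mean_b, sd_b), 1e-4, 0.5))
        scene_a = synthetic.membrane_scene(fa, seed=int(rng.integers(2**31)), image_size_px=image_size_px)
        scene_b = synthetic.membrane_scene(fb, seed=int(rng.integers(2**31)), image_size_px=image_size_px)
        results_a.append(membrane.measure_area_fraction(scene_a.micrograph, condition="a"))
        results_b.append(membrane.measure_area_fraction(scene_b.micrograph, condition="b"))
        truth_a.append(scene_a.true_area_fraction)
        truth_b.append(scene_b.true_area_fraction)
    comparison = membrane.compare_membrane_yield(results_a, results_b)
    truth_fold = float(np.mean(truth_a) / np.mean(truth_b))

    # Monte-Carlo oracle for the ratio of means under the observed group spreads
    fa = np.array([r.fraction for r in results_a])
    fb = np.array([r.fraction for r in results_b])
    mc_rng = np.random.default_rng(seed + 1)
    mc_a = mc_rng.normal(fa.mean(), fa.std(ddof=1) / math.sqrt(len(fa)), n_mc)
    mc_b = mc_rng.normal(fb.mean(), fb.std(ddof=1) / math.sqrt(len(fb)), n_mc)
    mc_sd = float((mc_a / mc_b).std(ddof=1))
    return {
        "fold": comparison.fold,
        "fold_sd": comparison.fold_sd,
        "truth_fold": truth_fold,
        "mc_sd": mc_sd,
        "p_value": comparison.p_value,
    }


def bead_recovery(seed: int = 3, n_beads: int = 50, n_artifacts: int = 5) -> dict:
    """Relative target binding (test vs control montage) plus artifact handling."""
    spec_test = synthetic.bead_scene(
        n_beads=n_beads, ratio_mean=2.0, ratio_sd=0.1, n_artifacts=n_artifacts, seed=seed
    )
    spec_ctrl = synthetic.bead_scene(
        n_beads=n_beads, ratio_mean=1.0, ratio_sd=0.05, seed=seed + 1
    )
    ch_test, truth_test = synthetic.render_bead_montage(spec_test)
    ch_ctrl, _ = synthetic.render_bead_montage(spec_ctrl)
    regions_test = beads.quantify_montage(ch_test)
    regions_ctrl = beads.quantify_montage(ch_ctrl)

    artifacts = truth_test[truth_test.kind == "artifact"]
    artifacts_excluded = 0
    for row in artifacts.itertuples(index=False):
        for r in regions_test:
            y, x = int(round(row.center_y_px)), int(round(row.center_x_px))
            if r.mask[y, x] and r.excluded:
                artifacts_excluded += 1
                break

    ratios = {
        "test": [r.ratio for r in regions_test if not r.excluded],
        "control": [r.ratio for r in regions_ctrl if not r.excluded],
    }
    summary = {s.condition: s for s in beads.condition_summary(ratios, "control")}
    return {
        "relative_binding": summary["test"].relative_to_control,
        "n_artifacts": int(len(artifacts)),
        "n_artifacts_excluded": artifacts_excluded,
        "n_included_test": summary["test"].n_included,
        "mean_ratio_test": summary["test"].mean_ratio,
        "truth_mean_ratio_test": float(truth_test.loc[truth_test.kind == "bead", "ratio"].mean()),
    }


def t_test_type_i_rate(
    seed: int = 42, n_sim: int = 10_000, n_per_group: int = 3, alpha: float = 0.05
) -> float:
    """Rejection rate of the unpaired t test under the null N(0,1) vs N(0,1)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    x = rng.normal(size=(n_sim, n_per_group))
    y = rng.normal(size=(n_sim, n_per_group))
    for i in range(n_sim):
        if stats.t_test_unpaired(x[i], y[i]).p_value < alpha:
            rejections += 1
    return rejections / n_sim
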
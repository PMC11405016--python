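"""Lowpass filter contracts and segmentation recovery on synthetic scenes."""

import numpy as np
import pytest

from evquant import detect, synthetic
from evquant.io import Micrograph
from evquant.validation import match_to_truth


def smooth_test_image(seed=0, size=96):
    rng = np.random.default_rng(seed)
    ys, xs = np.mgrid[0:size, 0:size]
    img = np.ones((size, size))
    for _ in range(3):
        cx, cy, s = rng.uniform(20, size - 20, 2).tolist() + [rng.uniform(4, 8)]
        img += np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * s**2))
    return img


class TestLowpassFilter:
    def test_mean_preserved(self):
        rng = np.random.default_rng(1)
        m = Micrograph(rng.normal(5.0, 1.0, (64, 64)), pixel_size_nm=1.0)
        out = detect.lowpass_filter(m, cutoff_angstrom=60.0)
        assert out.pixels.mean() == pytest.approx(m.pixels.mean(), rel=1e-6)

    def test_identity_at_nyquist_for_bandlimited_image(self):
        # band-limited periodic image: all spectral content strictly inside
        # the Nyquist radius, so a brick-wall cutoff at Nyquist is an identity
        size = 96
        rng = np.random.default_rng(5)
        spec = rng.normal(size=(size, size)) + 1j * rng.normal(size=(size, size))
        fy = np.fft.fftfreq(size)[:, None]
        fx = np.fft.fftfreq(size)[None, :]
        spec[np.sqrt(fx**2 + fy**2) > 0.45] = 0
        img = np.real(np.fft.ifft2(spec)) + 10.0
        m = Micrograph(img, pixel_size_nm=1.0)
        out = detect.lowpass_filter(m, cutoff_angstrom=2 * m.pixel_size_a, soft=False)
        assert np.allclose(out.pixels, m.pixels, atol=1e-12)

    def test_below_nyquist_rejected(self):
        m = Micrograph(smooth_test_image(), pixel_size_nm=1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            detect.lowpass_filter(m, cutoff_angstrom=19.0)

    def test_impulse_response_matches_direct_fft_mask_oracle(self):
        # independent construction of the same radial mask applied to a
        # delta function, full complex FFT (implementation uses rfft2)
        size, pixel_a, cutoff = 64, 10.0, 40.0
        img = np.zeros((size, size))
        img[size // 2, size // 2] = 1.0
        m = Micrograph(img, pixel_size_nm=pixel_a / 10)
        out = detect.lowpass_filter(m, cutoff_angstrom=cutoff)

        fy = np.fft.fftfreq(size, d=pixel_a)[:, None]
        fx = np.fft.fftfreq(size, d=pixel_a)[None, :]
        f = np.sqrt(fx**2 + fy**2)
        fc = 1.0 / cutoff
        lo, hi = 0.9 * fc, 1.1 * fc
        ramp = np.clip((hi - f) / (hi - lo), 0.0, 1.0)
        mask = 0.5 - 0.5 * np.cos(np.pi * ramp)
        oracle = np.real(np.fft.ifft2(np.fft.fft2(img) * mask))
        assert np.allclose(out.pixels, oracle, atol=1e-12)


class TestSegmentVesicles:
    def test_blank_image_yields_empty_list(self):
        m = Micrograph(np.ones((64, 64)), pixel_size_nm=2.0, modality="cryo")
        assert detect.segment_vesicles(m) == []

    def test_pathological_params_rejected(self):
        with pytest.raises(ValueError):
            detect.DetectionParams(min_diameter_nm=500, max_diameter_nm=100)

    def test_spheres_recovered_and_matched_to_truth(self):
        # 20 non-overlapping spheres, SNR 5: every one found, all complete
        rng = np.random.default_rng(21)
        shapes = []
        for i in range(20):
            row, col = divmod(i, 5)
            shapes.append(
                synthetic.ShapeTruth(
                    shape_id=f"s{i}", kind="sphere",
                    center_nm=(300 + col * 420 + rng.uniform(-30, 30),
                               300 + row * 420 + rng.uniform(-30, 30)),
                    diameter_nm=float(rng.uniform(40, 250)),
                )
            )
        spec = synthetic.SceneSpec(
            image_size_px=(1100, 1000), pixel_size_nm=2.0, modality="cryo",
            shapes=shapes, noise=synthetic.NoiseSpec(0.2, 0.02, 0.1), seed=21,
        )
        mic, truths = synthetic.render_micrograph(spec)
        detections = detect.segment_vesicles(mic)
        assert len(detections) == 20
        assert all(d.complete for d in detections)
        assert len(match_to_truth(truths, detections, mic.pixel_size_nm)) == 20

    def test_border_sphere_flagged_incomplete(self):
        spec = synthetic.SceneSpec(
            image_size_px=(200, 200), pixel_size_nm=2.0, modality="cryo",
            shapes=[synthetic.ShapeTruth(shape_id="e", kind="sphere",
                                         center_nm=(0.0, 200.0), diameter_nm=120)],
            seed=3,
        )
        mic, _ = synthetic.render_micrograph(spec)
        detections = detect.segment_vesicles(mic)
        assert len(detections) == 1
        assert detections[0].complete is False

    def test_gain_and_offset_invariance(self):
        spec = synthetic.SceneSpec(
            image_size_px=(256, 256), pixel_size_nm=2.0, modality="nstem",
            shapes=[synthetic.ShapeTruth(shape_id="s", kind="sphere",
                                         center_nm=(256, 256), diameter_nm=150)],
            noise=synthetic.NoiseSpec(gaussian_sd=0.1), seed=5,
        )
        mic, _ = synthetic.render_micrograph(spec)
        base = detect.segment_vesicles(mic)
        scaled = Micrograph(3.5 * mic.pixels + 40.0, pixel_size_nm=2.0, modality="nstem")
        transformed = detect.segment_vesicles(scaled)
        assert len(base) == len(transformed) == 1
        assert base[0].area_px == transformed[0].area_px
        assert np.allclose(base[0].contour, transformed[0].contour)

    def test_touching_spheres_split_not_merged(self):
        # two overlapping bodies must yield two detections (watershed), never one
        shapes = [
            synthetic.ShapeTruth(shape_id="a", kind="sphere", center_nm=(210, 256), diameter_nm=120),
            synthetic.ShapeTruth(shape_id="b", kind="sphere", center_nm=(320, 256), diameter_nm=120),
        ]
        spec = synthetic.SceneSpec(
            image_size_px=(256, 256), pixel_size_nm=2.0, modality="nstem",
            shapes=shapes, noise=synthetic.NoiseSpec(gaussian_sd=0.05), seed=6,
        )
        mic, truths = synthetic.render_micrograph(spec)
        detections = detect.segment_vesicles(mic)
        assert len(detections) == 2

    def test_no_complete_detection_touches_margin(self):
        shapes = [
            synthetic.ShapeTruth(shape_id="edge", kind="sphere", center_nm=(10, 100), diameter_nm=100),
            synthetic.ShapeTruth(shape_id="mid", kind="sphere", center_nm=(400, 300), diameter_nm=120),
            synthetic.ShapeTruth(shape_id="corner", kind="sphere", center_nm=(790, 590), diameter_nm=90),
        ]
        spec = synthetic.SceneSpec(
            image_size_px=(400, 300), pixel_size_nm=2.0, modality="nstem",
            shapes=shapes, noise=synthetic.NoiseSpec(gaussian_sd=0.1), seed=7,
        )
        mic, _ = synthetic.render_micrograph(spec)
        params = detect.DetectionParams()
        for d in detect.segment_vesicles(mic, params):
            if d.complete:
                x, y = d.contour[:, 0], d.contour[:, 1]
                assert x.min() > params.border_margin_px
                assert y.min() > params.border_margin_px
                assert x.max() < 400 - 1 - params.border_margin_px
                assert y.max() < 300 - 1 - params.border_margin_px
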
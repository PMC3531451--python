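"""Spot quantification: background, detection, IOD integration."""

import numpy as np
import pandas as pd
import pytest

from mdgel.model import AxisCalibration, DetectedSpot, GelImage
from mdgel.quantify import (
    ParameterError,
    correct_background,
    detect_spots,
    integrate_iod,
    quantify_gel,
)
from mdgel.simulate import SimulationConfig, render_gel, simulate_proteome


def _single_spot_truth(pi=6.5, mw=30.0, volume=1000.0):
    return pd.DataFrame({
        "spot_id": ["s0"], "pi": [pi], "mw_kda": [mw],
        "volume_control": [volume], "volume_case": [volume],
        "true_ratio": [1.0], "differential": [False],
    })


class TestBackground:
    def test_constant_image_goes_to_zero(self):
        img = GelImage(pixels=np.full((128, 128), 37.0))
        out = correct_background(img, radius=10)
        assert np.allclose(out.pixels, 0.0, atol=1e-9)

    def test_all_zero_image_stays_zero(self):
        img = GelImage(pixels=np.zeros((64, 64)))
        out = correct_background(img, radius=10)
        assert np.allclose(out.pixels, 0.0)

    def test_gaussian_spot_on_background_recovered(self):
        cfg = SimulationConfig(noise_sd=0.0, background_level=100.0,
                               gel_scale_factors={"control": 1.0},
                               image_shape=(256, 256), seed=0)
        img = render_gel(_single_spot_truth(), "control", cfg)
        out = correct_background(img, radius=25)
        assert out.pixels.sum() == pytest.approx(1000.0, rel=0.02)

    def test_oversized_window_rejected(self):
        img = GelImage(pixels=np.zeros((32, 32)))
        with pytest.raises(ParameterError):
            correct_background(img, radius=40)


class TestDetection:
    def test_well_separated_spots_all_found(self):
        cfg = SimulationConfig(n_spots=50, seed=13)
        truth = simulate_proteome(cfg)
        img = render_gel(truth, "control", cfg)
        corrected = correct_background(img)
        spots = detect_spots(corrected)
        assert len(spots) == 50
        cal = corrected.calibration
        truth_px = np.array([
            [cal.row_of_mw(mw), cal.col_of_pi(pi)]
            for pi, mw in zip(truth["pi"], truth["mw_kda"])
        ])
        for s in spots:
            d = np.sqrt(((truth_px - np.array(s.centroid)) ** 2).sum(axis=1))
            assert d.min() <= 2.0  # centroid within 2 px of a truth spot

    def test_empty_image_no_detections(self):
        img = GelImage(pixels=np.zeros((64, 64)))
        assert detect_spots(img) == []

    def test_two_close_peaks_merge_to_one(self):
        # two Gaussians 4 px apart, closer than min_separation=8
        px = np.zeros((64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        for c0 in (30.0, 34.0):
            px += 100 * np.exp(-0.5 * (((rr - 32) / 1.5) ** 2 + ((cc - c0) / 1.5) ** 2))
        img = GelImage(pixels=px, meta={"background": {"noise_sd": 1.0}})
        assert len(detect_spots(img, min_separation=8)) == 1

    def test_deterministic_for_fixed_image(self, benchmark_scene):
        corrected = correct_background(benchmark_scene.images["case"])
        a = detect_spots(corrected)
        b = detect_spots(corrected)
        assert [s.spot_id for s in a] == [s.spot_id for s in b]
        assert [s.iod for s in a] == [s.iod for s in b]

    def test_benchmark_recall_and_precision(self, benchmark_scene):
        cfg = benchmark_scene.config
        img = benchmark_scene.images["control"]
        corrected = correct_background(img)
        spots = detect_spots(corrected)
        cal = corrected.calibration
        truth = benchmark_scene.truth
        truth_px = np.array([
            [cal.row_of_mw(mw), cal.col_of_pi(pi)]
            for pi, mw in zip(truth["pi"], truth["mw_kda"])
        ])
        matched_truth = set()
        n_true_positive = 0
        for s in spots:
            d = np.sqrt(((truth_px - np.array(s.centroid)) ** 2).sum(axis=1))
            k = int(np.argmin(d))
            if d[k] <= 4.0 and k not in matched_truth:
                matched_truth.add(k)
                n_true_positive += 1
        recall = len(matched_truth) / cfg.n_spots
        precision = n_true_positive / len(spots)
        assert recall >= 0.95
        assert precision >= 0.95


class TestIntegration:
    def test_constant_mask_arithmetic(self):
        px = np.zeros((16, 16))
        px[2:4, 3:8] = 3.0  # 10 pixels of value 3
        img = GelImage(pixels=px, gel_id="G")
        mask = np.argwhere(px > 0)
        spot = DetectedSpot("s1", (2.5, 5.0), 5.0, 30.0, mask=mask)
        table = integrate_iod(img, [spot])
        assert table.records[0].iod_raw == pytest.approx(30.0)

    def test_empty_mask_zero_iod(self):
        img = GelImage(pixels=np.zeros((8, 8)))
        spot = DetectedSpot("s1", (4, 4), 5.0, 30.0, mask=np.empty((0, 2), dtype=int))
        assert integrate_iod(img, [spot]).records[0].iod_raw == 0.0

    def test_overlapping_masks_rejected(self):
        img = GelImage(pixels=np.ones((8, 8)))
        m = np.array([[1, 1], [1, 2]])
        spots = [DetectedSpot("a", (1, 1), 5, 30, mask=m),
                 DetectedSpot("b", (1, 2), 5, 30, mask=m[1:])]
        with pytest.raises(RuntimeError, match="overlap"):
            integrate_iod(img, spots)

    def test_noiseless_spot_volume_within_2pct(self):
        cfg = SimulationConfig(noise_sd=0.0, background_level=0.0,
                               gel_scale_factors={"control": 1.0},
                               image_shape=(256, 256), seed=0)
        img = render_gel(_single_spot_truth(volume=1000.0), "control", cfg)
        table = quantify_gel(img)
        assert len(table) == 1
        assert table.records[0].iod_raw == pytest.approx(1000.0, rel=0.02)

    def test_noiseless_total_iod_conservation(self, noiseless_scene):
        cfg = noiseless_scene.config
        for group, image in noiseless_scene.images.items():
            table = quantify_gel(image)
            expected = (
                noiseless_scene.truth[f"volume_{group}"].sum()
                * cfg.gel_scale_factors[group]
            )
            assert table.total_iod() == pytest.approx(expected, rel=0.02)

    def test_iod_linear_in_volume(self):
        # a volume ladder rendered noiselessly: slope within [0.95, 1.05]
        volumes = np.geomspace(200, 15000, 16)
        pis = np.linspace(3.8, 9.2, 16)
        truth = pd.DataFrame({
            "spot_id": [f"s{i}" for i in range(16)],
            "pi": pis, "mw_kda": [30.0] * 16,
            "volume_control": volumes, "volume_case": volumes,
            "true_ratio": [1.0] * 16, "differential": [False] * 16,
        })
        cfg = SimulationConfig(noise_sd=0.0, background_level=60.0,
                               gel_scale_factors={"control": 1.0}, seed=0)
        img = render_gel(truth, "control", cfg)
        table = quantify_gel(img)
        assert len(table) == 16
        cal = img.calibration
        est = []
        for v, pi in zip(volumes, pis):
            rec = min(table, key=lambda r: abs(r.pi_coord - pi))
            est.append(rec.iod_raw)
        slope = np.polyfit(volumes, est, 1)[0]
        assert 0.95 <= slope <= 1.05
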
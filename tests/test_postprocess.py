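import numpy as np
import pytest
from scipy import ndimage

from rhizotrace.postprocess import (
    CRFConfig,
    crf_refine,
    dedup_points,
    localize_features,
    nms_peaks,
)
from rhizotrace.targets import ClassMaps, render_heatmaps


def gaussian_map(shape, centers, amplitude=1.0, sigma=1.5):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.zeros(shape)
    for cx, cy in centers:
        out += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return np.clip(out, 0.0, 1.0)


class TestNms:
    def test_all_zero_map_is_empty(self):
        assert nms_peaks(np.zeros((32, 32))) == []

    def test_single_gaussian_returns_its_peak(self):
        chan = gaussian_map((128, 128), [(100, 100)])
        assert [(x, y) for x, y, _ in nms_peaks(chan)] == [(100, 100)]

    def test_peak_below_threshold_suppressed(self):
        chan = gaussian_map((64, 64), [(30, 30)], amplitude=0.6)
        assert nms_peaks(chan, threshold=0.7) == []

    def test_two_distant_gaussians_both_found(self):
        chan = gaussian_map((64, 96), [(20, 30), (50, 30)])
        pts = nms_peaks(chan)
        assert len(pts) == 2
        for (x, y, _), (cx, cy) in zip(sorted(pts), [(20, 30), (50, 30)]):
            assert abs(x - cx) <= 1 and abs(y - cy) <= 1

    def test_tied_plateau_keeps_earlier_scanned_pixel(self):
        chan = np.zeros((16, 16))
        chan[5, 5] = chan[5, 6] = 0.9  # two equal adjacent maxima
        pts = nms_peaks(chan)
        assert [(x, y) for x, y, _ in pts] == [(5, 5)]


class TestDedup:
    def test_empty_input(self):
        assert dedup_points([]) == []

    def test_close_pair_keeps_first(self):
        pts = [(10, 10, 1.0), (13, 14, 0.9)]  # 5 px apart
        assert dedup_points(pts, radius=8.0) == [pts[0]]

    def test_pair_beyond_radius_kept(self):
        pts = [(10, 10, 1.0), (19, 10, 0.9)]  # 9 px apart
        assert dedup_points(pts, radius=8.0) == pts

    def test_greedy_chain(self):
        # c is within radius of b, but b was dropped for a; c survives
        pts = [(0, 0, 1.0), (6, 0, 0.9), (12, 0, 0.8)]
        assert dedup_points(pts, radius=8.0) == [pts[0], pts[2]]


class TestLocalizeFeatures:
    def test_counts_match_synthetic_ground_truth(self, small_fibrous_system):
        heats = render_heatmaps(small_fibrous_system, (384, 384), sigma=1.0)
        fs = localize_features(heats)
        assert len(fs.seeds) == 1
        assert len(fs.tips1) == small_fibrous_system.count_roots(1)
        assert len(fs.tips2) == small_fibrous_system.count_roots(2)

    def test_all_zero_channels_empty(self):
        from rhizotrace.targets import HeatMaps

        z = np.zeros((32, 32))
        fs = localize_features(HeatMaps(seed=z, tip1=z, tip2=z))
        assert fs.seeds == [] and fs.tips1 == [] and fs.tips2 == []

    def test_two_tips_six_px_apart_collapse_to_one(self):
        from rhizotrace.targets import HeatMaps

        z = np.zeros((64, 64))
        tip = gaussian_map((64, 64), [(30, 30), (36, 30)])  # 6 px apart
        fs = localize_features(HeatMaps(seed=z, tip1=tip, tip2=z))
        assert len(fs.tips1) == 1


class TestDenseCrf:
    def _image(self, rng, shape):
        return rng.random(shape + (3,)) * 0.2

    def test_disabled_stage_is_identity(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet([1, 1, 1], size=(16, 16)).transpose(2, 0, 1)
        maps = ClassMaps(background=probs[0], order1=probs[1], order2=probs[2])
        out = crf_refine(maps, self._image(rng, (16, 16)), CRFConfig(enabled=False))
        assert out is maps

    def test_confident_prediction_nearly_unchanged(self):
        rng = np.random.default_rng(1)
        h = w = 48
        bg = np.full((h, w), 0.98)
        other = np.full((h, w), 0.01)
        maps = ClassMaps(background=bg, order1=other, order2=other)
        out = crf_refine(maps, self._image(rng, (h, w)))
        flips = (out.stack().argmax(axis=0) != 0).mean()
        assert flips < 0.001

    def test_salt_and_pepper_noise_reduced(self):
        rng = np.random.default_rng(2)
        h = w = 64
        fg = np.full((h, w), 0.05)
        noise = rng.random((h, w)) < 0.01
        fg[noise] = 0.9  # isolated foreground spikes on clean background
        bg = 1.0 - fg
        maps = ClassMaps(background=bg, order1=fg, order2=np.zeros((h, w)))
        img = np.full((h, w, 3), 0.5)  # uniform appearance

        def isolated_count(m):
            lab = m.stack().argmax(axis=0) == 1
            labeled, n = ndimage.label(lab, structure=np.ones((3, 3)))
            sizes = ndimage.sum(lab, labeled, range(1, n + 1))
            return int(np.sum(sizes == 1))

        before = isolated_count(maps)
        after = isolated_count(crf_refine(maps, img))
        assert before > 0
        assert after < before

    def test_output_remains_normalized(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet([1, 2, 3], size=(24, 24)).transpose(2, 0, 1)
        maps = ClassMaps(background=probs[0], order1=probs[1], order2=probs[2])
        out = crf_refine(maps, self._image(rng, (24, 24)))
        np.testing.assert_allclose(out.stack().sum(axis=0), 1.0, atol=1e-9)
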
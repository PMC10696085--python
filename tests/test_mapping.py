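"""Mirror padding, grid geometry and sliding-window label maps."""

import numpy as np
import pytest

from musemap import (DecisionThreshold, WindowConfig, compute_label_map,
                     map_dimensions, mirror_pad)
from musemap.mapping import LabelMap
from .conftest import blank_image


class TestMirrorPad:
    def test_full_scale_padded_size(self):
        img = np.zeros((2048, 2592, 3), np.float32)
        assert mirror_pad(img, 128).shape == (2304, 2848, 3)

    def test_zero_pad_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(40, 50, 3))
        assert np.array_equal(mirror_pad(img, 0), img)

    def test_reflection_excludes_edge_pixel(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(size=(30, 40))
        pad = 8
        out = mirror_pad(img, pad)
        for k in range(pad):
            assert np.allclose(out[pad:-pad, pad - 1 - k], img[:, k + 1])
            assert np.allclose(out[pad - 1 - k, pad:-pad], img[k + 1, :])

    def test_pad_as_large_as_image_rejected(self):
        with pytest.raises(ValueError):
            mirror_pad(np.zeros((16, 16)), 16)


class TestMapDimensions:
    def test_full_scale_contract(self):
        assert map_dimensions(2592, 2048, WindowConfig(256, 10, 128)) == (259, 204)

    def test_single_window_fits(self):
        assert map_dimensions(266, 266, WindowConfig(256, 10, 0)) == (1, 1)

    def test_desk_scale_matches_position_enumeration(self):
        cfg = WindowConfig(64, 10, 32)
        nw, nh = map_dimensions(640, 512, cfg)
        assert (nw, nh) == (64, 51)
        # enumerate scan positions: the scan advances while one more step
        # still fits, which drops the final window unless it lands exactly
        for length, n in ((640, nw), (512, nh)):
            padded = length + 2 * cfg.pad
            starts, p = [], 0
            while p + cfg.step <= padded - cfg.window:
                starts.append(p)
                p += cfg.step
            assert len(starts) == n

    def test_inclusive_convention_adds_one_per_axis(self):
        cfg = WindowConfig(256, 10, 128, inclusive_last_window=True)
        assert map_dimensions(2592, 2048, cfg) == (260, 205)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            map_dimensions(100, 100, WindowConfig(256, 10, 0))


class _ConstantScorer:
    def __init__(self, score):
        self.score = score

    def decision_scores(self, windows):
        return np.full(len(windows), self.score)


class _MeanScorer:
    """Deterministic content-dependent scorer for oracle comparisons."""

    def decision_scores(self, windows):
        return np.asarray(windows).mean(axis=(1, 2, 3)) / 255.0


class TestComputeLabelMap:
    def test_constant_positive_scorer_fills_grid(self, ffpe_image):
        cfg = WindowConfig(64, 16, 32)
        lm = compute_label_map(ffpe_image, None, _ConstantScorer(1.0),
                               DecisionThreshold(0.5), cfg)
        assert lm.grid.all()
        nw, nh = map_dimensions(ffpe_image.pixels.shape[1],
                                ffpe_image.pixels.shape[0], cfg)
        assert lm.grid.shape == (nh, nw)

    @pytest.mark.parametrize("h,w,window,step,pad", [
        (96, 128, 32, 8, 16), (100, 100, 64, 10, 32), (80, 160, 32, 16, 0),
        (128, 96, 48, 12, 24), (160, 160, 64, 32, 32)])
    def test_grid_shape_matches_contract(self, h, w, window, step, pad):
        cfg = WindowConfig(window, step, pad)
        lm = compute_label_map(blank_image(h, w), None, _ConstantScorer(0.0),
                               DecisionThreshold(0.5), cfg)
        assert lm.grid.shape == (map_dimensions(w, h, cfg)[1],
                                 map_dimensions(w, h, cfg)[0])

    def test_matches_sequential_window_oracle(self, ffpe_image):
        cfg = WindowConfig(64, 16, 32)
        model = _MeanScorer()
        t = DecisionThreshold(0.2)
        lm = compute_label_map(ffpe_image, None, model, t, cfg)
        padded = mirror_pad(ffpe_image.pixels, cfg.pad)
        nw, nh = map_dimensions(ffpe_image.pixels.shape[1],
                                ffpe_image.pixels.shape[0], cfg)
        for i in range(nh):
            for j in range(nw):
                win = padded[i * cfg.step:i * cfg.step + cfg.window,
                             j * cfg.step:j * cfg.step + cfg.window]
                score = win.mean() / 255.0
                assert lm.grid[i, j] == (1 if score >= t.value else 0), (i, j)

    def test_deterministic(self, unfixed_image):
        cfg = WindowConfig(64, 32, 32)
        a = compute_label_map(unfixed_image, None, _MeanScorer(),
                              DecisionThreshold(0.3), cfg)
        b = compute_label_map(unfixed_image, None, _MeanScorer(),
                              DecisionThreshold(0.3), cfg)
        assert np.array_equal(a.grid, b.grid)

    def test_constant_image_yields_constant_map(self):
        img = blank_image(96, 96)
        img.pixels += 120.0
        lm = compute_label_map(img, None, _MeanScorer(),
                               DecisionThreshold(0.4), WindowConfig(32, 16, 16))
        assert len(np.unique(lm.grid)) == 1

    def test_translator_requires_unfixed_domain(self, ffpe_image):
        class _FakePair:
            g_ab = g_ba = None

        with pytest.raises(ValueError):
            compute_label_map(ffpe_image, _FakePair(), _ConstantScorer(1.0),
                              DecisionThreshold(0.5), WindowConfig(64, 32, 32))
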
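"""Coverage arithmetic, tiling identity, segmenter contract, series building."""

import numpy as np
import pytest

from panicov import coverage_extraction as ce
from panicov import piecewise_model as pm
from panicov import synthetic_data as sd


class TileOracle:
    """Segmenter that returns the ground-truth mask tile by tile."""

    def __init__(self, mask, tile):
        self.mask = mask
        self.tile = tile
        self.i = 0
        self.per_row = mask.shape[1] // tile

    def __call__(self, tile_img):
        r, c = divmod(self.i, self.per_row)
        self.i += 1
        t = self.tile
        return self.mask[r * t : (r + 1) * t, c * t : (c + 1) * t]


class TestCoverageFromMask:
    def test_all_foreground_is_one(self):
        assert ce.coverage_from_mask(np.ones((5, 5), dtype=int)) == 1.0

    def test_direct_ratio(self):
        mask = np.zeros(400, dtype=int)
        mask[:100] = 1
        assert ce.coverage_from_mask(mask.reshape(20, 20)) == 0.25

    def test_generator_bookkeeping_matches(self, small_image_config):
        pair = sd.generate_image_pair(small_image_config, 0.3, seed=2)
        assert ce.coverage_from_mask(pair.mask) == pair.true_coverage

    def test_empty_and_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            ce.coverage_from_mask(np.empty((0,)))
        with pytest.raises(ValueError):
            ce.coverage_from_mask(np.full((3, 3), 7))


class TestPlotCoverage:
    def test_mean_of_tiles_equals_whole_image_coverage(self, ref_params):
        # equal-area tiles: the 9-tile average is algebraically exact
        cfg = sd.ScenarioConfig(true_params=ref_params, image_size=384, seed=0)
        pair = sd.generate_image_pair(cfg, 0.33, seed=4)
        cov = ce.plot_coverage(pair.image, TileOracle(pair.mask, 128), size=384, tile=128)
        assert cov == pytest.approx(ce.coverage_from_mask(pair.mask), abs=1e-12)

    def test_all_zero_segmenter_gives_zero(self, small_image_config):
        pair = sd.generate_image_pair(small_image_config, 0.5, seed=5)
        cov = ce.plot_coverage(
            pair.image, lambda t: np.zeros(t.shape[:2], dtype=np.uint8),
            size=96, tile=32,
        )
        assert cov == 0.0

    def test_color_rule_segmenter_recovers_synthetic_coverage(self, ref_params):
        cfg = sd.ScenarioConfig(true_params=ref_params, image_size=384)
        pair = sd.generate_image_pair(cfg, 0.25, seed=6)
        seg = ce.make_color_rule_segmenter(
            ce.ColorRule(lo=(150, 130, 40), hi=(255, 235, 160))
        )
        est = ce.plot_coverage(pair.image, seg, size=384, tile=128)
        assert abs(est - pair.true_coverage) < 0.02

    def test_bad_segmenter_shape_reported_with_tile_index(self, small_image_config):
        pair = sd.generate_image_pair(small_image_config, 0.2, seed=7)
        with pytest.raises(ValueError, match="tile 0"):
            ce.plot_coverage(
                pair.image, lambda t: np.zeros((7, 7)), size=96, tile=32
            )


class TestColorRule:
    def test_exact_rule_without_jitter_recovers_ground_truth(self, ref_params):
        cfg = sd.ScenarioConfig(
            true_params=ref_params, image_size=64, color_jitter_sd=0.0
        )
        pair = sd.generate_image_pair(cfg, 0.4, seed=8)
        rule = ce.ColorRule(lo=cfg.panicle_color, hi=cfg.panicle_color)
        assert np.array_equal(ce.color_rule_segmenter(pair.image, rule), pair.mask)

    def test_inverted_rule_gives_complement(self, ref_params):
        cfg = sd.ScenarioConfig(
            true_params=ref_params, image_size=64, color_jitter_sd=0.0
        )
        pair = sd.generate_image_pair(cfg, 0.4, seed=8)
        rule = ce.ColorRule(lo=cfg.panicle_color, hi=cfg.panicle_color, invert=True)
        assert np.array_equal(ce.color_rule_segmenter(pair.image, rule), 1 - pair.mask)

    def test_jittered_error_rate_below_gaussian_tail_bound(self, ref_params):
        # midpoint thresholds: a pixel flips class only if one channel's
        # N(0, sd) jitter crosses half the class color gap; union bound
        # over 3 channels and both classes gives the ceiling
        from scipy.stats import norm

        sdv = 10.0
        cfg = sd.ScenarioConfig(
            true_params=ref_params, image_size=256, color_jitter_sd=sdv
        )
        pair = sd.generate_image_pair(cfg, 0.35, seed=9)
        lo = tuple(
            (p + b) // 2 for p, b in zip(cfg.panicle_color, cfg.background_color)
        )
        rule = ce.ColorRule(lo=lo, hi=(255, 255, 255))
        pred = ce.color_rule_segmenter(pair.image, rule)
        err = float(np.mean(pred != pair.mask))
        gaps = [abs(p - b) / 2 for p, b in zip(cfg.panicle_color, cfg.background_color)]
        bound = sum(norm.sf((g - 1) / sdv) for g in gaps)  # -1: integer rounding
        assert err <= bound

    def test_degenerate_rule_warns_and_returns_background(self):
        tile = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.warns(UserWarning):
            mask = ce.color_rule_segmenter(
                tile, ce.ColorRule(lo=(200, 200, 200), hi=(10, 10, 10))
            )
        assert not mask.any()


class TestBuildSeries:
    @staticmethod
    def _flat_image(value, size=32):
        img = np.empty((size, size, 3), dtype=np.uint8)
        img[:] = value
        return img

    @staticmethod
    def _threshold_segmenter(tile):
        return (tile[..., 0] > 127).astype(np.uint8)

    def test_single_image_single_observation(self):
        entries = [("p1", 3.0, self._flat_image(200))]
        with pytest.warns(UserWarning, match="only 1 observations"):
            (series,) = ce.build_series(
                entries, self._threshold_segmenter, size=32, tile=16
            )
        assert len(series) == 1
        assert series.coverage[0] == 1.0

    def test_same_day_images_averaged(self):
        entries = [
            ("p1", float(d), self._flat_image(v))
            for d, v in [(0, 0), (2, 0), (4, 0), (6, 0), (8, 200), (8, 0)]
        ]
        (series,) = ce.build_series(entries, self._threshold_segmenter, size=32, tile=16)
        assert len(series) == 5
        assert series.coverage[-1] == pytest.approx(0.5)

    def test_end_to_end_series_tracks_noiseless_curve(self, ref_params):
        # synthetic images at coverages from the model curve; the color-rule
        # pipeline should reproduce the curve within segmenter error
        days = np.array([4.0, 8.0, 12.0, 16.0, 24.0, 32.0])
        truth = pm.evaluate(ref_params, days)
        cfg = sd.ScenarioConfig(true_params=ref_params, image_size=192)
        entries = []
        for d, c in zip(days, truth):
            pair = sd.generate_image_pair(cfg, float(c), seed=int(d), tolerance=0.005)
            entries.append(("p1", float(d), pair.image))
        seg = ce.make_color_rule_segmenter(
            ce.ColorRule(lo=(150, 130, 40), hi=(255, 235, 160))
        )
        (series,) = ce.build_series(entries, seg, size=192, tile=64)
        assert series.coverage == pytest.approx(truth, abs=0.02)

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            ce.build_series(
                [("p", -1.0, self._flat_image(0))], self._threshold_segmenter,
                size=32, tile=16,
            )
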
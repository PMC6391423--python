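"""Simulator: growth bookkeeping, telegraph statistics, calibration series."""

import math

import numpy as np
import pytest

from microhet import (ColonyConfig, ConfigurationError, ExpressionParams,
                      generate_calibration_series, simulate_colony)
from microhet.simulate import calibration_points


def _det_config(**kw):
    base = dict(n_initial_cells=1, doubling_time=30.0, total_duration=120.0,
                frame_interval=6.0, deterministic_growth=True, rng_seed=0)
    base.update(kw)
    return ColonyConfig(**base)


CONSTITUTIVE = ExpressionParams(model="constitutive", synthesis_rate_on=1.0)


class TestGrowth:
    def test_deterministic_doubling_gives_sixteen_cells(self):
        # one cell, four doubling times -> 2^4 cells
        gt = simulate_colony(_det_config(), CONSTITUTIVE)
        assert len(gt.frames[-1]) == 16

    def test_cell_count_non_decreasing(self):
        cfg = ColonyConfig(total_duration=180.0, rng_seed=3)
        gt = simulate_colony(cfg, CONSTITUTIVE)
        counts = gt.cell_counts()
        assert (np.diff(counts) >= 0).all()

    def test_total_length_tracks_exponential_growth(self):
        gt = simulate_colony(_det_config(total_duration=150.0), CONSTITUTIVE)
        t = np.array(gt.times)
        total = np.array([gt.total_length(i) for i in range(len(gt))])
        expected = total[0] * 2.0 ** (t / 30.0)
        assert np.all(np.abs(total / expected - 1) < 0.05)

    def test_growth_stops_at_stationary_onset(self):
        cfg = _det_config(total_duration=180.0, stationary_onset=90.0)
        gt = simulate_colony(cfg, CONSTITUTIVE)
        i90 = gt.frame_index_at(90.0)
        assert gt.total_length(len(gt) - 1) == pytest.approx(gt.total_length(i90))

    def test_lineage_traces_to_initial_cells(self):
        cfg = ColonyConfig(n_initial_cells=2, total_duration=150.0, rng_seed=7)
        gt = simulate_colony(cfg, CONSTITUTIVE)
        parents = {}
        for frame in gt.frames:
            for c in frame:
                parents[c.cell_id] = c.parent_id
        for cid in parents:
            seen = set()
            while parents[cid] != -1:
                assert cid not in seen, "lineage cycle"
                seen.add(cid)
                cid = parents[cid]
            assert cid < 2  # initial cells have ids 0..n_initial-1

    def test_invalid_config_raises(self):
        with pytest.raises(ConfigurationError):
            simulate_colony(ColonyConfig(doubling_time=-1.0), CONSTITUTIVE)
        with pytest.raises(ConfigurationError):
            simulate_colony(ColonyConfig(birth_length=6.0, division_length=5.0),
                            CONSTITUTIVE)

    def test_arena_overflow_stops_with_warning(self):
        cfg = ColonyConfig(total_duration=300.0, arena_size=12.0, rng_seed=1)
        gt = simulate_colony(cfg, CONSTITUTIVE)
        assert gt.warnings and "arena" in gt.warnings[0]
        assert gt.times[-1] < 300.0


class TestOverlap:
    def test_pairwise_overlap_below_ten_percent_of_smaller_area(self):
        from microhet.render import rasterize_cells
        cfg = ColonyConfig(total_duration=180.0, stationary_cell_cap=40,
                           rng_seed=11)
        gt = simulate_colony(cfg, CONSTITUTIVE)
        cells = gt.frames[-1]
        shape = (384, 384)
        areas = []
        masks = []
        for c in cells:
            lab, _ = rasterize_cells([c], shape, cfg.pixel_size)
            m = lab > 0
            masks.append(m)
            areas.append(m.sum())
        worst = 0.0
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                inter = np.logical_and(masks[i], masks[j]).sum()
                if inter:
                    worst = max(worst, inter / min(areas[i], areas[j]))
        assert worst <= 0.10

    def test_same_seed_bit_identical_series(self):
        cfg = ColonyConfig(total_duration=120.0, rng_seed=5)
        expr = ExpressionParams(model="telegraph", k_on=0.05, k_off=0.05,
                                synthesis_rate_on=2.0)
        a = simulate_colony(cfg, expr)
        b = simulate_colony(cfg, expr)
        assert a.times == b.times
        for fa, fb in zip(a.frames, b.frames):
            assert [vars(c) for c in fa] == [vars(c) for c in fb]


class TestExpression:
    def test_constitutive_no_extrinsic_noise_is_homogeneous(self):
        cfg = ColonyConfig(total_duration=240.0, stationary_cell_cap=50,
                           rng_seed=2)
        expr = ExpressionParams(model="constitutive", synthesis_rate_on=2.0)
        gt = simulate_colony(cfg, expr)
        for i in range(1, len(gt)):
            cv = gt.concentration_cv(i)
            assert cv <= 0.05

    def test_absorbing_on_state_with_zero_k_off(self):
        cfg = ColonyConfig(total_duration=300.0, rng_seed=4)
        expr = ExpressionParams(model="telegraph", k_on=0.2, k_off=0.0,
                                synthesis_rate_on=2.0)
        gt = simulate_colony(cfg, expr)
        # once every lineage has switched ON, all cells stay ON
        all_on = [all(c.promoter_state for c in f) for f in gt.frames]
        first = all_on.index(True)
        assert all(all_on[first:])

    def test_telegraph_stationary_on_fraction(self):
        # analytic stationary occupancy k_on/(k_on+k_off) = 0.5
        k = 0.1
        fractions = []
        for seed in range(10):
            cfg = ColonyConfig(n_initial_cells=8, total_duration=180.0,
                               stationary_cell_cap=500, rng_seed=seed)
            expr = ExpressionParams(model="telegraph", k_on=k, k_off=k,
                                    synthesis_rate_on=1.0)
            gt = simulate_colony(cfg, expr)
            states = [c.promoter_state for c in gt.frames[-1]]
            fractions.append(np.mean(states))
        mc_se = np.std(fractions, ddof=1) / math.sqrt(len(fractions))
        assert abs(np.mean(fractions) - 0.5) < 3 * max(mc_se, 1e-3)

    def test_dilution_balances_synthesis_at_steady_state(self):
        # constitutive steady state: conc -> synthesis / growth rate
        cfg = _det_config(total_duration=300.0)
        expr = ExpressionParams(model="constitutive", synthesis_rate_on=2.0)
        gt = simulate_colony(cfg, expr)
        lam = math.log(2) / 30.0
        conc = gt.concentrations(len(gt) - 1)
        assert conc == pytest.approx(2.0 / lam, rel=1e-6)


class TestCalibrationSeries:
    def test_zero_noise_levels_are_exact(self):
        levels = generate_calibration_series((50, 100, 200, 400), 0.0, 0.0, 50)
        for lv in levels:
            assert np.all(lv.values == lv.target_mean)
            assert lv.sample_sd() == 0.0

    def test_output_sorted_by_ascending_mean(self):
        levels = generate_calibration_series((400, 50, 200, 100), 0.05, 1.0, 40)
        means = [lv.target_mean for lv in levels]
        assert means == sorted(means)

    def test_slope_recovery_within_ten_percent(self):
        slopes = []
        for seed in range(10):
            levels = generate_calibration_series((50, 100, 200, 400), 0.1, 5.0,
                                                 1000, rng_seed=seed)
            pts = np.array(calibration_points(levels))
            slope = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]
            slopes.append(slope)
        assert abs(np.mean(slopes) - 0.1) < 0.01

    @pytest.mark.parametrize("means,slope,intercept,n", [
        ((50, 100, 200), 0.1, 5.0, 100),        # only 3 levels
        ((50, 100, 200, 200), 0.1, 5.0, 100),   # duplicate level
        ((50, 100, 200, 400), 0.1, 5.0, 10),    # too few cells
        ((50, 100, 200, 400), -0.2, 0.0, 100),  # negative implied SD
    ])
    def test_invalid_series_config_raises(self, means, slope, intercept, n):
        with pytest.raises(ConfigurationError):
            generate_calibration_series(means, slope, intercept, n)
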
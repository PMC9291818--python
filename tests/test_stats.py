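"""Breakpoint regression, model selection, Spearman, line scans, root sides."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isopixel import (
    RootSystemConfig,
    fit_segmented,
    fungal_cw_coupling,
    generate_root_system_table,
    line_scan_profile,
    root_side_analysis,
    select_model,
    simulate_roi_coupling,
    spearman_correlation,
)
from isopixel.stats import grid_search_breakpoint


def kinked(n=50, bp=1.5, a_low=2.0, a_high=0.5, b0=0.2, x_max=3.0):
    x = np.linspace(0.0, x_max, n)
    y = b0 + a_low * x + (a_high - a_low) * np.maximum(0.0, x - bp)
    return x, y


class TestSegmentedFit:
    def test_noiseless_kink_recovered_exactly(self):
        x, y = kinked()
        fit = fit_segmented(x, y, n_boot=0)
        assert fit.segmented
        assert fit.breakpoint == pytest.approx(1.5, abs=1e-6)
        assert fit.slope_low == pytest.approx(2.0, abs=1e-6)
        assert fit.slope_high == pytest.approx(0.5, abs=1e-6)
        assert fit.intercept == pytest.approx(0.2, abs=1e-6)
        assert fit.predict(np.array([1.5 - 1e-9]))[0] == \
            pytest.approx(fit.predict(np.array([1.5 + 1e-9]))[0], abs=1e-6)

    def test_exact_line_falls_back_to_linear(self):
        x = np.linspace(0, 3, 40)
        fit = fit_segmented(x, 1.0 * x, n_boot=0)
        assert not fit.segmented
        assert np.isnan(fit.breakpoint)
        assert fit.slope_low == pytest.approx(1.0, abs=1e-9)

    def test_noisy_line_falls_back_to_linear(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 3, 80)
        y = 0.5 + 1.2 * x + rng.normal(0, 0.3, 80)
        fit = fit_segmented(x, y, n_boot=0)
        assert not fit.segmented
        assert fit.p_existence > 0.05

    def test_iterative_refinement_matches_grid_oracle(self):
        # on noiseless kinks the refined fit equals exhaustive search
        rng = np.random.default_rng(8)
        for bp_true in (0.7, 1.2, 2.2):
            x = np.sort(rng.uniform(0, 3, 120))
            y = 0.1 + 3.0 * x + (0.4 - 3.0) * np.maximum(0, x - bp_true)
            fit = fit_segmented(x, y, n_boot=0)
            dense = np.linspace(*np.quantile(x, [0.05, 0.95]), 20001)
            bp_grid, _ = grid_search_breakpoint(x, y, dense)
            assert fit.breakpoint == pytest.approx(bp_true, abs=1e-6)
            assert fit.breakpoint == pytest.approx(bp_grid, abs=2e-4)

    def test_segmented_rss_never_exceeds_linear(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.uniform(0, 4, 60)
            y = rng.normal(0, 1, 60) + 0.5 * x
            fit = fit_segmented(x, y, n_boot=0, force_segmented=True)
            lin = sps.linregress(x, y)
            lin_rss = np.sum((y - lin.intercept - lin.slope * x) ** 2)
            assert fit.rss <= lin_rss + 1e-9

    def test_bootstrap_se_reproducible(self):
        x, y = simulate_roi_coupling(fungal_cw_coupling(), n=150, r2=0.65, seed=4)
        f1 = fit_segmented(x, y, n_boot=99, seed=42)
        f2 = fit_segmented(x, y, n_boot=99, seed=42)
        assert f1.se_breakpoint == f2.se_breakpoint
        assert f1.se_breakpoint > 0

    def test_reference_generator_recovery(self):
        # median breakpoint over seeded replicates from the fungal cell-wall
        # coupling model stays within 2 reported SEs (0.19) of 1.93
        bps = []
        for seed in range(1, 41):
            x, y = simulate_roi_coupling(fungal_cw_coupling(), n=1118, r2=0.65, seed=seed)
            bps.append(fit_segmented(x, y, n_boot=0, force_segmented=True).breakpoint)
        assert np.median(bps) == pytest.approx(1.93, abs=0.19)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            fit_segmented(np.arange(5.0), np.arange(5.0), n_boot=0)
        with pytest.raises(ValueError, match="distinct"):
            fit_segmented(np.array([1.0, 2.0] * 5), np.arange(10.0), n_boot=0)


class TestModelSelection:
    def test_straight_line_selects_linear(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 4, 500)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.2, 500)
        res = select_model(x, y, criterion="BIC")
        assert res.selected == "linear"

    def test_log_saturation_selects_log_x(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.05, 5, 120)
            y = 1.0 + 2.0 * np.log(x) + rng.normal(0, 0.25, 120)
            res = select_model(x, y, criterion="AIC")
            hits += res.selected == "log-x"
        assert hits >= 95

    def test_pronounced_kink_selects_segmented(self):
        x, y = simulate_roi_coupling(fungal_cw_coupling(), n=600, r2=0.8, seed=9)
        res = select_model(x, y, criterion="AIC")
        assert res.selected == "segmented"

    def test_log_candidates_excluded_for_nonpositive_data(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)  # contains negatives
        y = 2 * x + rng.normal(0, 0.1, 50)
        res = select_model(x, y)
        notes = dict(zip(res.table.model, res.table.note))
        assert "non-positive x" in notes["log-x"]

    def test_jacobian_correction_reported_both_ways(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.5, 4, 100)
        y = np.exp(0.2 + 0.3 * x + rng.normal(0, 0.1, 100))
        res = select_model(x, y)
        row = res.table[res.table.model == "log-y"].iloc[0]
        assert row["aic"] != row["aic_uncorrected"]


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 5, 9])
        r, p = spearman_correlation(x, x**3)
        assert r == pytest.approx(1.0)

    def test_worked_example_exact(self):
        # d^2 = (1,1,1,1): r_s = 1 - 6*4/(4*15) = 0.6
        r, p = spearman_correlation(np.array([1, 2, 3, 4]), np.array([2, 1, 4, 3]))
        assert r == pytest.approx(0.6)
        # exact permutation p over all 24 orderings
        count = sum(1 for perm in itertools.permutations([2, 1, 4, 3])
                    if abs(np.corrcoef(sps.rankdata([1, 2, 3, 4]),
                                       sps.rankdata(perm))[0, 1]) >= 0.6 - 1e-12)
        assert p == pytest.approx(count / 24)

    def test_matches_brute_force_on_random_vectors(self):
        # rank-then-Pearson oracle, 1000 small random vectors
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(3, 15))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            r, _ = spearman_correlation(x, y, p_method="asymptotic")
            brute = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert r == pytest.approx(brute, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.1, 5, 30)
        y = rng.uniform(0.1, 5, 30)
        r0, _ = spearman_correlation(x, y)
        r1, _ = spearman_correlation(np.log(x), y**3)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation(np.ones(5), np.arange(5.0))


class TestLineScan:
    def test_constant_map(self):
        img = np.full((20, 20), 7.5)
        prof = line_scan_profile(img, np.array([[2, 2], [2, 14]]), bin_px=3)
        assert (prof.value == 7.5).all()

    def test_nine_pixel_line_three_bins(self):
        img = np.arange(100, dtype=float).reshape(10, 10)
        prof = line_scan_profile(img, np.array([[5, 0], [5, 8]]), bin_px=3)
        assert len(prof) == 3
        assert prof.n_px.tolist() == [3, 3, 3]
        np.testing.assert_allclose(prof.value, [51.0, 54.0, 57.0])

    def test_linear_ramp_recovered_at_bin_centres(self):
        img = np.tile(np.arange(30, dtype=float), (5, 1))
        prof = line_scan_profile(img, np.array([[2, 0], [2, 29]]), bin_px=3,
                                 pixel_size_um=0.5)
        np.testing.assert_allclose(prof.value, np.arange(1, 30, 3))
        np.testing.assert_allclose(prof.distance_um, np.arange(1, 30, 3) * 0.5)

    def test_polyline_outside_image_rejected(self):
        with pytest.raises(ValueError, match="exits"):
            line_scan_profile(np.zeros((5, 5)), np.array([[0, 0], [0, 9]]))


class TestRootSideAnalysis:
    @staticmethod
    def records(masses, ape13, ape15, side="amended"):
        return pd.DataFrame({
            "side": [side] * len(masses), "kind": ["segment"] * len(masses),
            "ape13c": ape13, "ape15n": ape15, "mass_mg": masses,
        })

    def test_equal_masses_give_arithmetic_mean(self):
        rec = self.records([2.0, 2.0, 2.0], [0.1, 0.2, 0.3], [0.0, 0.1, 0.2])
        res = root_side_analysis(rec)["amended"]
        assert res.weighted_mean_ape13c == pytest.approx(0.2)
        assert res.weighted_mean_ape15n == pytest.approx(0.1)

    def test_mass_weighting_hand_example(self):
        rec = self.records([1.0, 3.0], [1.0, 1.0], [0.4, 0.0])
        res = root_side_analysis(rec)["amended"]
        assert res.weighted_mean_ape15n == pytest.approx(0.1)

    def test_unamended_slope_recovery(self):
        # mean recovered OLS slope over 100 seeded tables within 10% of 0.029
        slopes = []
        for seed in range(1, 101):
            tab = generate_root_system_table(RootSystemConfig(seed=seed))
            slopes.append(root_side_analysis(tab)["unamended"].slope)
        assert np.mean(slopes) == pytest.approx(0.029, rel=0.10)

    def test_single_segment_side_has_no_regression(self):
        rec = pd.concat([
            self.records([1.0, 2.0, 1.5], [0.1, 0.4, 0.9], [0.0, 0.1, 0.2]),
            self.records([1.0], [0.5], [0.01], side="unamended"),
        ])
        res = root_side_analysis(rec)
        assert res["amended"].regression_available
        assert not res["unamended"].regression_available
        assert np.isnan(res["unamended"].slope)
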
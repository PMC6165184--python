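"""Estimator correctness against independent oracles and invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from mrkit import (
    ConfigError,
    EstimationError,
    HarmonizedInstrument,
    InstrumentSet,
    cochran_q,
    forest_table,
    ivw,
    leave_one_out,
    mr_egger,
    rescale,
    results_to_frame,
    wald_ratio,
    weighted_median,
)
from conftest import random_instrument_set


def make_set(ratios, beta_exp=0.05, se_out=0.02, se_exp=0.005, sd_scale=0.33):
    """Instruments engineered to have the given Wald ratios, equal weights."""
    return InstrumentSet(
        "engineered",
        sd_scale,
        tuple(
            HarmonizedInstrument(f"rs{i}", beta_exp, se_exp,
                                 r * beta_exp, se_out)
            for i, r in enumerate(ratios)
        ),
    )


# ---------------------------------------------------------------------------
# Wald ratio

class TestWaldRatio:
    @pytest.mark.parametrize(
        "beta_exp, se_exp, beta_out, se_out, ratio",
        [
            (0.07, 0.003, 0.028, 0.019, 0.4),        # CYP24A1 PTH instrument
            (0.03, 0.004, -0.032, 0.022, -32 / 30),  # the only negative PTH ratio
        ],
    )
    def test_table_examples(self, beta_exp, se_exp, beta_out, se_out, ratio):
        inst = HarmonizedInstrument("rs", beta_exp, se_exp, beta_out, se_out)
        res = wald_ratio(inst)
        assert res.estimate == pytest.approx(ratio)
        assert res.se == pytest.approx(se_out / abs(beta_exp))

    def test_zero_outcome_beta_gives_p_one(self):
        res = wald_ratio(HarmonizedInstrument("rs", 0.05, 0.01, 0.0, 0.02))
        assert res.estimate == 0.0 and res.pvalue == 1.0

    def test_zero_exposure_beta_undefined(self):
        with pytest.raises(EstimationError, match="undefined"):
            wald_ratio(HarmonizedInstrument("rs", 0.0, 0.01, 0.01, 0.02))


# ---------------------------------------------------------------------------
# IVW

def wls_origin_oracle(iset):
    """Weighted least squares of beta_out on beta_exp through the origin,
    via statsmodels — independent of the ratio-pooling implementation."""
    import statsmodels.api as sm

    bx, _, by, sy = map(np.asarray, iset.arrays())
    w = 1.0 / np.asarray(sy) ** 2
    fit = sm.WLS(by, bx[:, None], weights=w).fit()
    est = fit.params[0]
    # fixed-effect SE: undo statsmodels' estimated residual scale
    se = fit.bse[0] / np.sqrt(fit.scale)
    return est * iset.sd_scale, se * iset.sd_scale


class TestIvw:
    @pytest.mark.parametrize("seed, n", [(1, 2), (2, 6), (3, 6), (4, 11)])
    def test_matches_wls_through_origin_oracle(self, seed, n):
        iset = random_instrument_set(seed, n)
        res = ivw(iset)
        est, se = wls_origin_oracle(iset)
        assert res.estimate == pytest.approx(est, rel=1e-12)
        assert res.se == pytest.approx(se, rel=1e-12)

    def test_single_instrument_equals_rescaled_wald(self):
        inst = HarmonizedInstrument("rs", 0.07, 0.003, 0.028, 0.019)
        iset = InstrumentSet("x", 0.33, (inst,))
        pooled = ivw(iset)
        single = rescale(wald_ratio(inst), 0.33)
        assert pooled.estimate == pytest.approx(single.estimate, rel=1e-15)
        assert pooled.se == pytest.approx(single.se, rel=1e-15)

    def test_random_effects_inflates_se_only_under_heterogeneity(self):
        homogeneous = make_set([0.5, 0.5, 0.5])
        assert ivw(homogeneous, "random_multiplicative").se == \
            ivw(homogeneous, "fixed").se
        heterogeneous = random_instrument_set(5, 8)
        fixed = ivw(heterogeneous, "fixed")
        rand = ivw(heterogeneous, "random_multiplicative")
        assert rand.se >= fixed.se
        assert rand.estimate == fixed.estimate

    def test_sign_flip_of_one_snp_leaves_ivw_invariant(self):
        iset = random_instrument_set(6, 5)
        inst = iset.instruments[2]
        # re-orienting one SNP flips both betas; beta_exp >= 0 is an
        # invariant of the container, so compare via raw arithmetic
        bx, _, by, sy = map(np.asarray, iset.arrays())
        r, w = by / bx, (bx / sy) ** 2
        est = np.sum(w * r) / np.sum(w)
        bx2, by2 = bx.copy(), by.copy()
        bx2[2], by2[2] = -bx2[2], -by2[2]
        est2 = np.sum((bx2 / sy) ** 2 * (by2 / bx2)) / np.sum((bx2 / sy) ** 2)
        assert est2 == pytest.approx(est, rel=1e-15)

    def test_adding_instrument_at_estimate_shrinks_se_only(self):
        iset = random_instrument_set(7, 6)
        res = ivw(iset)
        theta_ln = res.estimate / iset.sd_scale
        extra = HarmonizedInstrument("rs_new", 0.05, 0.005,
                                     theta_ln * 0.05, 0.02)
        bigger = InstrumentSet(iset.exposure_name, iset.sd_scale,
                               iset.instruments + (extra,))
        res2 = ivw(bigger)
        assert res2.estimate == pytest.approx(res.estimate, rel=1e-12)
        assert res2.se < res.se

    def test_zero_exposure_beta_identifies_snp(self):
        iset = InstrumentSet("x", 0.33, (
            HarmonizedInstrument("rs_ok", 0.05, 0.01, 0.01, 0.02),
            HarmonizedInstrument("rs_zero", 0.0, 0.01, 0.01, 0.02),
        ))
        with pytest.raises(EstimationError, match="rs_zero"):
            ivw(iset)

    def test_random_mode_needs_two_instruments(self):
        iset = InstrumentSet("x", 0.33, (
            HarmonizedInstrument("rs", 0.05, 0.01, 0.01, 0.02),))
        with pytest.raises(EstimationError):
            ivw(iset, mode="random_multiplicative")

    def test_rescaling_order_is_irrelevant(self):
        """Scaling per SD before pooling equals scaling the pooled result."""
        iset = random_instrument_set(8, 5, sd_scale=0.33)
        pre_scaled = InstrumentSet(
            "pre", 1.0,
            tuple(
                HarmonizedInstrument(i.rsid, i.beta_exp / 0.33,
                                     i.se_exp / 0.33, i.beta_out, i.se_out)
                for i in iset
            ),
        )
        assert ivw(pre_scaled).estimate == pytest.approx(
            ivw(iset).estimate, rel=1e-12)
        assert ivw(pre_scaled).se == pytest.approx(ivw(iset).se, rel=1e-12)


# ---------------------------------------------------------------------------
# Weighted median

def grid_quantile_oracle(ratios, weights, n_grid=10**6):
    """Evaluate the interpolated weighted-quantile function on a dense grid
    and read off the value nearest s = 0.5."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    s = (np.cumsum(w) - w / 2) / np.sum(w)
    s_grid = np.linspace(0.0, 1.0, n_grid)
    values = np.interp(s_grid, s, r)
    return values[np.argmin(np.abs(s_grid - 0.5))]


class TestWeightedMedian:
    def test_equal_weights_pick_middle_ratio(self):
        iset = make_set([1.0, 2.0, 9.0])
        res = weighted_median(iset, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(2.0 * 0.33, rel=1e-12)

    def test_equal_weights_match_unweighted_median_even_n(self):
        iset = make_set([1.0, 2.0, 5.0, 9.0])
        res = weighted_median(iset, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(np.median([1, 2, 5, 9]) * 0.33)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_grid_quantile_oracle(self, seed):
        iset = random_instrument_set(seed, 5)
        bx, _, by, sy = map(np.asarray, iset.arrays())
        r, w = by / bx, (bx / sy) ** 2
        oracle = grid_quantile_oracle(r, w)
        res = weighted_median(iset, n_boot=50, seed=0)
        tol = (r.max() - r.min()) / 1e5
        assert abs(res.estimate / 0.33 - oracle) <= tol

    def test_estimate_within_ratio_range(self):
        iset = random_instrument_set(14, 9)
        bx, _, by, sy = map(np.asarray, iset.arrays())
        r = by / bx
        res = weighted_median(iset, n_boot=50, seed=0)
        assert r.min() * 0.33 <= res.estimate <= r.max() * 0.33

    def test_bootstrap_is_deterministic_given_seed(self, pth_set):
        a = weighted_median(pth_set, n_boot=500, seed=99)
        b = weighted_median(pth_set, n_boot=500, seed=99)
        assert a == b
        c = weighted_median(pth_set, n_boot=500, seed=100)
        assert c.se != a.se

    def test_preconditions(self):
        iset = make_set([1.0, 2.0])
        with pytest.raises(EstimationError, match="3 instruments"):
            weighted_median(iset)
        with pytest.raises(EstimationError, match="n_boot"):
            weighted_median(make_set([1.0, 2.0, 3.0]), n_boot=0)


# ---------------------------------------------------------------------------
# MR-Egger

def egger_normal_equations_oracle(iset):
    """Hand-coded weighted normal equations for intercept + slope."""
    bx, _, by, sy = map(np.asarray, iset.arrays())
    w = 1.0 / np.asarray(sy) ** 2
    sw, swx = w.sum(), (w * bx).sum()
    swxx, swy, swxy = (w * bx * bx).sum(), (w * by).sum(), (w * bx * by).sum()
    det = sw * swxx - swx**2
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = by - intercept - slope * bx
    rse2 = (w * resid**2).sum() / (len(bx) - 2)
    infl = max(1.0, math.sqrt(rse2))
    se_intercept = math.sqrt(swxx / det) * infl
    se_slope = math.sqrt(sw / det) * infl
    return intercept, slope, se_intercept, se_slope


class TestMrEgger:
    @pytest.mark.parametrize("seed, n", [(21, 3), (22, 7), (23, 12)])
    def test_matches_normal_equations_oracle(self, seed, n):
        iset = random_instrument_set(seed, n)
        res = mr_egger(iset)
        b0, b1, se0, se1 = egger_normal_equations_oracle(iset)
        assert res.intercept.estimate == pytest.approx(b0, rel=1e-12)
        assert res.slope.estimate == pytest.approx(b1 * 0.33, rel=1e-12)
        assert res.intercept.se == pytest.approx(se0, rel=1e-12)
        assert res.slope.se == pytest.approx(se1 * 0.33, rel=1e-12)

    def test_perfect_line_through_origin(self):
        c = -0.8
        iset = InstrumentSet("x", 0.33, tuple(
            HarmonizedInstrument(f"rs{i}", bx, 0.005, c * bx, 0.02)
            for i, bx in enumerate([0.02, 0.05, 0.08, 0.1])
        ))
        res = mr_egger(iset)
        assert res.intercept.estimate == pytest.approx(0.0, abs=1e-15)
        assert res.slope.estimate == pytest.approx(c * 0.33, rel=1e-12)

    def test_intercept_not_rescaled_but_slope_is(self):
        iset = random_instrument_set(24, 6, sd_scale=0.33)
        unscaled = InstrumentSet("u", 1.0, iset.instruments)
        res_s, res_u = mr_egger(iset), mr_egger(unscaled)
        assert res_s.intercept.estimate == res_u.intercept.estimate
        assert res_s.slope.estimate == pytest.approx(
            0.33 * res_u.slope.estimate, rel=1e-15)

    def test_orientation_flip_changes_intercept(self):
        """The Egger intercept depends on instrument orientation (unlike
        IVW): re-orienting a SNP moves its point to (-bx, -by), which is
        not a reflection through the regression line."""
        bx = np.array([0.02, 0.04, 0.06, 0.09])
        by = np.array([0.01, -0.01, 0.03, 0.02])
        sy = np.full(4, 0.02)

        def intercept(bxv, byv):
            w = 1 / sy**2
            x = np.column_stack([np.ones(4), bxv])
            coef = np.linalg.solve(x.T @ (x * w[:, None]), x.T @ (w * byv))
            return coef[0]

        flipped_bx, flipped_by = bx.copy(), by.copy()
        flipped_bx[0], flipped_by[0] = -bx[0], -by[0]
        assert not np.isclose(intercept(bx, by),
                              intercept(flipped_bx, flipped_by))

    def test_t_inference_option_widens_p(self):
        iset = random_instrument_set(25, 4)
        normal = mr_egger(iset, dist="normal")
        student = mr_egger(iset, dist="t")
        assert student.slope.pvalue > normal.slope.pvalue
        assert student.slope.estimate == normal.slope.estimate

    def test_preconditions(self):
        with pytest.raises(EstimationError, match="3 instruments"):
            mr_egger(make_set([1.0, 2.0]))
        collinear = InstrumentSet("x", 0.33, tuple(
            HarmonizedInstrument(f"rs{i}", 0.05, 0.005, y, 0.02)
            for i, y in enumerate([0.01, 0.02, 0.03])
        ))
        with pytest.raises(EstimationError, match="variance"):
            mr_egger(collinear)


# ---------------------------------------------------------------------------
# Cochran's Q

class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        het = cochran_q(make_set([0.7, 0.7, 0.7, 0.7]))
        assert het.q == pytest.approx(0.0, abs=1e-22)
        assert het.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("seed, n", [(31, 2), (32, 7)])
    def test_direct_summation_oracle(self, seed, n):
        iset = random_instrument_set(seed, n)
        bx, _, by, sy = map(np.asarray, iset.arrays())
        r, w = by / bx, (bx / sy) ** 2
        theta = np.sum(w * r) / np.sum(w)
        q_oracle = sum(float(wj) * (float(rj) - theta) ** 2
                       for wj, rj in zip(w, r))
        het = cochran_q(iset)
        assert het.q == pytest.approx(q_oracle, rel=1e-12)
        assert het.df == n - 1
        assert het.pvalue == pytest.approx(stats.chi2.sf(q_oracle, n - 1))

    def test_q_is_invariant_under_sd_rescaling(self):
        iset = random_instrument_set(33, 6, sd_scale=0.33)
        other = InstrumentSet("o", 1.7, iset.instruments)
        assert cochran_q(iset).q == cochran_q(other).q

    def test_needs_two_instruments(self):
        with pytest.raises(EstimationError):
            cochran_q(make_set([1.0]))


# ---------------------------------------------------------------------------
# Leave-one-out and forest layout

class TestLeaveOneOutAndForest:
    def test_loo_equals_explicit_subsetting(self, vitd_set):
        results = leave_one_out(vitd_set)
        assert len(results) == 7
        for res in results:
            manual = ivw(vitd_set.drop(res.label))
            assert res.estimate == manual.estimate
            assert res.se == manual.se
            assert res.n_snps == 6

    def test_three_snp_set_pools_pairs(self):
        results = leave_one_out(make_set([0.1, 0.5, 0.9]))
        assert [r.n_snps for r in results] == [2, 2, 2]

    def test_loo_preconditions(self):
        with pytest.raises(EstimationError):
            leave_one_out(make_set([1.0, 2.0]))
        with pytest.raises(ConfigError):
            leave_one_out(make_set([1.0, 2.0, 3.0]), method="egger")

    def test_forest_row_counts(self, pth_set, vitd_set):
        pooled = [ivw(pth_set)]
        assert len(forest_table(pth_set, pooled).rows) == 6
        pooled3 = [ivw(vitd_set),
                   weighted_median(vitd_set, n_boot=50, seed=0),
                   mr_egger(vitd_set).slope]
        forest = forest_table(vitd_set, pooled3)
        assert len(forest.rows) == 10
        # per-SNP rows first, in instrument order, then the pooled methods
        assert [r.label for r in forest.rows[:7]] == list(vitd_set.rsids)
        assert [r.method for r in forest.rows[7:]] == \
            ["ivw_fixed", "weighted_median", "egger_slope"]

    def test_forest_snp_rows_are_per_sd_wald_ratios(self, vitd_set):
        forest = forest_table(vitd_set, [ivw(vitd_set)])
        row = next(r for r in forest.rows if r.label == "rs17216707")
        assert row.estimate == pytest.approx(-0.045 / 0.026 * 0.33)
        assert row.estimate < 0

    def test_forest_needs_pooled_rows(self, pth_set):
        with pytest.raises(ConfigError):
            forest_table(pth_set, [])


# ---------------------------------------------------------------------------
# Result views

class TestMrResult:
    def test_or_views_are_exp_of_log_fields(self, pth_set):
        res = ivw(pth_set)
        lo, hi = res.odds_ratio_ci()
        assert lo == math.exp(res.ci_low) and hi == math.exp(res.ci_high)
        assert lo <= res.odds_ratio() <= hi

    def test_rescale_preserves_z_and_p(self, pth_set):
        res = ivw(pth_set)
        scaled = rescale(res, 3.0)
        assert scaled.estimate / scaled.se == pytest.approx(
            res.estimate / res.se, rel=1e-15)
        assert scaled.pvalue == res.pvalue

    def test_results_frame_has_full_precision_columns(self, pth_set):
        frame = results_to_frame([ivw(pth_set)])
        assert frame.loc[0, "odds_ratio"] == ivw(pth_set).odds_ratio()
        assert set(frame.columns) >= {"method", "n_snps", "estimate", "se",
                                      "pvalue", "odds_ratio"}
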
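"""MR estimators, pleiotropy diagnostics and method selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

from cellmr.mr import (
    MethodChoice,
    _weighted_percentile,
    cochran_q,
    egger_intercept_test,
    heterogeneity,
    ivw,
    leave_one_out,
    mr_egger,
    mr_raps,
    presso_global,
    select_main_method,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from cellmr.simulate import SimMRConfig, simulate_mr_dataset
from cellmr.sumstats import InputError


def make_inst(bx, by, sx=0.005, sy=0.01):
    bx, by = np.atleast_1d(np.asarray(bx, float)), np.atleast_1d(np.asarray(by, float))
    k = len(bx)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(k)],
            "beta_exp": bx,
            "se_exp": np.broadcast_to(sx, k).astype(float),
            "beta_out": by,
            "se_out": np.broadcast_to(sy, k).astype(float),
        }
    )


class TestWaldRatio:
    def test_closed_form(self):
        est = wald_ratio(make_inst([0.1], [0.3], sy=0.05))
        assert est.beta == pytest.approx(3.0)
        assert est.se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        assert wald_ratio(make_inst([0.1], [0.0])).beta == 0.0

    def test_negative_exposure_flips_sign_only(self):
        pos = wald_ratio(make_inst([0.1], [0.3]))
        neg = wald_ratio(make_inst([-0.1], [0.3]))
        assert neg.beta == pytest.approx(-pos.beta)
        assert neg.se == pytest.approx(pos.se)

    def test_zero_exposure_rejected(self):
        with pytest.raises(InputError):
            wald_ratio(make_inst([0.0], [0.3]))


class TestIvw:
    def test_homogeneous_ratios_exact(self, toy_instruments):
        est, het = ivw(toy_instruments)
        assert est.beta == pytest.approx(0.5)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        # no heterogeneity: multiplicative scaling cannot shrink the SE
        w = 1 / toy_instruments["se_out"] ** 2
        se_fixed = 1 / np.sqrt(np.sum(w * toy_instruments["beta_exp"] ** 2))
        assert est.se == pytest.approx(se_fixed)

    def test_matches_wls_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        bx = rng.uniform(0.05, 0.2, 8)
        by = 0.4 * bx + rng.normal(0, 0.01, 8)
        sy = rng.uniform(0.005, 0.02, 8)
        inst = make_inst(bx, by, sy=sy)
        est, _ = ivw(inst)
        oracle = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(oracle.params[0], abs=1e-10)

    def test_duplicating_instruments_preserves_beta_scales_q(self):
        rng = np.random.default_rng(22)
        bx = rng.uniform(0.05, 0.2, 6)
        by = 0.4 * bx + rng.normal(0, 0.02, 6)
        single = make_inst(bx, by)
        double = make_inst(np.tile(bx, 2), np.tile(by, 2))
        est1, het1 = ivw(single)
        est2, het2 = ivw(double)
        assert est2.beta == pytest.approx(est1.beta, abs=1e-12)
        assert het2.q == pytest.approx(2 * het1.q, abs=1e-10)
        assert het2.q_df == 2 * len(bx) - 1

    def test_single_instrument_reduces_to_wald(self):
        inst = make_inst([0.1], [0.03])
        est, _ = ivw(inst)
        wald = wald_ratio(inst)
        assert est.beta == pytest.approx(wald.beta, abs=1e-15)
        assert est.se == pytest.approx(wald.se, abs=1e-15)


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        est, het = mr_egger(make_inst(bx, 0.5 * bx))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)
        assert het.q_prime == pytest.approx(0.0, abs=1e-15)

    def test_recovers_planted_intercept_and_slope(self):
        bx = np.linspace(0.05, 0.3, 10)
        by = 0.1 + 0.3 * bx
        est, _ = mr_egger(make_inst(bx, by))
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert est.intercept == pytest.approx(0.1, abs=1e-10)

    def test_matches_wls_oracle_with_noise(self):
        rng = np.random.default_rng(23)
        bx = rng.uniform(0.05, 0.3, 12)
        by = 0.05 + 0.4 * bx + rng.normal(0, 0.01, 12)
        sy = rng.uniform(0.005, 0.02, 12)
        est, _ = mr_egger(make_inst(bx, by, sy=sy))
        oracle = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert est.intercept == pytest.approx(oracle.params[0], abs=1e-10)
        assert est.beta == pytest.approx(oracle.params[1], abs=1e-10)

    def test_three_points_df_edge(self):
        bx = np.array([0.05, 0.1, 0.2])
        by = 0.02 + 0.3 * bx + np.array([0.001, -0.002, 0.001])
        _, het = mr_egger(make_inst(bx, by))
        assert het.q_prime_df == 1
        assert np.isfinite(het.q_prime_p)

    def test_requires_three_instruments(self):
        with pytest.raises(InputError):
            mr_egger(make_inst([0.1, 0.2], [0.03, 0.06]))


class TestWeightedMedian:
    def test_equal_weights_reduce_to_median(self):
        inst = make_inst([0.1, 0.1, 0.1], [0.1, 0.2, 0.9])
        est = weighted_median(inst, n_boot=50, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_matches_brute_force_percentile_oracle(self):
        rng = np.random.default_rng(24)
        for _ in range(5):
            k = int(rng.integers(3, 20))
            bx = rng.uniform(0.05, 0.3, k)
            by = rng.normal(0.3 * bx, 0.02)
            sy = rng.uniform(0.005, 0.02, k)
            inst = make_inst(bx, by, sy=sy)
            est = weighted_median(inst, n_boot=10, seed=0)
            ratios = by / bx
            weights = bx**2 / sy**2
            # brute-force weighted percentile: scan the cumulative-weight
            # midpoints and interpolate at 0.5
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order]
            cum = (np.cumsum(w) - 0.5 * w) / w.sum()
            expected = float(np.interp(0.5, cum, r))
            assert est.beta == pytest.approx(expected, abs=1e-10)

    def test_resistant_to_single_extreme_outlier(self):
        bx = np.full(10, 0.1)
        by = 0.03 * np.ones(10)
        by[-1] = 5.0
        est = weighted_median(make_inst(bx, by), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.3, abs=0.01)

    def test_majority_weight_snp_dominates(self):
        inst = make_inst([0.1, 0.1, 0.1], [0.1, 0.2, 0.03], sy=[0.05, 0.05, 0.001])
        est = weighted_median(inst, n_boot=10, seed=0)
        # midpoint convention: the dominant SNP's ratio up to interpolation
        assert est.beta == pytest.approx(0.3, abs=1e-2)


class TestWeightedMode:
    def test_identical_ratios_return_common_value(self):
        inst = make_inst([0.1, 0.2, 0.15], [0.05, 0.1, 0.075])
        est = weighted_mode(inst, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_majority_cluster_wins(self):
        bx = np.full(10, 0.1)
        ratios = np.array([0.3] * 7 + [1.5, 2.0, -1.0])
        est = weighted_mode(make_inst(bx, ratios * bx), n_boot=50, seed=2)
        assert est.beta == pytest.approx(0.3, abs=0.05)

    def test_heavier_weighted_cluster_center(self):
        bx = np.full(6, 0.1)
        ratios = np.array([0.3, 0.3, 0.3, 0.9, 0.9, 0.9])
        sy = np.array([0.002] * 3 + [0.02] * 3)  # first cluster heavily weighted
        est = weighted_mode(make_inst(bx, ratios * bx, sy=sy), n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.3, abs=0.05)


class TestMrRaps:
    def test_noiseless_recovery_with_zero_overdispersion(self):
        bx = np.linspace(0.05, 0.3, 10)
        inst = make_inst(bx, 0.3 * bx)
        est = mr_raps(inst)
        assert est.beta == pytest.approx(0.3, abs=1e-6)

    def test_reduces_to_profile_score_root_when_unrobust(self):
        """With squared loss (psi = identity) and tau^2 = 0 the estimating
        equation has an independently computable root."""
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.035, 0.055, 0.048])
        sx, sy = 0.01, 0.01

        def profile_score(beta):
            v = sy**2 + beta**2 * sx**2
            return np.sum((by - beta * bx) * bx / v)

        root = optimize.brentq(profile_score, -10, 10)
        est = mr_raps(make_inst(bx, by, sx=sx, sy=sy), overdispersion=False)
        # Huber psi is inactive when all standardized residuals are < 1.345
        v = sy**2 + est.beta**2 * sx**2
        t = np.abs(by - est.beta * bx) / np.sqrt(v)
        assert np.all(t < 1.345)
        assert est.beta == pytest.approx(root, abs=1e-8)

    def test_recovers_truth_under_balanced_pleiotropy(self):
        errs = []
        for seed in range(30):
            inst, truth = simulate_mr_dataset(
                SimMRConfig(k_iv=50, true_beta=0.3, pleiotropy="balanced",
                            tau=0.05, seed=seed)
            )
            est = mr_raps(inst)
            errs.append(est.beta - truth["true_beta"])
        errs = np.array(errs)
        assert abs(errs.mean()) < 2 * errs.std() / np.sqrt(len(errs)) + 0.01


class TestHeterogeneity:
    def test_homogeneous_q_zero_p_one(self, toy_instruments):
        het = cochran_q(toy_instruments)
        assert het.q == pytest.approx(0.0, abs=1e-18)
        assert het.q_p == pytest.approx(1.0)

    def test_q_dominates_q_prime(self):
        rng = np.random.default_rng(30)
        for _ in range(10):
            bx = rng.uniform(0.05, 0.3, 10)
            by = 0.02 + 0.3 * bx + rng.normal(0, 0.02, 10)
            het = heterogeneity(make_inst(bx, by))
            assert het.q >= het.q_prime - 1e-10

    def test_null_calibration(self):
        """Under homogeneity, Cochran's Q should reject at close to the
        nominal 5% rate."""
        rej = 0
        reps = 300
        for seed in range(reps):
            inst, _ = simulate_mr_dataset(
                SimMRConfig(k_iv=20, true_beta=0.3, pleiotropy="none", seed=seed)
            )
            het = cochran_q(inst)
            rej += het.q_p < 0.05
        assert 0.02 <= rej / reps <= 0.08


class TestEggerIntercept:
    def test_line_through_origin_not_significant(self):
        rng = np.random.default_rng(31)
        bx = rng.uniform(0.05, 0.3, 20)
        by = 0.3 * bx + rng.normal(0, 1e-6, 20)
        _, _, p = egger_intercept_test(make_inst(bx, by))
        assert p > 0.05

    def test_planted_directional_pleiotropy_detected(self):
        rng = np.random.default_rng(32)
        bx = rng.uniform(0.05, 0.3, 30)
        by = 0.1 + 0.3 * bx + rng.normal(0, 0.005, 30)
        intercept, _, p = egger_intercept_test(make_inst(bx, by))
        assert p < 0.05
        assert intercept == pytest.approx(0.1, abs=0.01)

    def test_intercept_sign_flips_with_outcome(self):
        rng = np.random.default_rng(33)
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.05 + 0.3 * bx + rng.normal(0, 0.01, 10)
        i1, _, _ = egger_intercept_test(make_inst(bx, by))
        i2, _, _ = egger_intercept_test(make_inst(bx, -by))
        assert i2 == pytest.approx(-i1, abs=1e-12)


class TestPresso:
    def test_deterministic_under_seed(self):
        inst, _ = simulate_mr_dataset(SimMRConfig(k_iv=10, seed=3))
        p1 = presso_global(inst, n_sim=200, seed=42).p_global
        p2 = presso_global(inst, n_sim=200, seed=42).p_global
        assert p1 == p2

    def test_p_has_monte_carlo_resolution(self):
        inst, _ = simulate_mr_dataset(SimMRConfig(k_iv=10, seed=3))
        res = presso_global(inst, n_sim=99, seed=0)
        assert res.p_global >= 1 / 100
        assert res.p_global <= 1.0

    def test_planted_pleiotropic_snp_detected(self):
        detected = 0
        for seed in range(20):
            inst, _ = simulate_mr_dataset(
                SimMRConfig(k_iv=20, pleiotropy="outlier", n_outliers=1,
                            outlier_size=10, seed=seed)
            )
            res = presso_global(inst, n_sim=200, seed=seed)
            detected += res.p_global <= 0.05
        assert detected >= 18

    def test_requires_four_instruments(self, toy_instruments):
        with pytest.raises(InputError):
            presso_global(toy_instruments)


class TestLeaveOneOut:
    def test_homogeneous_rows_all_equal_full_estimate(self, toy_instruments):
        full, _ = ivw(toy_instruments)
        table = leave_one_out(toy_instruments)
        assert np.allclose(table["beta"], full.beta)
        assert not table["flag"].any()

    def test_dominant_outlier_flagged(self):
        bx = np.full(6, 0.1)
        by = 0.03 * np.ones(6)
        by[0] = 0.4
        table = leave_one_out(make_inst(bx, by))
        # removing the outlier changes the estimate most
        deltas = (table["beta"] - ivw(make_inst(bx, by))[0].beta).abs()
        assert table.loc[deltas.idxmax(), "excluded_snp"] == "rs0"

    def test_row_bookkeeping(self, toy_instruments):
        table = leave_one_out(toy_instruments)
        assert len(table) == 3
        assert set(table["excluded_snp"]) == set(toy_instruments["snp"])


class TestMethodSelection:
    def test_single_instrument_uses_wald(self):
        choice = select_main_method(1, None, None, None, None)
        assert choice.chosen == "wald"

    def test_no_pleiotropy_uses_ivw(self):
        choice = select_main_method(10, 0.3, 0.3, 0.3, 0.5)
        assert choice.chosen == "ivw"

    def test_pleiotropy_with_clean_egger_uses_egger(self):
        choice = select_main_method(10, 0.3, 0.3, 0.01, 0.2)
        assert choice.chosen == "egger"

    def test_pleiotropy_with_bad_egger_uses_weighted_median(self):
        choice = select_main_method(10, 0.001, 0.3, 0.01, 0.01)
        assert choice.chosen == "wmedian"

    def test_missing_diagnostic_marks_incomplete(self):
        choice = select_main_method(3, 0.3, 0.3, None, 0.5)
        assert choice.chosen == "ivw"
        assert choice.incomplete

    def test_unresolvable_branch_raises(self):
        with pytest.raises(InputError):
            select_main_method(10, 0.01, 0.3, 0.3, None)


class TestEquivariance:
    @pytest.mark.parametrize("method", ["ivw", "egger", "wmedian", "wmode", "raps"])
    def test_simultaneous_sign_flip_invariance(self, method):
        """Flipping the allele orientation of any SNP (negating both its
        exposure and outcome effects) must not change any estimate."""
        rng = np.random.default_rng(40)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.3 * bx + rng.normal(0, 0.01, 8)
        flip = rng.choice([-1.0, 1.0], 8)
        a, b = make_inst(bx, by), make_inst(bx * flip, by * flip)
        fns = {
            "ivw": lambda t: ivw(t)[0],
            "egger": lambda t: mr_egger(t)[0],
            "wmedian": lambda t: weighted_median(t, n_boot=10, seed=0),
            "wmode": lambda t: weighted_mode(t, n_boot=10, seed=0),
            "raps": lambda t: mr_raps(t),
        }
        assert fns[method](a).beta == pytest.approx(fns[method](b).beta, abs=1e-6)


class TestCIs:
    def test_normal_theory_ci_brackets_beta(self):
        inst, _ = simulate_mr_dataset(SimMRConfig(k_iv=10, seed=7))
        est, _ = ivw(inst)
        assert est.ci_low <= est.beta <= est.ci_high
        assert est.ci_high - est.beta == pytest.approx(1.96 * est.se, rel=1e-3)
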
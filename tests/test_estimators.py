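"""Causal estimators: oracles, algebraic identities, robustness behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mrkit as mk
from mrkit.estimators import (
    EggerRegression,
    GRSEstimator,
    IVWEstimator,
    MedianEstimator,
    MRPresso,
    RAPSEstimator,
    _huber_rho,
    grs_summary,
    ratio_estimates,
)
from mrkit.types import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from conftest import random_instruments


def _inst(gammas, Gammas, se_g=None, se_G=None):
    J = len(gammas)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(J)],
            "gamma": gammas,
            "se_gamma": se_g if se_g is not None else [0.01] * J,
            "Gamma": Gammas,
            "se_Gamma": se_G if se_G is not None else [0.1] * J,
        }
    )


class TestRatioEstimates:
    def test_unit_exposure_effect(self):
        r = ratio_estimates(_inst([1.0], [0.3], se_G=[0.1]))[0]
        assert (r.wald_ratio, r.se_ratio) == (0.3, 0.1)

    def test_null_outcome(self):
        r = ratio_estimates(_inst([2.0], [0.0], se_G=[0.1]))[0]
        assert (r.wald_ratio, r.se_ratio) == (0.0, 0.05)

    def test_matches_elementwise_division(self, rng):
        X = random_instruments(rng, 10)
        rs = ratio_estimates(X)
        np.testing.assert_allclose(
            [r.wald_ratio for r in rs], X["Gamma"] / X["gamma"]
        )
        np.testing.assert_allclose(
            [r.se_ratio for r in rs], X["se_Gamma"] / np.abs(X["gamma"])
        )
        np.testing.assert_allclose([r.weight for r in rs],
                                   (np.abs(X["gamma"]) / X["se_Gamma"]) ** 2)

    def test_zero_exposure_effect_names_snp(self):
        with pytest.raises(DegenerateInstrumentError, match="rs1"):
            ratio_estimates(_inst([0.5, 0.0], [0.1, 0.1]))


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        m = IVWEstimator(model="fixed", allow_single=True).fit(_inst([2.0], [0.6], se_G=[0.2]))
        assert m.beta_ == pytest.approx(0.3)
        assert m.se_ == pytest.approx(0.1)

    def test_insufficient_without_override(self):
        with pytest.raises(InsufficientInstrumentsError):
            IVWEstimator().fit(_inst([2.0], [0.6]))

    def test_equal_weights_give_unweighted_mean(self):
        X = _inst([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], se_G=[0.1, 0.1, 0.1])
        assert IVWEstimator(model="fixed").fit(X).beta_ == pytest.approx(0.2)

    def test_matches_wls_through_origin_normal_equations(self, rng):
        X = random_instruments(rng, 25)
        m = IVWEstimator(model="fixed").fit(X)
        w = X["se_Gamma"].to_numpy() ** -2.0
        g, G = X["gamma"].to_numpy(), X["Gamma"].to_numpy()
        beta_oracle = np.sum(w * g * G) / np.sum(w * g * g)  # explicit normal equation
        se_oracle = np.sum(w * g * g) ** -0.5
        assert m.beta_ == pytest.approx(beta_oracle, rel=1e-12)
        assert m.fixed_se_ == pytest.approx(se_oracle, rel=1e-12)

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            X = random_instruments(rng, 12)
            fixed = IVWEstimator(model="fixed").fit(X)
            rand = IVWEstimator(model="random").fit(X)
            assert rand.se_ >= fixed.se_
            if fixed.q_ <= fixed.q_df_:
                assert rand.se_ == pytest.approx(fixed.se_)

    def test_auto_selects_random_iff_q_significant(self, rng):
        for _ in range(10):
            X = random_instruments(rng, 10)
            m = IVWEstimator(model="auto").fit(X)
            assert m.model_used_ == ("random" if m.q_pvalue_ < 0.05 else "fixed")


class TestMedian:
    def test_simple_is_middle_order_statistic(self):
        X = _inst([1.0, 1.0, 1.0], [0.1, 0.2, 0.9])
        m = MedianEstimator(weighted=False, n_boot=200, random_state=0).fit(X)
        assert m.beta_ == pytest.approx(0.2)

    def test_equal_weights_reduce_to_simple(self, rng):
        for J in (4, 5, 9):
            ratios = rng.normal(0.2, 0.3, J)
            X = _inst(np.ones(J), ratios, se_G=np.full(J, 0.1))
            w_est = MedianEstimator(weighted=True, n_boot=100, random_state=1).fit(X)
            s_est = MedianEstimator(weighted=False, n_boot=100, random_state=1).fit(X)
            assert w_est.beta_ == pytest.approx(s_est.beta_)
            assert s_est.beta_ == pytest.approx(np.median(ratios))

    def test_weighted_median_matches_cdf_grid_scan(self, rng):
        X = random_instruments(rng, 5)
        m = MedianEstimator(weighted=True, n_boot=100, random_state=0).fit(X)
        rs = ratio_estimates(X)
        b = np.array([r.wald_ratio for r in rs])
        w = np.array([r.weight for r in rs])
        order = np.argsort(b)
        b, w = b[order], w[order]
        p = (np.cumsum(w) - w / 2) / w.sum()
        # scan the piecewise-linear weighted CDF on a fine grid for the 0.5 crossing
        grid = np.linspace(b.min(), b.max(), 200_001)
        cdf = np.interp(grid, b, p)
        oracle = grid[np.argmin(np.abs(cdf - 0.5))]
        assert m.beta_ == pytest.approx(oracle, abs=1e-4)

    def test_bootstrap_reproducible(self, rng):
        X = random_instruments(rng, 8)
        e1 = MedianEstimator(weighted=True, n_boot=300, random_state=7).fit(X)
        e2 = MedianEstimator(weighted=True, n_boot=300, random_state=7).fit(X)
        assert (e1.beta_, e1.se_) == (e2.beta_, e2.se_)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            MedianEstimator().fit(_inst([1.0, 1.0], [0.1, 0.2]))


class TestEgger:
    def test_exact_line_through_origin(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        m = EggerRegression().fit(_inst(g, 0.5 * g))
        assert m.beta_ == pytest.approx(0.5, abs=1e-10)
        assert m.intercept_ == pytest.approx(0.0, abs=1e-10)
        assert m.rss_ == pytest.approx(0.0, abs=1e-18)

    def test_exact_affine_line(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        m = EggerRegression().fit(_inst(g, 0.5 * g + 0.02))
        assert m.intercept_ == pytest.approx(0.02, abs=1e-10)

    def test_matches_weighted_normal_equations(self, rng):
        X = random_instruments(rng, 15)
        m = EggerRegression().fit(X)
        g = X["gamma"].to_numpy()
        G = X["Gamma"].to_numpy()
        sG = X["se_Gamma"].to_numpy()
        s = np.where(g < 0, -1.0, 1.0)
        g, G = g * s, G * s
        w = sG**-2.0
        # explicit 2x2 weighted normal equations
        A = np.array([[np.sum(w), np.sum(w * g)], [np.sum(w * g), np.sum(w * g * g)]])
        rhs = np.array([np.sum(w * G), np.sum(w * g * G)])
        intercept, slope = np.linalg.solve(A, rhs)
        resid = G - intercept - slope * g
        rss = np.sum(w * resid**2)
        scale = max(1.0, np.sqrt(rss / (len(g) - 2)))
        cov_unit = np.linalg.inv(A)
        assert m.beta_ == pytest.approx(slope, rel=1e-10)
        assert m.intercept_ == pytest.approx(intercept, rel=1e-10)
        assert m.se_ == pytest.approx(scale * np.sqrt(cov_unit[1, 1]), rel=1e-10)
        assert m.intercept_se_ == pytest.approx(scale * np.sqrt(cov_unit[0, 0]), rel=1e-10)

    def test_pvalues_use_t_reference(self, rng):
        X = random_instruments(rng, 6)
        m = EggerRegression().fit(X)
        expected = 2 * stats.t.sf(abs(m.beta_ / m.se_), 4)
        assert m.pvalue_ == pytest.approx(expected)


class TestPresso:
    def test_empirical_p_floor(self):
        inst, _ = mk.simulate_instruments(mk.SimulationConfig(n_snps=10, alpha_true=0.2, seed=1))
        inst.loc[3, "Gamma"] += 50 * inst.loc[3, "se_Gamma"]
        m = MRPresso(n_sim=100, random_state=0).fit(inst)
        assert m.result_.global_p == pytest.approx(1 / 101)
        assert min(m.result_.outlier_pvalues.values()) >= 1 / 101

    def test_planted_outlier_flagged_and_corrected_closer(self):
        inst, _ = mk.simulate_instruments(mk.SimulationConfig(n_snps=15, alpha_true=0.2, seed=3))
        j = int(np.argmax((inst["gamma"] / inst["se_Gamma"]).abs()))
        inst.loc[j, "Gamma"] += 10 * inst.loc[j, "se_Gamma"]
        m = MRPresso(n_sim=1000, random_state=0).fit(inst)
        assert inst.loc[j, "SNP"] in m.result_.outlier_ids
        assert abs(m.corrected_estimate_.beta - 0.2) < abs(m.raw_estimate_.beta - 0.2)
        assert m.result_.distortion_p is not None

    def test_global_test_calibrated_without_pleiotropy(self):
        # no planted pleiotropy: the global test should rarely reject
        keep = 0
        for s in range(50):
            inst, _ = mk.simulate_instruments(
                mk.SimulationConfig(n_snps=20, alpha_true=0.2, seed=1000 + s)
            )
            m = MRPresso(n_sim=500, random_state=s).fit(inst)
            keep += m.result_.global_p > 0.05
        assert keep >= 45  # >= 90% of 50 repetitions

    def test_reproducible_given_seed(self):
        inst, _ = mk.simulate_instruments(mk.SimulationConfig(n_snps=12, alpha_true=0.1, seed=2))
        m1 = MRPresso(n_sim=200, random_state=9).fit(inst)
        m2 = MRPresso(n_sim=200, random_state=9).fit(inst)
        assert m1.result_.global_p == m2.result_.global_p
        assert m1.result_.outlier_pvalues == m2.result_.outlier_pvalues


class TestRaps:
    def test_exact_root_on_residual_free_data(self):
        g = np.array([0.1, 0.25, 0.3, 0.15])
        m = RAPSEstimator().fit(_inst(g, 0.37 * g))
        assert m.beta_ == pytest.approx(0.37, abs=1e-9)

    def test_agrees_with_ivw_without_pleiotropy(self):
        disagreements = 0
        for s in range(50):
            inst, _ = mk.simulate_instruments(
                mk.SimulationConfig(n_snps=25, alpha_true=0.3, seed=2000 + s)
            )
            r = RAPSEstimator().fit(inst)
            i = IVWEstimator(model="fixed").fit(inst)
            if abs(r.beta_ - i.beta_) > 2 * np.hypot(r.se_, i.se_):
                disagreements += 1
        assert disagreements == 0

    def test_root_matches_integrated_loss_grid_minimum(self, rng):
        X = random_instruments(rng, 12)
        m = RAPSEstimator().fit(X)
        g = X["gamma"].to_numpy()
        sg = X["se_gamma"].to_numpy()
        G = X["Gamma"].to_numpy()
        sG = X["se_Gamma"].to_numpy()

        def loss(beta):
            t = (G - beta * g) / np.sqrt(sG**2 + beta**2 * sg**2)
            return np.sum(_huber_rho(t, 1.345))

        grid = np.linspace(-2, 2, 40_001)
        oracle = grid[np.argmin([loss(b) for b in grid])]
        assert m.beta_ == pytest.approx(oracle, abs=1e-4)

    def test_overdispersion_absorbs_balanced_pleiotropy(self):
        inst, _ = mk.simulate_instruments(
            mk.SimulationConfig(
                n_snps=40, alpha_true=0.2, pleiotropy="balanced", pleiotropy_sd=0.05, seed=8
            )
        )
        plain = RAPSEstimator(overdispersion=False).fit(inst)
        over = RAPSEstimator(overdispersion=True).fit(inst)
        assert over.tau2_ > 0
        assert over.se_ > plain.se_  # acknowledging pleiotropy inflates uncertainty


class TestGRS:
    def test_single_variant_reduction(self):
        e = grs_summary([1.0], [0.3], [0.1])
        assert (e.beta, e.se) == (pytest.approx(0.3), pytest.approx(0.1))

    def test_identity_with_fixed_ivw(self, rng):
        for _ in range(20):
            X = random_instruments(rng, int(rng.integers(3, 40)))
            g_est = GRSEstimator().fit(X)
            i_est = IVWEstimator(model="fixed").fit(X)
            assert g_est.beta_ == pytest.approx(i_est.beta_, rel=1e-12)
            assert g_est.se_ == pytest.approx(i_est.se_, rel=1e-12)

    def test_degenerate_weights(self):
        with pytest.raises(mk.estimators.DegenerateWeightsError):
            grs_summary([0.0, 0.0], [0.1, 0.2], [0.1, 0.1])


class TestScaleEquivariance:
    """Multiplying all Gamma and se_Gamma by c scales every beta and se by c."""

    @pytest.mark.parametrize("c", [0.5, 3.0])
    @pytest.mark.parametrize(
        "fit",
        [
            lambda X: IVWEstimator(model="auto").fit(X),
            lambda X: MedianEstimator(weighted=True, n_boot=200, random_state=3).fit(X),
            lambda X: MedianEstimator(weighted=False, n_boot=200, random_state=3).fit(X),
            lambda X: EggerRegression().fit(X),
            lambda X: RAPSEstimator().fit(X),
            lambda X: GRSEstimator().fit(X),
        ],
        ids=["ivw", "w_median", "s_median", "egger", "raps", "grs"],
    )
    def test_outcome_rescaling(self, rng, fit, c):
        X = random_instruments(rng, 15)
        Xc = X.assign(Gamma=X["Gamma"] * c, se_Gamma=X["se_Gamma"] * c)
        m, mc = fit(X), fit(Xc)
        assert mc.beta_ == pytest.approx(c * m.beta_, rel=1e-6)
        assert mc.se_ == pytest.approx(c * m.se_, rel=1e-6)
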
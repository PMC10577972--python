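"""Causal-effect estimators for summary-data Mendelian randomization.

Each estimator is a scikit-learn style class: construct with hyperparameters,
call ``fit(X)`` on a harmonized instrument set, read fitted attributes
(``beta_``, ``se_``, ``pvalue_``, ...) or the assembled
:class:`~mrkit.types.CausalEstimate` in ``estimate_``. ``X`` may be a pandas
DataFrame with columns ``gamma, se_gamma, Gamma, se_Gamma`` (plus optional
``SNP``) or a sequence of :class:`~mrkit.types.HarmonizedInstrument`.

The model: for instrument j with exposure association gamma_j (SE s_xj) and
outcome association Gamma_j (SE s_yj), a causal effect beta implies
Gamma_j = beta * gamma_j for valid instruments. All estimators are
inverse-variance weighted regressions through (or, for Egger, not through)
the origin, differing in their robustness to pleiotropy:

* IVW: weighted least squares through the origin; fixed-effect SE or a
  multiplicative random-effects SE inflated by sqrt(Q/(J-1)) when Cochran's
  Q signals heterogeneity.
* simple/weighted median: (weighted) median of the per-SNP Wald ratios,
  consistent when at least half the weight is on valid instruments; SE by
  parametric bootstrap.
* Egger: weighted regression with an intercept; the slope is the causal
  estimate, the intercept measures directional pleiotropy.
* MR-PRESSO: simulation-based global heterogeneity test on the residual sum
  of squares, per-SNP outlier test, outlier-corrected estimate and a
  distortion test.
* RAPS: robust adjusted profile score — solves a profile-score estimating
  equation with a Huber-bounded influence function, optionally with an
  overdispersion parameter for systematic pleiotropy.
* GRS: genetic-risk-score summary method; with the exposure effects as score
  weights it coincides algebraically with fixed-effect IVW.

Module-level functions (:func:`ivw`, :func:`egger`, ...) are thin wrappers
over the classes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .types import (
    CausalEstimate,
    DegenerateCorrectionError,
    DegenerateInstrumentError,
    DegenerateWeightsError,
    HarmonizedInstrument,
    HeterogeneityReport,
    InsufficientInstrumentsError,
    NonConvergenceError,
    PressoResult,
    RatioEstimate,
    ValidationError,
)

_Z975 = stats.norm.ppf(0.975)
_TINY_P = 5e-324  # smallest positive float; p-values are clipped into (0, 1]

_INSTRUMENT_COLUMNS = ("gamma", "se_gamma", "Gamma", "se_Gamma")


def as_instrument_arrays(
    X: pd.DataFrame | Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coerce an instrument set to (ids, gamma, se_gamma, Gamma, se_Gamma)."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in _INSTRUMENT_COLUMNS if c not in X.columns]
        if missing:
            raise ValidationError(f"instrument table lacks columns: {missing}")
        ids = (
            X["SNP"].astype(str).to_numpy()
            if "SNP" in X.columns
            else np.array([f"snp_{i}" for i in range(len(X))])
        )
        g = X["gamma"].to_numpy(dtype=float)
        sg = X["se_gamma"].to_numpy(dtype=float)
        G = X["Gamma"].to_numpy(dtype=float)
        sG = X["se_Gamma"].to_numpy(dtype=float)
    else:
        items = list(X)
        ids = np.array([h.variant_id for h in items])
        g = np.array([h.gamma for h in items], dtype=float)
        sg = np.array([h.se_gamma for h in items], dtype=float)
        G = np.array([h.Gamma for h in items], dtype=float)
        sG = np.array([h.se_Gamma for h in items], dtype=float)
    if np.any(sg <= 0) or np.any(sG <= 0):
        raise ValidationError("all instrument standard errors must be > 0")
    return ids, g, sg, G, sG


def _p_two_sided_normal(z: np.ndarray | float) -> np.ndarray | float:
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), _TINY_P, 1.0)


def _make_estimate(
    method: str, beta: float, se: float, n_snps: int,
    dist: str = "normal", df: int | None = None, notes: str = "",
) -> CausalEstimate:
    if dist == "t":
        crit = stats.t.ppf(0.975, df)
        pvalue = float(np.clip(2.0 * stats.t.sf(abs(beta / se), df), _TINY_P, 1.0))
    else:
        crit = _Z975
        pvalue = float(_p_two_sided_normal(beta / se))
    return CausalEstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - crit * se), ci_high=float(beta + crit * se),
        pvalue=pvalue, n_snps=int(n_snps), notes=notes,
    )


def ratio_estimates(X) -> list[RatioEstimate]:
    """Per-SNP Wald ratios Gamma/gamma with first-order SE se_Gamma/|gamma|."""
    ids, g, sg, G, sG = as_instrument_arrays(X)
    zero = np.flatnonzero(g == 0)
    if zero.size:
        raise DegenerateInstrumentError(
            f"zero exposure effect for instrument(s): {', '.join(ids[zero])}"
        )
    return [
        RatioEstimate(variant_id=v, wald_ratio=float(Gj / gj), se_ratio=float(sGj / abs(gj)))
        for v, gj, Gj, sGj in zip(ids, g, G, sG)
    ]


def _ivw_fixed(g: np.ndarray, G: np.ndarray, sG: np.ndarray) -> tuple[float, float]:
    """WLS through the origin of Gamma on gamma, weights 1/se_Gamma^2."""
    w = sG**-2.0
    sxx = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G)) / sxx
    return beta, sxx**-0.5


def _cochran_q(g: np.ndarray, G: np.ndarray, sG: np.ndarray, beta: float) -> float:
    # equivalent to sum_j w_j (ratio_j - beta)^2 with w_j = (gamma_j/se_Gamma_j)^2
    return float(np.sum((G - beta * g) ** 2 / sG**2))


class IVWEstimator(BaseEstimator):
    """Inverse-variance weighted estimator.

    Parameters
    ----------
    model : {"auto", "fixed", "random"}
        ``auto`` selects the multiplicative random-effects model when the
        Cochran's Q p-value is below ``q_alpha``, otherwise fixed-effect.
    q_alpha : float
        Heterogeneity significance level driving the auto choice.
    allow_single : bool
        Permit a single instrument (the estimate is then its Wald ratio).
    """

    def __init__(self, model: str = "auto", q_alpha: float = 0.05, allow_single: bool = False):
        self.model = model
        self.q_alpha = q_alpha
        self.allow_single = allow_single

    def fit(self, X, y=None):
        if self.model not in ("auto", "fixed", "random"):
            raise ValidationError(f"unknown IVW model {self.model!r}")
        ids, g, sg, G, sG = as_instrument_arrays(X)
        J = len(g)
        minimum = 1 if self.allow_single else 2
        if J < minimum:
            raise InsufficientInstrumentsError(f"IVW needs >= {minimum} instruments, got {J}")
        beta, fixed_se = _ivw_fixed(g, G, sG)
        if J >= 2:
            Q = _cochran_q(g, G, sG, beta)
            q_df = J - 1
            q_p = float(stats.chi2.sf(Q, q_df))
            scale = max(1.0, np.sqrt(Q / q_df))
        else:
            Q, q_df, q_p, scale = 0.0, 0, float("nan"), 1.0
        if self.model == "fixed":
            model_used = "fixed"
        elif self.model == "random":
            model_used = "random"
        else:
            model_used = "random" if (J >= 2 and q_p < self.q_alpha) else "fixed"
        se = fixed_se * scale if model_used == "random" else fixed_se

        self.n_snps_ = J
        self.beta_ = beta
        self.se_ = float(se)
        self.fixed_se_ = float(fixed_se)
        self.model_used_ = model_used
        self.q_ = Q
        self.q_df_ = q_df
        self.q_pvalue_ = q_p
        self.heterogeneity_ = HeterogeneityReport(
            Q=Q, df=max(q_df, 1), pvalue=q_p,
            model_selected="random" if (J >= 2 and q_p < 0.05) else "fixed",
        )
        self.estimate_ = _make_estimate(
            f"ivw_{model_used}", beta, se, J, notes=f"Q={Q:.4g} p={q_p:.4g}"
        )
        self.pvalue_ = self.estimate_.pvalue
        return self


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """50th percentile of the weighted empirical distribution of b.

    Linear interpolation between order statistics at standardized cumulative
    weights p_j = (S_j - w_j/2) / S_total.
    """
    order = np.argsort(b, kind="stable")
    b, w = b[order], w[order]
    cw = np.cumsum(w)
    p = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(0.5, p, b))


def _weighted_median_rows(B: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of B (n_rows x J) with shared weights w."""
    order = np.argsort(B, axis=1, kind="stable")
    Bs = np.take_along_axis(B, order, axis=1)
    Ws = w[order]
    cw = np.cumsum(Ws, axis=1)
    p = (cw - 0.5 * Ws) / cw[:, -1:]
    # manual per-row interpolation of the 0.5 quantile
    idx = np.sum(p < 0.5, axis=1)
    n, J = B.shape
    out = np.empty(n)
    at_edge_low = idx == 0
    at_edge_high = idx == J
    out[at_edge_low] = Bs[at_edge_low, 0]
    out[at_edge_high] = Bs[at_edge_high, -1]
    mid = ~(at_edge_low | at_edge_high)
    i_hi = idx[mid]
    i_lo = i_hi - 1
    rows = np.flatnonzero(mid)
    p_lo, p_hi = p[rows, i_lo], p[rows, i_hi]
    b_lo, b_hi = Bs[rows, i_lo], Bs[rows, i_hi]
    frac = np.where(p_hi > p_lo, (0.5 - p_lo) / np.where(p_hi > p_lo, p_hi - p_lo, 1.0), 0.0)
    out[mid] = b_lo + frac * (b_hi - b_lo)
    return out


class MedianEstimator(BaseEstimator):
    """Simple or inverse-variance weighted median of the Wald ratios.

    SE comes from a parametric bootstrap: each ratio is resampled from
    Normal(ratio_j, se_ratio_j), the median recomputed, and the SE is the
    standard deviation over ``n_boot`` replicates (seeded).
    """

    def __init__(self, weighted: bool = True, n_boot: int = 1000, random_state: int = 0):
        self.weighted = weighted
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None):
        ratios = ratio_estimates(X)
        J = len(ratios)
        if J < 3:
            raise InsufficientInstrumentsError(f"median estimator needs >= 3 instruments, got {J}")
        b = np.array([r.wald_ratio for r in ratios])
        se_r = np.array([r.se_ratio for r in ratios])
        w = se_r**-2.0 if self.weighted else np.ones(J)
        beta = _weighted_median(b, w) if self.weighted else float(np.median(b))

        rng = np.random.default_rng(self.random_state)
        B = rng.normal(b, se_r, size=(self.n_boot, J))
        boots = (
            _weighted_median_rows(B, w) if self.weighted else np.median(B, axis=1)
        )
        se = float(np.std(boots, ddof=1))

        self.n_snps_ = J
        self.beta_ = beta
        self.se_ = se
        method = "weighted_median" if self.weighted else "simple_median"
        self.estimate_ = _make_estimate(method, beta, se, J, notes=f"n_boot={self.n_boot}")
        self.pvalue_ = self.estimate_.pvalue
        return self


class EggerRegression(BaseEstimator):
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    Exposure effects are oriented non-negative first (Egger is not invariant
    to allele recoding). The slope estimates the causal effect under the
    InSIDE assumption; a nonzero intercept indicates directional pleiotropy.
    SEs use a multiplicative overdispersion scale max(1, sqrt(RSS/(J-2)));
    p-values come from t(J-2).
    """

    def fit(self, X, y=None):
        ids, g, sg, G, sG = as_instrument_arrays(X)
        J = len(g)
        if J < 3:
            raise InsufficientInstrumentsError(f"Egger needs >= 3 instruments, got {J}")
        sign = np.where(g < 0, -1.0, 1.0)
        g_o, G_o = g * sign, G * sign
        w = sG**-2.0
        res = sm.WLS(G_o, sm.add_constant(g_o), weights=w).fit()
        sigma2 = float(res.scale)  # weighted RSS / (J - 2)
        scale = max(1.0, np.sqrt(sigma2))
        se_unit = res.bse / np.sqrt(sigma2)
        intercept, slope = res.params
        se_intercept, se_slope = se_unit * scale

        self.n_snps_ = J
        self.beta_ = float(slope)
        self.se_ = float(se_slope)
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_intercept)
        self.rss_ = float(res.ssr)
        self.estimate_ = _make_estimate("egger_slope", slope, se_slope, J, dist="t", df=J - 2)
        self.intercept_estimate_ = _make_estimate(
            "egger_intercept", intercept, se_intercept, J, dist="t", df=J - 2
        )
        self.pvalue_ = self.estimate_.pvalue
        self.intercept_pvalue_ = self.intercept_estimate_.pvalue
        return self


def _loo_ivw_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out WLS-through-origin slopes, vectorized over the left-out SNP."""
    sxx = np.sum(w * g * g)
    sxy = np.sum(w * g * G)
    return (sxy - w * g * G) / (sxx - w * g * g)


class MRPresso(BaseEstimator):
    """Pleiotropy residual sum and outlier test.

    The observed residual sum of squares uses leave-one-out IVW predictions;
    its null distribution is built by parametric simulation of both the
    exposure and outcome associations. Per-SNP outliers are flagged at a
    Bonferroni-corrected empirical p threshold, the corrected estimate is
    IVW on the unflagged instruments, and the distortion test compares the
    raw/corrected difference against random outlier assignments. Empirical
    p-values carry the +1 correction, so the smallest reportable p is
    1/(n_sim+1).
    """

    def __init__(self, n_sim: int = 1000, outlier_alpha: float = 0.05, random_state: int = 0):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.random_state = random_state

    def fit(self, X, y=None):
        ids, g, sg, G, sG = as_instrument_arrays(X)
        J = len(g)
        if J < 4:
            raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {J}")
        if self.n_sim < 100:
            raise ValidationError("MR-PRESSO requires n_sim >= 100")
        w = sG**-2.0
        loo_beta = _loo_ivw_slopes(g, G, w)
        rss_obs = w * (G - loo_beta * g) ** 2
        global_rss = float(np.sum(rss_obs))

        rng = np.random.default_rng(self.random_state)
        g_star = rng.normal(g, sg, size=(self.n_sim, J))
        G_star = rng.normal(loo_beta * g, sG, size=(self.n_sim, J))
        sxx_r = np.sum(w * g_star**2, axis=1, keepdims=True)
        sxy_r = np.sum(w * g_star * G_star, axis=1, keepdims=True)
        loo_r = (sxy_r - w * g_star * G_star) / (sxx_r - w * g_star**2)
        rss_sim = w * (G_star - loo_r * g_star) ** 2
        global_sim = np.sum(rss_sim, axis=1)

        global_p = float((1 + np.sum(global_sim >= global_rss)) / (self.n_sim + 1))
        outlier_p = (1 + np.sum(rss_sim >= rss_obs, axis=0)) / (self.n_sim + 1)
        threshold = self.outlier_alpha / J
        flagged = outlier_p < threshold
        if flagged.all():
            raise DegenerateCorrectionError("every instrument flagged as an outlier")

        raw_beta, raw_se = _ivw_fixed(g, G, sG)
        keep = ~flagged
        corr_beta, corr_se = _ivw_fixed(g[keep], G[keep], sG[keep])

        distortion_p: float | None = None
        n_out = int(flagged.sum())
        if 0 < n_out < J:
            d_obs = (raw_beta - corr_beta) / corr_beta
            d_sim = np.empty(self.n_sim)
            for b in range(self.n_sim):
                drop = rng.choice(J, size=n_out, replace=False)
                mask = np.ones(J, dtype=bool)
                mask[drop] = False
                beta_b, _ = _ivw_fixed(g[mask], G[mask], sG[mask])
                d_sim[b] = (raw_beta - beta_b) / beta_b
            distortion_p = float(
                (1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (self.n_sim + 1)
            )

        self.n_snps_ = J
        self.result_ = PressoResult(
            global_rss=global_rss,
            global_p=global_p,
            outlier_pvalues={v: float(p) for v, p in zip(ids, outlier_p)},
            outlier_ids=[v for v, f in zip(ids, flagged) if f],
            distortion_p=distortion_p,
            n_sim=self.n_sim,
            seed=self.random_state,
        )
        self.raw_estimate_ = _make_estimate(
            "presso_raw", raw_beta, raw_se, J, notes=f"global_p={global_p:.4g}"
        )
        self.corrected_estimate_ = _make_estimate(
            "presso_corrected", corr_beta, corr_se, int(keep.sum()),
            notes=f"outliers_removed={n_out}",
        )
        self.beta_ = self.corrected_estimate_.beta if n_out else raw_beta
        self.se_ = self.corrected_estimate_.se if n_out else raw_se
        self.estimate_ = self.corrected_estimate_ if n_out else self.raw_estimate_
        return self


def _huber_psi(t: np.ndarray, k: float) -> np.ndarray:
    return np.clip(t, -k, k)


def _huber_rho(t: np.ndarray, k: float) -> np.ndarray:
    a = np.abs(t)
    return np.where(a <= k, 0.5 * t**2, k * a - 0.5 * k**2)


class RAPSEstimator(BaseEstimator):
    """Robust adjusted profile score estimator.

    Solves sum_j psi(t_j(beta)) * dt_j/dbeta = 0 where
    t_j = (Gamma_j - beta*gamma_j) / sqrt(se_Gamma^2 + beta^2 se_gamma^2 + tau^2)
    and psi is the Huber score with tuning constant ``huber_k``. With
    ``overdispersion`` the pleiotropy variance tau^2 is profiled jointly from
    the second moment of the standardized residuals. The SE uses the sandwich
    form of the estimating equation with the Huber moments of a standard
    normal.
    """

    def __init__(self, huber_k: float = 1.345, overdispersion: bool = False):
        self.huber_k = huber_k
        self.overdispersion = overdispersion

    def _score(self, beta: float, tau2: float, g, sg, G, sG) -> float:
        v = sG**2 + beta**2 * sg**2 + tau2
        r = G - beta * g
        t = r / np.sqrt(v)
        dtdb = -(g * v + r * beta * sg**2) / v**1.5
        return float(np.sum(_huber_psi(t, self.huber_k) * dtdb))

    def _solve_beta(self, tau2: float, beta0: float, g, sg, G, sG) -> float:
        f = lambda b: self._score(b, tau2, g, sg, G, sG)
        if f(beta0) == 0.0:
            return beta0
        half = 0.25
        for _ in range(12):
            lo, hi = beta0 - half, beta0 + half
            if f(lo) * f(hi) < 0:
                return float(optimize.brentq(f, lo, hi, xtol=1e-12))
            half *= 2.0
        # grid-scan fallback over a wide bracket
        grid = np.linspace(-10.0, 10.0, 4001)
        vals = np.array([f(b) for b in grid])
        sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        if sign_change.size == 0:
            raise NonConvergenceError(
                "no sign change in the RAPS estimating function over [-10, 10]"
            )
        i = sign_change[np.argmin(np.abs(grid[sign_change] - beta0))]
        return float(optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-12))

    def fit(self, X, y=None):
        ids, g, sg, G, sG = as_instrument_arrays(X)
        J = len(g)
        if J < 3:
            raise InsufficientInstrumentsError(f"RAPS needs >= 3 instruments, got {J}")
        k = self.huber_k
        # Huber moments of a standard normal: E[psi'(Z)] and E[psi(Z)^2]
        c1 = 2 * stats.norm.cdf(k) - 1
        c2 = c1 - 2 * k * stats.norm.pdf(k) + 2 * k**2 * stats.norm.sf(k)

        beta0, _ = _ivw_fixed(g, G, sG)
        tau2 = 0.0
        beta = self._solve_beta(tau2, beta0, g, sg, G, sG)
        if self.overdispersion:
            def tau_resid(t2: float, b: float) -> float:
                v = sG**2 + b**2 * sg**2 + t2
                t = (G - b * g) / np.sqrt(v)
                return float(np.sum((_huber_psi(t, k) ** 2 - c2) / v))

            for _ in range(50):
                upper = float(10.0 * np.max(sG**2 + beta**2 * sg**2))
                if tau_resid(0.0, beta) <= 0:
                    tau2_new = 0.0
                elif tau_resid(upper, beta) > 0:
                    tau2_new = upper
                else:
                    tau2_new = float(optimize.brentq(
                        lambda t2: tau_resid(t2, beta), 0.0, upper, xtol=1e-14
                    ))
                beta_new = self._solve_beta(tau2_new, beta, g, sg, G, sG)
                converged = abs(beta_new - beta) < 1e-10 and abs(tau2_new - tau2) < 1e-12
                beta, tau2 = beta_new, tau2_new
                if converged:
                    break

        v = sG**2 + beta**2 * sg**2 + tau2
        r = G - beta * g
        dtdb = -(g * v + r * beta * sg**2) / v**1.5
        s = float(np.sum(dtdb**2))
        se = float(np.sqrt(c2 / (c1**2 * s)))

        self.n_snps_ = J
        self.beta_ = beta
        self.se_ = se
        self.tau2_ = float(tau2)
        self.estimate_ = _make_estimate(
            "raps", beta, se, J,
            notes=f"huber_k={k} tau2={tau2:.4g}" if self.overdispersion else f"huber_k={k}",
        )
        self.pvalue_ = self.estimate_.pvalue
        return self


class GRSEstimator(BaseEstimator):
    """Genetic-risk-score summary method.

    With score weights omega and outcome effects beta_out (SE se_out):
    alpha = sum(omega*beta*se^-2) / sum(omega^2*se^-2),
    se_alpha = sqrt(1 / sum(omega^2*se^-2)). Fitting on an instrument set
    uses the exposure effects as weights, which makes the point estimate and
    SE identical to fixed-effect IVW.
    """

    def fit(self, X, y=None):
        ids, g, sg, G, sG = as_instrument_arrays(X)
        est = grs_summary(g, G, sG)
        est.n_snps = len(g)
        self.n_snps_ = len(g)
        self.beta_ = est.beta
        self.se_ = est.se
        self.estimate_ = est
        self.pvalue_ = est.pvalue
        return self


def grs_summary(omega, beta_out, se_out) -> CausalEstimate:
    """Causal estimate from score weights and outcome summary statistics."""
    omega = np.asarray(omega, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    if not (len(omega) == len(beta_out) == len(se_out)) or len(omega) < 1:
        raise ValidationError("omega, beta_out, se_out must have equal length >= 1")
    if np.any(se_out <= 0):
        raise ValidationError("all outcome standard errors must be > 0")
    w = se_out**-2.0
    denom = float(np.sum(omega**2 * w))
    if denom == 0:
        raise DegenerateWeightsError("sum(omega^2 / se^2) is zero")
    alpha = float(np.sum(omega * beta_out * w)) / denom
    se_alpha = denom**-0.5
    return _make_estimate("grs", alpha, se_alpha, len(omega))


# ---------------------------------------------------------------------------
# thin functional wrappers

def ivw(X, model: str = "auto", allow_single: bool = False) -> CausalEstimate:
    return IVWEstimator(model=model, allow_single=allow_single).fit(X).estimate_


def median_estimate(
    X, weighted: bool = True, n_boot: int = 1000, seed: int = 0
) -> CausalEstimate:
    return MedianEstimator(weighted=weighted, n_boot=n_boot, random_state=seed).fit(X).estimate_


def egger(X) -> tuple[CausalEstimate, CausalEstimate]:
    m = EggerRegression().fit(X)
    return m.estimate_, m.intercept_estimate_


def mr_presso(
    X, n_sim: int = 1000, outlier_alpha: float = 0.05, seed: int = 0
) -> tuple[PressoResult, CausalEstimate, CausalEstimate]:
    m = MRPresso(n_sim=n_sim, outlier_alpha=outlier_alpha, random_state=seed).fit(X)
    return m.result_, m.raw_estimate_, m.corrected_estimate_


def raps(X, huber_k: float = 1.345, overdispersion: bool = False) -> CausalEstimate:
    return RAPSEstimator(huber_k=huber_k, overdispersion=overdispersion).fit(X).estimate_
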
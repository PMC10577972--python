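"""Heterogeneity, pleiotropy, instrument-strength and influence diagnostics.

These drive model choice (fixed vs multiplicative random-effects IVW via
Cochran's Q) and the sensitivity reporting (Egger intercept, leave-one-out,
per-instrument F statistics). Flags annotate results, they never gate the
estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EggerRegression,
    IVWEstimator,
    _ivw_fixed,
    as_instrument_arrays,
)
from .types import (
    CausalEstimate,
    EggerInterceptTest,
    HeterogeneityReport,
    InfluenceReport,
    InsufficientInstrumentsError,
)


def cochran_q(X, alpha: float = 0.05) -> HeterogeneityReport:
    """Cochran's Q heterogeneity test across the per-SNP Wald ratios.

    Q = sum_j w_j (ratio_j - beta_ivw)^2 with first-order fixed weights;
    p from the upper tail of chi-square(J-1). ``model_selected`` is
    ``random`` iff p < ``alpha``.
    """
    ids, g, sg, G, sG = as_instrument_arrays(X)
    J = len(g)
    if J < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 instruments, got {J}")
    beta, _ = _ivw_fixed(g, G, sG)
    Q = float(np.sum((G - beta * g) ** 2 / sG**2))
    df = J - 1
    p = float(stats.chi2.sf(Q, df))
    return HeterogeneityReport(
        Q=Q, df=df, pvalue=p, model_selected="random" if p < alpha else "fixed"
    )


def egger_intercept_test(X, alpha: float = 0.05) -> EggerInterceptTest:
    """Directional-pleiotropy test: the Egger regression intercept row."""
    m = EggerRegression().fit(X)
    return EggerInterceptTest(
        intercept=m.intercept_,
        se=m.intercept_se_,
        pvalue=m.intercept_pvalue_,
        pleiotropy_flag=m.intercept_pvalue_ < alpha,
    )


def leave_one_out(X) -> tuple[list[tuple[str, CausalEstimate]], list[str]]:
    """IVW (auto model) with each instrument omitted in turn.

    Flags an instrument when omitting it flips the sign of the estimate or
    moves it outside the full-set confidence interval.
    """
    ids, g, sg, G, sG = as_instrument_arrays(X)
    J = len(g)
    if J < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 3 instruments, got {J}")
    df = pd.DataFrame(
        {"SNP": ids, "gamma": g, "se_gamma": sg, "Gamma": G, "se_Gamma": sG}
    )
    full = IVWEstimator(model="auto").fit(df)
    estimates: list[tuple[str, CausalEstimate]] = []
    flagged: list[str] = []
    for j in range(J):
        sub = df.drop(index=j)
        est = IVWEstimator(model="auto").fit(sub).estimate_
        estimates.append((ids[j], est))
        sign_flip = np.sign(est.beta) != np.sign(full.beta_) and est.beta != full.beta_
        outside = not (full.estimate_.ci_low <= est.beta <= full.estimate_.ci_high)
        if sign_flip or outside:
            flagged.append(ids[j])
    return estimates, flagged


def f_statistics(X) -> tuple[dict[str, float], float, float, bool]:
    """Per-SNP instrument strength F = (gamma/se_gamma)^2.

    ``weak_flag`` is raised unless every F exceeds 10 (strict rule: F = 10
    exactly counts as weak).
    """
    ids, g, sg, G, sG = as_instrument_arrays(X)
    f = (g / sg) ** 2
    stats_by_id = {v: float(x) for v, x in zip(ids, f)}
    min_f = float(np.min(f))
    mean_f = float(np.mean(f))
    return stats_by_id, min_f, mean_f, min_f <= 10.0


def influence_report(X) -> InfluenceReport:
    """Assemble leave-one-out and F-statistic diagnostics into one report."""
    loo, flagged = leave_one_out(X)
    f_by_id, min_f, mean_f, weak = f_statistics(X)
    return InfluenceReport(
        leave_one_out=loo,
        influential_ids=flagged,
        f_statistics=f_by_id,
        min_f=min_f,
        mean_f=mean_f,
        weak_flag=weak,
    )
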
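"""Synthetic two-trait GWAS summary statistics with known ground truth.

The generative model mirrors the assumptions of summary-data MR: J
independent instruments with true exposure effects gamma_j, outcome effects
Gamma_j = alpha * gamma_j + u_j (u_j the per-SNP horizontal-pleiotropy
effect), and observed associations drawn around the truth with the stated
standard errors. Pleiotropy regimes: ``none``; ``balanced`` (zero-mean);
``directional`` (nonzero mean, violates the zero-average-pleiotropy
assumption); ``inside_violation`` (u_j correlated with gamma_j, violating
InSIDE). A configurable fraction of instruments receives an additive outcome
shift of ``outlier_scale`` standard errors.

:func:`simulate_raw_tables` wraps the instruments as full summary tables —
adding alleles (with an exact planted share of palindromic variants),
positions, p-values consistent with beta/se, sub-threshold decoys, LD-linked
satellites, low-MAF variants and exclusion-listed variants — so the whole
read -> select -> harmonize -> estimate pipeline runs end to end against a
known truth record. One global seed governs a fixed draw order; partial
re-draws are not supported.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LdMatrix
from .types import ValidationError

_PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "inside_violation")

#: non-palindromic allele pairs cycled over simulated variants
_SAFE_ALLELES = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"))
_PALINDROMIC_ALLELES = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for synthetic two-trait summary statistics.

    Defaults describe a well-powered GWAS exposure: 30 independent
    instruments with effects around 0.15 log-odds (SEs 0.01-0.03, so
    per-SNP F statistics are comfortably above the weak-instrument line),
    outcome SEs 0.02-0.05, causal effect 0.2 and no pleiotropy.
    """

    n_snps: int = 30
    alpha_true: float = 0.2
    gamma_dist: tuple[float, float] = (0.15, 0.05)
    se_gamma_range: tuple[float, float] = (0.01, 0.03)
    se_Gamma_range: tuple[float, float] = (0.02, 0.05)
    pleiotropy: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    inside_rho: float = 0.7
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0
    maf_range: tuple[float, float] = (0.01, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValidationError("n_snps must be >= 2")
        if self.gamma_dist[1] <= 0:
            raise ValidationError("gamma_dist sd must be > 0")
        for name in ("se_gamma_range", "se_Gamma_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be strictly positive and ordered")
        if self.pleiotropy not in _PLEIOTROPY_REGIMES:
            raise ValidationError(f"pleiotropy must be one of {_PLEIOTROPY_REGIMES}")
        if self.pleiotropy != "none" and self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be >= 0")
        if not (0 <= self.outlier_fraction < 0.5):
            raise ValidationError("outlier_fraction must be in [0, 0.5)")
        if not (-1 <= self.inside_rho <= 1):
            raise ValidationError("inside_rho must be in [-1, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("gamma_dist", "se_gamma_range", "se_Gamma_range", "maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _draw_pleiotropy(cfg: SimulationConfig, gamma: np.ndarray, rng: np.random.Generator):
    J = cfg.n_snps
    if cfg.pleiotropy == "none":
        return np.zeros(J)
    if cfg.pleiotropy == "balanced":
        return rng.normal(0.0, cfg.pleiotropy_sd, size=J)
    if cfg.pleiotropy == "directional":
        return rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=J)
    # inside_violation: u correlated with instrument strength
    rho = cfg.inside_rho
    centered = gamma - cfg.gamma_dist[0]
    scale = cfg.pleiotropy_sd / cfg.gamma_dist[1] if cfg.gamma_dist[1] > 0 else 0.0
    noise = rng.normal(0.0, cfg.pleiotropy_sd, size=J)
    return cfg.pleiotropy_mean + rho * scale * centered + np.sqrt(1 - rho**2) * noise


def simulate_instruments(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Draw one harmonized instrument set plus its ground-truth record.

    Draw order (fixed): true gamma, se_gamma, se_Gamma, pleiotropy,
    observation noise for gamma-hat then Gamma-hat, outlier subset, eaf.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps
    gamma = rng.normal(*config.gamma_dist, size=J)
    se_gamma = rng.uniform(*config.se_gamma_range, size=J)
    se_Gamma = rng.uniform(*config.se_Gamma_range, size=J)
    u = _draw_pleiotropy(config, gamma, rng)
    Gamma_true = config.alpha_true * gamma + u
    gamma_hat = gamma + se_gamma * rng.standard_normal(J)
    Gamma_hat = Gamma_true + se_Gamma * rng.standard_normal(J)

    n_outliers = int(round(config.outlier_fraction * J))
    outlier_idx = np.sort(rng.choice(J, size=n_outliers, replace=False)) if n_outliers else np.array([], dtype=int)
    Gamma_hat = Gamma_hat.copy()
    Gamma_hat[outlier_idx] += config.outlier_scale * se_Gamma[outlier_idx]

    eaf = rng.uniform(*config.maf_range, size=J)
    ids = [f"rs{100001 + i}" for i in range(J)]
    instruments = pd.DataFrame(
        {
            "SNP": ids,
            "gamma": gamma_hat,
            "se_gamma": se_gamma,
            "Gamma": Gamma_hat,
            "se_Gamma": se_Gamma,
            "eaf_exposure": eaf,
            "eaf_outcome": eaf,
            "flipped": False,
        }
    )
    truth = {
        "alpha_true": config.alpha_true,
        "gamma_true": gamma.tolist(),
        "pleiotropy": u.tolist(),
        "outlier_ids": [ids[i] for i in outlier_idx],
        "seed": config.seed,
        "config": config.to_dict(),
    }
    return instruments, truth


@dataclass(frozen=True)
class RawTableConfig:
    """Extra structure layered on top of the instruments for full tables.

    ``palindromic_share`` converts an exact round(share * J) of the planted
    instruments to strand-ambiguous alleles. Decoys are guaranteed
    sub-threshold, satellites significant-but-linked (r2
    ``satellite_r2`` within ``satellite_offset_kb`` of their index, always
    with a larger p-value than the index), low-MAF variants significant but
    rare, and excluded variants significant but listed in the emitted
    exclusion list — so the expected survivors of each selection stage are
    known by construction.
    """

    palindromic_share: float = 0.0
    n_decoys: int = 0
    n_satellites: int = 0  # per instrument
    satellite_r2: float = 0.95
    satellite_offset_kb: float = 50.0
    n_lowmaf: int = 0
    n_excluded: int = 0
    p_threshold: float = 5e-8
    locus_spacing_bp: int = 2_000_000

    def __post_init__(self) -> None:
        if not (0 <= self.palindromic_share <= 1):
            raise ValidationError("palindromic_share must be in [0, 1]")
        for name in ("n_decoys", "n_satellites", "n_lowmaf", "n_excluded"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 5e-324, 1.0)


def _significant_beta(rng: np.random.Generator, mean: float, sd: float, se: float,
                      threshold: float) -> float:
    """Rejection-sample an observed effect until it passes the threshold."""
    z_crit = stats.norm.isf(threshold / 2.0)
    for _ in range(10_000):
        beta = rng.normal(mean, sd) + se * rng.standard_normal()
        if abs(beta) / se > z_crit:
            return float(beta)
    raise ValidationError("could not draw a genome-wide significant effect")


def simulate_raw_tables(
    config: SimulationConfig, raw: RawTableConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, LdMatrix, dict]:
    """Generate exposure and outcome summary tables plus LD matrix and truth.

    Returns ``(exposure, outcome, ld, truth)``; ``truth`` carries the planted
    instrument ids, the ids expected to survive each selection stage, the
    emitted exclusion list and the expected per-stage audit counts.
    """
    raw = raw or RawTableConfig()
    instruments, truth = simulate_instruments(config)
    rng = np.random.default_rng((config.seed, 1))
    J = config.n_snps
    z_crit = stats.norm.isf(raw.p_threshold / 2.0)

    # guarantee planted instruments are genome-wide significant, with margin
    # enough that their attenuated satellites stay significant too
    # (construction requirement for exact selection recovery). The whole SNP
    # (true effect, observed exposure and outcome associations) is resampled
    # jointly so the exposure/outcome pairing stays consistent.
    z_min = z_crit / 0.97
    g_hat = instruments["gamma"].to_numpy().copy()
    G_hat = instruments["Gamma"].to_numpy().copy()
    se_g = instruments["se_gamma"].to_numpy()
    se_G = instruments["se_Gamma"].to_numpy()
    gamma_true = np.array(truth["gamma_true"])
    u = np.array(truth["pleiotropy"])
    outlier_ids = set(truth["outlier_ids"])
    ids_list = list(instruments["SNP"])
    for i in range(J):
        while abs(g_hat[i]) / se_g[i] <= z_min:
            gamma_true[i] = rng.normal(*config.gamma_dist)
            g_hat[i] = gamma_true[i] + se_g[i] * rng.standard_normal()
            G_hat[i] = (
                config.alpha_true * gamma_true[i] + u[i]
                + se_G[i] * rng.standard_normal()
            )
            if ids_list[i] in outlier_ids:
                G_hat[i] += config.outlier_scale * se_G[i]
    instruments = instruments.assign(gamma=g_hat, Gamma=G_hat)
    truth["gamma_true"] = gamma_true.tolist()

    n_palin = int(round(raw.palindromic_share * J))
    palindromic_ids = list(instruments["SNP"].iloc[:n_palin])

    rows_exp: list[dict] = []
    rows_out: list[dict] = []
    ld_pairs: list[tuple[str, str, float]] = []
    locus = 0

    def _place() -> tuple[str, int]:
        nonlocal locus
        chrom = str(1 + (locus % 22))
        bp = 1_000_000 + (locus // 22) * raw.locus_spacing_bp
        locus += 1
        return chrom, bp

    def _alleles(i: int, palindromic: bool) -> tuple[str, str]:
        pool = _PALINDROMIC_ALLELES if palindromic else _SAFE_ALLELES
        return pool[i % len(pool)]

    def _add(snp, chrom, bp, ea, nea, eaf, beta_exp, se_exp, beta_out, se_out, n=50_000):
        rows_exp.append(
            {"SNP": snp, "CHR": chrom, "BP": bp, "EA": ea, "NEA": nea, "EAF": eaf,
             "BETA": beta_exp, "SE": se_exp, "P": float(_pvalue(np.array(beta_exp), np.array(se_exp))),
             "N": n}
        )
        rows_out.append(
            {"SNP": snp, "CHR": chrom, "BP": bp, "EA": ea, "NEA": nea, "EAF": eaf,
             "BETA": beta_out, "SE": se_out, "P": float(_pvalue(np.array(beta_out), np.array(se_out))),
             "N": 60_000}
        )

    satellite_ids: list[str] = []
    for i, row in instruments.iterrows():
        chrom, bp = _place()
        ea, nea = _alleles(i, row["SNP"] in palindromic_ids)
        _add(row["SNP"], chrom, bp, ea, nea, row["eaf_exposure"],
             row["gamma"], row["se_gamma"], row["Gamma"], row["se_Gamma"])
        if row["SNP"] in palindromic_ids:
            continue  # satellites attach only to surviving (nonpalindromic) indexes
        for s in range(raw.n_satellites):
            sid = f"{row['SNP']}_sat{s + 1}"
            satellite_ids.append(sid)
            offset = int(raw.satellite_offset_kb * 1000) * (s + 1)
            sea, snea = _alleles(i + s + 1, False)
            # attenuated copy of the index effect: always a larger p-value
            _add(sid, chrom, bp + offset, sea, snea, row["eaf_exposure"],
                 row["gamma"] * 0.97, row["se_gamma"], row["Gamma"] * 0.97, row["se_Gamma"])
            ld_pairs.append((row["SNP"], sid, raw.satellite_r2))
            for t in range(s):
                ld_pairs.append((f"{row['SNP']}_sat{t + 1}", sid, max(raw.satellite_r2 - 0.05, 0.0)))

    decoy_ids = []
    for d in range(raw.n_decoys):
        snp = f"rs_decoy_{d + 1}"
        decoy_ids.append(snp)
        chrom, bp = _place()
        ea, nea = _alleles(d, False)
        se = float(rng.uniform(*config.se_gamma_range))
        beta = 0.0
        while True:  # guarantee sub-threshold
            beta = se * rng.standard_normal()
            if abs(beta) / se <= z_crit:
                break
        _add(snp, chrom, bp, ea, nea, float(rng.uniform(0.05, 0.5)),
             beta, se, se * rng.standard_normal(), float(rng.uniform(*config.se_Gamma_range)))

    lowmaf_ids = []
    for m in range(raw.n_lowmaf):
        snp = f"rs_rare_{m + 1}"
        lowmaf_ids.append(snp)
        chrom, bp = _place()
        ea, nea = _alleles(m, False)
        se = float(rng.uniform(*config.se_gamma_range))
        beta = _significant_beta(rng, config.gamma_dist[0], config.gamma_dist[1], se, raw.p_threshold)
        _add(snp, chrom, bp, ea, nea, 0.005, beta, se,
             config.alpha_true * beta, float(rng.uniform(*config.se_Gamma_range)))

    excluded_ids = []
    for e in range(raw.n_excluded):
        snp = f"rs_confounded_{e + 1}"
        excluded_ids.append(snp)
        chrom, bp = _place()
        ea, nea = _alleles(e, False)
        se = float(rng.uniform(*config.se_gamma_range))
        beta = _significant_beta(rng, config.gamma_dist[0], config.gamma_dist[1], se, raw.p_threshold)
        _add(snp, chrom, bp, ea, nea, float(rng.uniform(0.05, 0.5)), beta, se,
             config.alpha_true * beta, float(rng.uniform(*config.se_Gamma_range)))

    exposure = pd.DataFrame(rows_exp)
    outcome = pd.DataFrame(rows_out)
    ld = LdMatrix.from_pairs(ld_pairs) if ld_pairs else LdMatrix.empty()

    expected_selected = [s for s in instruments["SNP"] if s not in palindromic_ids]
    n_sat_total = len(satellite_ids)
    n_total = len(exposure)
    expected_audit = [
        {"stage": "significance", "kept": n_total - raw.n_decoys, "dropped": raw.n_decoys},
        {"stage": "palindrome", "kept": n_total - raw.n_decoys - n_palin, "dropped": n_palin},
        {"stage": "ld_clump", "kept": n_total - raw.n_decoys - n_palin - n_sat_total,
         "dropped": n_sat_total},
        {"stage": "maf", "kept": n_total - raw.n_decoys - n_palin - n_sat_total - raw.n_lowmaf,
         "dropped": raw.n_lowmaf},
        {"stage": "exclusion", "kept": len(expected_selected), "dropped": raw.n_excluded},
    ]
    truth.update(
        {
            "instrument_ids": list(instruments["SNP"]),
            "palindromic_ids": palindromic_ids,
            "satellite_ids": satellite_ids,
            "decoy_ids": decoy_ids,
            "lowmaf_ids": lowmaf_ids,
            "excluded_ids": excluded_ids,
            "exclusion_list": excluded_ids,
            "expected_selected": expected_selected,
            "expected_audit": expected_audit,
        }
    )
    return exposure, outcome, ld, truth
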
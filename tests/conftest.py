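import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from scipy import stats

import mrkit as mk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

_SAFE_ALLELES = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


def random_instruments(rng: np.random.Generator, J: int) -> pd.DataFrame:
    """An arbitrary instrument set for algebraic-identity checks."""
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(J)],
            "gamma": rng.normal(0.2, 0.1, J),
            "se_gamma": rng.uniform(0.01, 0.05, J),
            "Gamma": rng.normal(0.05, 0.1, J),
            "se_Gamma": rng.uniform(0.01, 0.08, J),
        }
    )


def make_trait_table(ids, betas, ses, chrom_start=0, locus_spacing=2_000_000):
    """A canonical summary table with well-separated, nonpalindromic variants."""
    rows = []
    for i, (snp, b, se) in enumerate(zip(ids, betas, ses)):
        ea, nea = _SAFE_ALLELES[i % len(_SAFE_ALLELES)]
        p = float(np.clip(2 * stats.norm.sf(abs(b) / se), 5e-324, 1))
        rows.append(
            {"SNP": snp, "CHR": str(1 + ((chrom_start + i) % 22)),
             "BP": 1_000_000 + ((chrom_start + i) // 22) * locus_spacing,
             "EA": ea, "NEA": nea, "EAF": 0.3, "BETA": b, "SE": se, "P": p, "N": 50_000}
        )
    return pd.DataFrame(rows)


def make_bidirectional_tables(alpha_fwd: float, alpha_rev: float, J: int, seed: int):
    """Two trait tables with their own instrument sets and asymmetric truth.

    Trait A's instruments affect trait B with effect ``alpha_fwd``; trait B's
    instruments affect trait A with effect ``alpha_rev``. Small SEs keep the
    instruments strong and the cross-trait associations sub-threshold unless
    the causal effect carries them over.
    """
    cfg = dict(se_gamma_range=(0.01, 0.02), se_Gamma_range=(0.01, 0.03))
    inst_a, _ = mk.simulate_instruments(
        mk.SimulationConfig(n_snps=J, alpha_true=alpha_fwd, seed=seed, **cfg)
    )
    inst_b, _ = mk.simulate_instruments(
        mk.SimulationConfig(n_snps=J, alpha_true=alpha_rev, seed=seed + 1, **cfg)
    )
    ids_a = [f"rsA{i}" for i in range(J)]
    ids_b = [f"rsB{i}" for i in range(J)]
    # trait A table: A instruments (own effects), B instruments (effect of B on A)
    table_a = make_trait_table(
        ids_a + ids_b,
        list(inst_a["gamma"]) + list(inst_b["Gamma"]),
        list(inst_a["se_gamma"]) + list(inst_b["se_Gamma"]),
    )
    table_b = make_trait_table(
        ids_a + ids_b,
        list(inst_a["Gamma"]) + list(inst_b["gamma"]),
        list(inst_a["se_Gamma"]) + list(inst_b["se_gamma"]),
    )
    return table_a, table_b


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def clean_instruments():
    """25 instruments, causal effect 0.3, no pleiotropy or outliers."""
    inst, truth = mk.simulate_instruments(
        mk.SimulationConfig(n_snps=25, alpha_true=0.3, seed=42)
    )
    return inst, truth
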
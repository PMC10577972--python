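"""Reading, validation and allele harmonization of GWAS summary statistics.

Tables are delimited text (tab by default, comma autodetected) with a header
row. Canonical column names are ``SNP CHR BP EA NEA EAF BETA SE P N``; other
spellings are supported through a column map. Loaded tables are plain pandas
DataFrames with canonical columns, paired with a :class:`~mrkit.types.LoadReport`
that accounts for every dropped row.

Harmonization aligns an outcome association to the exposure's effect allele:
identical alleles are copied, swapped alleles flip the sign of the outcome
effect, strand-complemented representations are matched before giving up, and
palindromic (A/T, C/G) variants are always dropped because their strand cannot
be resolved from the alleles alone.
"""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    CANONICAL_COLUMNS,
    COMPLEMENT,
    MANDATORY_COLUMNS,
    VALID_ALLELES,
    ConfigurationError,
    DropSignal,
    EmptyInputError,
    HarmonizedInstrument,
    LoadReport,
    ValidationError,
    VariantAssociation,
)

_NUMERIC_COLUMNS = ("BP", "EAF", "BETA", "SE", "P", "N")


def _detect_separator(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
) -> tuple[pd.DataFrame, LoadReport]:
    """Read and validate one summary-statistic table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Optional mapping from canonical names (``SNP``, ``EA``, ...) to the
        names used in the file. Unmapped canonical names are looked up as-is.
    trait_label
        Free-text label recorded in the load report.

    Returns
    -------
    (table, report)
        ``table`` has canonical columns; rows failing validation are dropped
        and counted per reason in ``report``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary table not found: {path}")
    raw = pd.read_csv(path, sep=_detect_separator(path), dtype=str)

    column_map = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in MANDATORY_COLUMNS:
            raise ConfigurationError(
                f"{path}: mandatory column {canonical!r} (mapped from {source!r}) missing"
            )
    df = raw.rename(columns=rename)
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]].copy()
    for col in ("CHR", "BP", "EAF", "N"):
        if col not in df.columns:
            df[col] = np.nan

    n_read = len(df)
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["EA"] = df["EA"].astype(str).str.upper().str.strip()
    df["NEA"] = df["NEA"].astype(str).str.upper().str.strip()
    df["SNP"] = df["SNP"].astype(str).str.strip()
    df["CHR"] = df["CHR"].astype(str).str.strip().replace({"nan": None, "": None})

    dropped: Counter[str] = Counter()

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            dropped[reason] += n
            df = df[~mask]

    _drop(~df["EA"].isin(VALID_ALLELES) | ~df["NEA"].isin(VALID_ALLELES), "invalid_allele")
    _drop(df["EA"] == df["NEA"], "identical_alleles")
    _drop(df["BETA"].isna() | df["SE"].isna() | df["P"].isna(), "missing_value")
    _drop(~(df["SE"] > 0), "nonpositive_se")
    _drop(~((df["P"] > 0) & (df["P"] <= 1)), "invalid_pvalue")
    _drop(df["EAF"].notna() & ~df["EAF"].between(0, 1), "invalid_eaf")

    # duplicate ids: keep the record with the smallest p-value (deterministic)
    df = df.sort_values(["P", "SNP"], kind="mergesort")
    dup = df.duplicated(subset="SNP", keep="first")
    _drop(dup, "duplicate_id")
    df = df.sort_index().reset_index(drop=True)

    report = LoadReport(
        trait_label=trait_label, read=n_read, kept=len(df),
        dropped_by_reason=dict(dropped),
    )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no valid rows after validation")
    return df, report


def write_summary_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical-column table as TSV (the dialect this module reads)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    ea, oa = effect_allele.upper(), other_allele.upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise ValidationError(f"alleles must be A/C/G/T, got {ea}/{oa}")
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def swap_alleles(record: VariantAssociation) -> VariantAssociation:
    """Re-express an association with the alleles swapped (an involution)."""
    return VariantAssociation(
        variant_id=record.variant_id,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        se=record.se,
        pvalue=record.pvalue,
        chromosome=record.chromosome,
        position=record.position,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
        n=record.n,
    )


def complement_alleles(record: VariantAssociation) -> VariantAssociation:
    """Re-express an association on the opposite strand (betas unchanged)."""
    return VariantAssociation(
        variant_id=record.variant_id,
        effect_allele=COMPLEMENT[record.effect_allele],
        other_allele=COMPLEMENT[record.other_allele],
        beta=record.beta,
        se=record.se,
        pvalue=record.pvalue,
        chromosome=record.chromosome,
        position=record.position,
        eaf=record.eaf,
        n=record.n,
    )


def harmonize(
    exposure: VariantAssociation, outcome: VariantAssociation
) -> HarmonizedInstrument | DropSignal:
    """Align one outcome association to the exposure's effect allele.

    Palindromic variants are dropped (never rescued by allele-frequency
    inference); allele sets matching neither directly nor after strand
    complement yield a drop signal with reason ``allele_mismatch``.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValidationError(
            f"variant ids differ: {exposure.variant_id} vs {outcome.variant_id}"
        )
    if is_palindromic(exposure.effect_allele, exposure.other_allele) or is_palindromic(
        outcome.effect_allele, outcome.other_allele
    ):
        return DropSignal(exposure.variant_id, "palindromic")

    exp_pair = (exposure.effect_allele, exposure.other_allele)
    out_pair = (outcome.effect_allele, outcome.other_allele)
    comp_pair = (COMPLEMENT[out_pair[0]], COMPLEMENT[out_pair[1]])

    if out_pair == exp_pair or comp_pair == exp_pair:
        flipped = False
        Gamma, eaf_out = outcome.beta, outcome.eaf
    elif out_pair == exp_pair[::-1] or comp_pair == exp_pair[::-1]:
        flipped = True
        Gamma = -outcome.beta
        eaf_out = None if outcome.eaf is None else 1.0 - outcome.eaf
    else:
        return DropSignal(exposure.variant_id, "allele_mismatch")

    return HarmonizedInstrument(
        variant_id=exposure.variant_id,
        gamma=exposure.beta,
        se_gamma=exposure.se,
        Gamma=Gamma,
        se_Gamma=outcome.se,
        eaf_exposure=exposure.eaf,
        eaf_outcome=eaf_out,
        flipped=flipped,
    )


def _row_to_association(row: pd.Series) -> VariantAssociation:
    return VariantAssociation(
        variant_id=row["SNP"],
        effect_allele=row["EA"],
        other_allele=row["NEA"],
        beta=float(row["BETA"]),
        se=float(row["SE"]),
        pvalue=float(row["P"]),
        chromosome=None if pd.isna(row.get("CHR")) else str(row["CHR"]),
        position=None if pd.isna(row.get("BP")) else int(row["BP"]),
        eaf=None if pd.isna(row.get("EAF")) else float(row["EAF"]),
        n=None if pd.isna(row.get("N")) else float(row["N"]),
    )


def table_to_associations(df: pd.DataFrame) -> list[VariantAssociation]:
    """Convert a canonical-column table to :class:`VariantAssociation` records."""
    return [_row_to_association(row) for _, row in df.iterrows()]


def harmonize_tables(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> tuple[pd.DataFrame, list[DropSignal]]:
    """Harmonize every shared variant between two canonical-column tables.

    Returns a DataFrame of instruments (columns ``SNP gamma se_gamma Gamma
    se_Gamma eaf_exposure eaf_outcome flipped``) in exposure-table order, and
    the list of drop signals. Variants absent from the outcome table are
    dropped with reason ``missing_in_outcome``.
    """
    out_by_id = {row["SNP"]: row for _, row in outcome.iterrows()}
    rows, drops = [], []
    for _, exp_row in exposure.iterrows():
        vid = exp_row["SNP"]
        out_row = out_by_id.get(vid)
        if out_row is None:
            drops.append(DropSignal(vid, "missing_in_outcome"))
            continue
        result = harmonize(_row_to_association(exp_row), _row_to_association(out_row))
        if isinstance(result, DropSignal):
            drops.append(result)
        else:
            rows.append(
                {
                    "SNP": result.variant_id,
                    "gamma": result.gamma,
                    "se_gamma": result.se_gamma,
                    "Gamma": result.Gamma,
                    "se_Gamma": result.se_Gamma,
                    "eaf_exposure": result.eaf_exposure,
                    "eaf_outcome": result.eaf_outcome,
                    "flipped": result.flipped,
                }
            )
    columns = [
        "SNP", "gamma", "se_gamma", "Gamma", "se_Gamma",
        "eaf_exposure", "eaf_outcome", "flipped",
    ]
    return pd.DataFrame(rows, columns=columns), drops
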
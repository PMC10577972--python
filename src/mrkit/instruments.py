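"""Instrument selection: the five-criterion screening of an exposure table.

The stages run in the order of the screening narrative: genome-wide
significance, palindrome removal, greedy LD clumping, minor-allele-frequency
filter, confounder-exclusion list. Each stage is a contraction of the table
and the audit records the count after every stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import is_palindromic
from .types import SelectionConfig, ValidationError


@dataclass(frozen=True)
class LdMatrix:
    """Pairwise LD (r-squared) lookups over an ordered set of variant ids.

    Pairs absent from the matrix are treated as unlinked (r2 = 0), which
    permits distance-only pruning when no reference panel is supplied.
    """

    variant_ids: tuple[str, ...]
    r2: np.ndarray  # square, symmetric, unit diagonal

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if r2.shape != (n, n):
            raise ValidationError("LD matrix shape does not match variant ids")
        if np.any((r2 < 0) | (r2 > 1)):
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        if not np.allclose(r2, r2.T):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValidationError("LD matrix diagonal must be 1")
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.variant_ids)})

    def r2_between(self, id1: str, id2: str) -> float:
        if id1 == id2:
            return 1.0
        i = self._index.get(id1)
        j = self._index.get(id2)
        if i is None or j is None:
            return 0.0
        return float(self.r2[i, j])

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "LdMatrix":
        """Build from long-format (id1, id2, r2) triples."""
        pairs = list(pairs)
        ids: list[str] = []
        seen = set()
        for a, b, _ in pairs:
            for v in (a, b):
                if v not in seen:
                    seen.add(v)
                    ids.append(v)
        n = len(ids)
        index = {v: i for i, v in enumerate(ids)}
        r2 = np.eye(n)
        for a, b, val in pairs:
            i, j = index[a], index[b]
            r2[i, j] = r2[j, i] = val
        return cls(tuple(ids), r2)

    @classmethod
    def empty(cls) -> "LdMatrix":
        return cls((), np.zeros((0, 0)))


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read an LD matrix: square (header row of ids) or long (id1, id2, r2)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [str(c).lower() for c in df.columns]
    if cols == ["id1", "id2", "r2"]:
        return LdMatrix.from_pairs(
            (str(a), str(b), float(v)) for a, b, v in df.itertuples(index=False)
        )
    ids = tuple(str(c) for c in df.columns)
    return LdMatrix(ids, df.to_numpy(dtype=float))


def read_exclusion_list(path: str | Path) -> frozenset[str]:
    """One variant id per line; '#' starts a comment."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return frozenset(ids)


def filter_significance(records: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Keep records with p-value strictly below the significance threshold."""
    return records[records["P"] < p_threshold]


def filter_palindromic(records: pd.DataFrame) -> pd.DataFrame:
    """Drop strand-ambiguous (A/T, C/G) variants."""
    keep = [
        not is_palindromic(ea, nea)
        for ea, nea in zip(records["EA"], records["NEA"])
    ]
    return records[np.asarray(keep, dtype=bool)] if len(records) else records


def filter_maf(records: pd.DataFrame, maf_min: float) -> pd.DataFrame:
    """Keep records with min(eaf, 1-eaf) > maf_min; missing eaf is dropped."""
    eaf = records["EAF"]
    maf = np.minimum(eaf, 1.0 - eaf)
    return records[eaf.notna() & (maf > maf_min)]


def apply_exclusions(records: pd.DataFrame, exclusion_list: Iterable[str]) -> pd.DataFrame:
    """Remove records whose variant id is on the confounder-exclusion list."""
    excl = set(exclusion_list)
    if not excl:
        return records
    return records[~records["SNP"].isin(excl)]


def ld_clump(
    records: pd.DataFrame,
    ld: LdMatrix | None,
    clump_r2: float = 0.01,
    clump_window_kb: float = 500.0,
) -> pd.DataFrame:
    """Greedy LD clumping by p-value.

    Repeatedly takes the unclaimed record with the smallest p-value as an
    index variant and removes unclaimed records on the same chromosome within
    +/- ``clump_window_kb`` whose r2 with the index is >= ``clump_r2``. Ties
    on p break by position then variant id. Output is sorted by chromosome
    then position.
    """
    if len(records) <= 1:
        return records
    if records["CHR"].isna().any() or records["BP"].isna().any():
        raise ValidationError("LD clumping requires chromosome and position for every record")
    if ld is None:
        ld = LdMatrix.empty()

    df = records.reset_index(drop=True)
    order = sorted(
        range(len(df)),
        key=lambda i: (df.at[i, "P"], df.at[i, "BP"], df.at[i, "SNP"]),
    )
    window_bp = clump_window_kb * 1000.0
    claimed = np.zeros(len(df), dtype=bool)
    index_rows: list[int] = []
    for i in order:
        if claimed[i]:
            continue
        index_rows.append(i)
        claimed[i] = True
        chrom, pos, vid = df.at[i, "CHR"], df.at[i, "BP"], df.at[i, "SNP"]
        for j in order:
            if claimed[j]:
                continue
            if (
                df.at[j, "CHR"] == chrom
                and abs(df.at[j, "BP"] - pos) <= window_bp
                and ld.r2_between(vid, df.at[j, "SNP"]) >= clump_r2
            ):
                claimed[j] = True
    out = df.loc[index_rows]
    return out.sort_values(["CHR", "BP", "SNP"], kind="mergesort").reset_index(drop=True)


#: stage labels in application order
SELECTION_STAGES = ("significance", "palindrome", "ld_clump", "maf", "exclusion")


def select_instruments(
    records: pd.DataFrame,
    config: SelectionConfig | None = None,
    ld: LdMatrix | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the five selection criteria in sequence, with a per-stage audit.

    Returns the surviving records and an audit list of
    ``{"stage": ..., "kept": ..., "dropped": ...}`` in stage order.
    """
    config = config or SelectionConfig()
    audit: list[dict] = []
    current = records

    def _stage(name: str, result: pd.DataFrame) -> pd.DataFrame:
        audit.append(
            {"stage": name, "kept": int(len(result)), "dropped": int(len(current) - len(result))}
        )
        return result

    current = _stage("significance", filter_significance(current, config.p_threshold))
    current = _stage("palindrome", filter_palindromic(current))
    current = _stage(
        "ld_clump", ld_clump(current, ld, config.clump_r2, config.clump_window_kb)
    )
    current = _stage("maf", filter_maf(current, config.maf_min))
    current = _stage("exclusion", apply_exclusions(current, config.exclusion_list))
    return current.reset_index(drop=True), audit
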
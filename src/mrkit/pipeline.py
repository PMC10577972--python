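"""Orchestration of the bidirectional analysis matrix.

One *pair* is an (exposure table, outcome table) analysis: select instruments
on the exposure, look them up in the outcome table (no proxy search),
harmonize, run the requested estimators and diagnostics, and write one report
bundle (estimates.tsv, per_snp.tsv, diagnostics.tsv, leave_one_out.tsv,
audit.json, run.log). A bidirectional plan runs every exposure/outcome pair
in both directions and aggregates a top-level summary table with one row per
pair x method; summary numbers are copied from the pair reports, never
recomputed. All randomness is seeded, outputs carry no timestamps, and an
identical plan reruns to byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diagnostics as diag
from . import estimators as est
from .instruments import LdMatrix, select_instruments
from .io import harmonize_tables, read_summary_table
from .types import (
    CausalEstimate,
    InsufficientInstrumentsError,
    SelectionConfig,
    ValidationError,
)

ALL_METHODS = (
    "ivw", "median_simple", "median_weighted", "egger", "presso", "raps", "grs",
)

_FLOAT_FORMAT = "%.10g"


@dataclass
class PairResult:
    """In-memory report bundle for one exposure/outcome pair."""

    exposure_label: str
    outcome_label: str
    status: str  # "ok" or "under_instrumented"
    n_instruments: int
    estimates: pd.DataFrame
    per_snp: pd.DataFrame
    diagnostics: pd.DataFrame
    leave_one_out: pd.DataFrame
    audit: dict
    log_lines: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AnalysisPlan:
    """A bidirectional analysis: trait tables, selection settings, methods."""

    pairs: tuple[tuple[str, str, str, str], ...]  # (exp_label, exp_path, out_label, out_path)
    selection: SelectionConfig = SelectionConfig()
    methods: tuple[str, ...] = ALL_METHODS
    seed: int = 0
    n_sim: int = 1000
    n_boot: int = 1000
    output_dir: str = "mr_output"
    ld_path: str | None = None

    def __post_init__(self) -> None:
        unknown = [m for m in self.methods if m not in ALL_METHODS]
        if unknown:
            raise ValidationError(f"unknown methods requested: {unknown}")
        labels = [(p[0], p[2]) for p in self.pairs]
        if len(set(labels)) != len(labels):
            raise ValidationError("pair labels must be unique")

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "selection": self.selection.to_dict(),
            "methods": list(self.methods),
            "seed": self.seed,
            "n_sim": self.n_sim,
            "n_boot": self.n_boot,
            "output_dir": self.output_dir,
            "ld_path": self.ld_path,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisPlan":
        return cls(
            pairs=tuple(tuple(p) for p in d["pairs"]),
            selection=SelectionConfig.from_dict(d.get("selection", {})),
            methods=tuple(d.get("methods", ALL_METHODS)),
            seed=int(d.get("seed", 0)),
            n_sim=int(d.get("n_sim", 1000)),
            n_boot=int(d.get("n_boot", 1000)),
            output_dir=d.get("output_dir", "mr_output"),
            ld_path=d.get("ld_path"),
        )


def _method_seed(seed: int, method: str) -> int:
    offsets = {"median_simple": 1, "median_weighted": 2, "presso": 3}
    return (seed * 8 + offsets.get(method, 0)) % (2**31)


def run_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    selection: SelectionConfig | None = None,
    ld: LdMatrix | None = None,
    methods: tuple[str, ...] = ALL_METHODS,
    seed: int = 0,
    n_sim: int = 1000,
    n_boot: int = 1000,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> PairResult:
    """Run one exposure -> outcome analysis and assemble its report bundle."""
    selection = selection or SelectionConfig()
    log = [
        f"pair: {exposure_label} -> {outcome_label}",
        f"selection: {json.dumps(selection.to_dict(), sort_keys=True)}",
        f"seed: {seed}  n_sim: {n_sim}  n_boot: {n_boot}",
    ]
    selected, audit_stages = select_instruments(exposure, selection, ld)
    log.append(f"selection audit: {json.dumps(audit_stages)}")

    instruments, drops = harmonize_tables(selected, outcome)
    drop_counts: dict[str, int] = {}
    for d in drops:
        drop_counts[d.reason] = drop_counts.get(d.reason, 0) + 1
    log.append(f"harmonization drops: {json.dumps(drop_counts, sort_keys=True)}")

    audit = {
        "exposure": exposure_label,
        "outcome": outcome_label,
        "selection_stages": audit_stages,
        "harmonization_drops": drop_counts,
        "n_instruments": int(len(instruments)),
        "seed": seed,
        "selection": selection.to_dict(),
    }

    empty = pd.DataFrame()
    if len(instruments) < 3:
        log.append(f"under-instrumented: {len(instruments)} instruments, pair skipped")
        audit["status"] = "under_instrumented"
        return PairResult(
            exposure_label, outcome_label, "under_instrumented", len(instruments),
            empty, instruments, empty, empty, audit, log,
        )
    audit["status"] = "ok"

    estimates: list[CausalEstimate] = []
    if "ivw" in methods:
        m = est.IVWEstimator(model="auto").fit(instruments)
        e = m.estimate_
        e.notes = (e.notes + "; primary").strip("; ")
        estimates.append(e)
    if "median_simple" in methods:
        estimates.append(est.median_estimate(
            instruments, weighted=False, n_boot=n_boot, seed=_method_seed(seed, "median_simple")
        ))
    if "median_weighted" in methods:
        estimates.append(est.median_estimate(
            instruments, weighted=True, n_boot=n_boot, seed=_method_seed(seed, "median_weighted")
        ))
    if "egger" in methods:
        slope, intercept = est.egger(instruments)
        estimates.extend([slope, intercept])
    presso_result = None
    if "presso" in methods and len(instruments) >= 4:
        presso_result, presso_raw, presso_corr = est.mr_presso(
            instruments, n_sim=n_sim, seed=_method_seed(seed, "presso")
        )
        estimates.extend([presso_raw, presso_corr])
    if "raps" in methods:
        estimates.append(est.raps(instruments))
    if "grs" in methods:
        e = est.GRSEstimator().fit(instruments).estimate_
        e.notes = (e.notes + "; secondary validation").strip("; ")
        estimates.append(e)
    estimates_df = pd.DataFrame([e.to_row() for e in estimates])

    per_snp = instruments.copy()
    ratio_list = est.ratio_estimates(instruments)
    per_snp["wald_ratio"] = [r.wald_ratio for r in ratio_list]
    per_snp["se_ratio"] = [r.se_ratio for r in ratio_list]

    het = diag.cochran_q(instruments)
    egger_test = diag.egger_intercept_test(instruments)
    f_by_id, min_f, mean_f, weak = diag.f_statistics(instruments)
    diag_rows = [
        {"metric": "cochran_q", "value": het.Q, "detail": f"df={het.df}", "pvalue": het.pvalue},
        {"metric": "model_selected", "value": float("nan"), "detail": het.model_selected,
         "pvalue": float("nan")},
        {"metric": "egger_intercept", "value": egger_test.intercept,
         "detail": f"se={egger_test.se:.6g}", "pvalue": egger_test.pvalue},
        {"metric": "min_f", "value": min_f, "detail": f"weak={weak}", "pvalue": float("nan")},
        {"metric": "mean_f", "value": mean_f, "detail": "", "pvalue": float("nan")},
    ]
    if presso_result is not None:
        diag_rows.append(
            {"metric": "presso_global", "value": presso_result.global_rss,
             "detail": f"outliers={','.join(presso_result.outlier_ids) or 'none'}",
             "pvalue": presso_result.global_p}
        )
        if presso_result.distortion_p is not None:
            diag_rows.append(
                {"metric": "presso_distortion", "value": float("nan"), "detail": "",
                 "pvalue": presso_result.distortion_p}
            )
    diagnostics_df = pd.DataFrame(diag_rows)

    loo, influential = diag.leave_one_out(instruments)
    loo_df = pd.DataFrame(
        [
            {"dropped_snp": vid, "beta": e.beta, "se": e.se, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "pvalue": e.pvalue, "n_snps": e.n_snps,
             "influential": vid in influential}
            for vid, e in loo
        ]
    )
    log.append(f"estimates: {len(estimates_df)} rows; influential: {influential or 'none'}")
    return PairResult(
        exposure_label, outcome_label, "ok", len(instruments),
        estimates_df, per_snp, diagnostics_df, loo_df, audit, log,
    )


def write_pair_result(result: PairResult, outdir: str | Path) -> Path:
    """Write one pair's report bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in (
        ("estimates.tsv", result.estimates),
        ("per_snp.tsv", result.per_snp),
        ("diagnostics.tsv", result.diagnostics),
        ("leave_one_out.tsv", result.leave_one_out),
    ):
        df.to_csv(outdir / name, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    (outdir / "audit.json").write_text(json.dumps(result.audit, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(result.log_lines) + "\n")
    return outdir


def run_bidirectional(plan: AnalysisPlan) -> tuple[pd.DataFrame, list[PairResult]]:
    """Execute every pair of the plan in both directions and write the bundle.

    Forward runs use each pair's first table as exposure; reverse runs swap
    the roles (the reverse exposure is re-clumped independently). Returns the
    top-level summary (one row per pair x method) and all pair results.
    """
    from .instruments import read_ld_matrix

    outdir = Path(plan.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ld = read_ld_matrix(plan.ld_path) if plan.ld_path else None

    tables: dict[str, pd.DataFrame] = {}
    for exp_label, exp_path, out_label, out_path in plan.pairs:
        for label, path in ((exp_label, exp_path), (out_label, out_path)):
            if label not in tables:
                tables[label], _ = read_summary_table(path, trait_label=label)

    results: list[PairResult] = []
    summary_rows: list[dict] = []
    for exp_label, _, out_label, _ in plan.pairs:
        for direction, (a, b) in (
            ("forward", (exp_label, out_label)),
            ("reverse", (out_label, exp_label)),
        ):
            result = run_pair(
                tables[a], tables[b], plan.selection, ld, plan.methods,
                seed=plan.seed, n_sim=plan.n_sim, n_boot=plan.n_boot,
                exposure_label=a, outcome_label=b,
            )
            results.append(result)
            write_pair_result(result, outdir / f"{direction}_{a}_to_{b}")
            if result.status == "ok":
                for _, row in result.estimates.iterrows():
                    summary_rows.append(
                        {"direction": direction, "exposure": a, "outcome": b,
                         **row.to_dict()}
                    )
            else:
                summary_rows.append(
                    {"direction": direction, "exposure": a, "outcome": b,
                     "method": "none", "n_snps": result.n_instruments,
                     "notes": "under_instrumented"}
                )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format=_FLOAT_FORMAT)
    (outdir / "plan.json").write_text(json.dumps(plan.to_dict(), indent=2, sort_keys=True) + "\n")
    return summary, results
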
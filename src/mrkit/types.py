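"""Core record types and exceptions shared across the package.

Effect sizes are log odds ratios throughout; conversion to the OR scale
happens only when an estimate is reported.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names for summary-statistic tables
CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N")
MANDATORY_COLUMNS = ("SNP", "EA", "NEA", "BETA", "SE", "P")


class MrKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrKitError):
    """Invalid configuration (e.g. a mapped column missing from the file)."""


class EmptyInputError(MrKitError):
    """No valid rows survived loading/validation."""


class ValidationError(MrKitError):
    """A record or matrix violates a structural invariant."""


class InsufficientInstrumentsError(MrKitError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateInstrumentError(MrKitError):
    """An instrument with zero exposure effect where a Wald ratio is needed."""


class NonConvergenceError(MrKitError):
    """Root finding failed to bracket a solution."""


class DegenerateCorrectionError(MrKitError):
    """Outlier correction removed every instrument."""


class DegenerateWeightsError(MrKitError):
    """All score weights are zero."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` (log odds
    for binary traits) with standard error ``se``; ``eaf`` is the effect
    allele frequency, which may be missing.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chromosome: str | None = None
    position: int | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: alleles must be A/C/G/T, got {ea}/{oa}"
            )
        if ea == oa:
            raise ValidationError(f"{self.variant_id}: effect and other allele identical")
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if not self.se > 0:
            raise ValidationError(f"{self.variant_id}: se must be > 0")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.variant_id}: p-value must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.variant_id}: eaf must be in [0, 1]")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome association pair aligned to a common effect allele."""

    variant_id: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (self.se_gamma > 0 and self.se_Gamma > 0):
            raise ValidationError(f"{self.variant_id}: standard errors must be > 0")


@dataclass(frozen=True)
class DropSignal:
    """A harmonization drop with its reason code (never raised)."""

    variant_id: str
    reason: str


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio: outcome effect over exposure effect."""

    variant_id: str
    wald_ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return self.se_ratio**-2


@dataclass
class CausalEstimate:
    """One method's causal-effect estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    notes: str = ""

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (self.odds_ratio, self.or_ci_low, self.or_ci_high)

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "notes": self.notes,
        }


@dataclass
class PressoResult:
    """Pleiotropy residual-sum-and-outlier test results."""

    global_rss: float
    global_p: float
    outlier_pvalues: dict[str, float]
    outlier_ids: list[str]
    distortion_p: float | None
    n_sim: int
    seed: int


@dataclass
class HeterogeneityReport:
    """Cochran's Q heterogeneity test and the model it selects."""

    Q: float
    df: int
    pvalue: float
    model_selected: str  # "fixed" or "random"


@dataclass
class EggerInterceptTest:
    """Directional-pleiotropy test from the Egger regression intercept."""

    intercept: float
    se: float
    pvalue: float
    pleiotropy_flag: bool


@dataclass
class InfluenceReport:
    """Leave-one-out estimates plus per-instrument strength statistics."""

    leave_one_out: list[tuple[str, CausalEstimate]]
    influential_ids: list[str]
    f_statistics: dict[str, float]
    min_f: float
    mean_f: float
    weak_flag: bool


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for the five-criterion instrument-selection procedure.

    Defaults are the conventional genome-wide values: p < 5e-8, pairwise LD
    r-squared < 0.01 within a +/-500 kb window, MAF > 0.01.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 500.0
    maf_min: float = 0.01
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValidationError("p_threshold must be in (0, 1)")
        if not (0 <= self.clump_r2 <= 1):
            raise ValidationError("clump_r2 must be in [0, 1]")
        if not self.clump_window_kb > 0:
            raise ValidationError("clump_window_kb must be > 0")
        if not (0 <= self.maf_min < 0.5):
            raise ValidationError("maf_min must be in [0, 0.5)")
        object.__setattr__(self, "exclusion_list", frozenset(self.exclusion_list))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclusion_list"] = sorted(self.exclusion_list)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionConfig":
        d = dict(d)
        d["exclusion_list"] = frozenset(d.get("exclusion_list", ()))
        return cls(**d)


@dataclass
class LoadReport:
    """Accounting of one summary-table load: rows read, kept, dropped by reason."""

    trait_label: str
    read: int
    kept: int
    dropped_by_reason: dict[str, int] = field(default_factory=dict)

    @property
    def dropped(self) -> int:
        return sum(self.dropped_by_reason.values())

    def to_dict(self) -> dict:
        return {
            "trait_label": self.trait_label,
            "read": self.read,
            "kept": self.kept,
            "dropped_by_reason": dict(sorted(self.dropped_by_reason.items())),
        }
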
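"""Domain model for a pelvic exenteration (PE) cohort.

Pelvic exenteration removes multiple pelvic organs for advanced pelvic
cancer.  The UKPEN lexicon codes the anatomical extent of each resection
as an ordinal level per compartment (P posterior/sacrum, A anterior,
C central, SV sidewall vessels, SN sidewall nerves, PM pelvic
musculature, E extra-pelvic components).  Resections confined to
``P<=1, A<=3, C<=3, SV0, SN0, PM1`` are *conventional* PE; anything more
radical (``P>=2, A>=4, SV>=1, SN>=1, PM>=2`` or an E1-E4 component) is
*high-complexity* PE.  E5 components (oligometastatic/incidental
resections) and coccygectomy alone do not count towards complexity.

This module holds the patient record, the complexity classifier, and the
two-group comparison machinery (normality-routed continuous tests and
Fisher/chi-square categorical tests) used for the descriptive tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats


class ValidationError(ValueError):
    """Raised when input data violate a domain invariant."""


class DegenerateSampleError(ValueError):
    """Raised when a statistical comparison is requested on degenerate data."""


# Inclusive level ranges the classifier is configured with.  "CC" is the
# coccygectomy-alone marker: recorded, validated, never counted towards
# complexity.  The full lexicon permits more levels in some compartments;
# ranges here are a configuration, not a re-statement of the lexicon.
LEXICON_RANGES: dict[str, tuple[int, int]] = {
    "P": (0, 4),
    "A": (0, 7),
    "C": (0, 3),
    "SV": (0, 3),
    "SN": (0, 3),
    "PM": (0, 3),
    "E": (1, 5),
    "CC": (0, 0),
}

# Minimum level per compartment that makes a resection high-complexity.
# C never qualifies (its configured range is entirely conventional).
HIGH_COMPLEXITY_MIN = {"P": 2, "A": 4, "SV": 1, "SN": 1, "PM": 2}

# E components that count towards complexity; E5 is explicitly excluded.
QUALIFYING_E_LEVELS = frozenset({1, 2, 3, 4})

_CODE_RE = re.compile(r"^([A-Z]+?)(\d*)$")


@dataclass(frozen=True, order=True)
class UKPENCode:
    """One lexicon code, e.g. ``P2`` = sacrectomy at/above S3."""

    compartment: str
    level: int

    def __post_init__(self) -> None:
        if self.compartment not in LEXICON_RANGES:
            raise ValidationError(f"unknown UKPEN compartment in code {self.compartment}{self.level}")
        lo, hi = LEXICON_RANGES[self.compartment]
        if not (lo <= self.level <= hi):
            raise ValidationError(
                f"UKPEN level out of range for {self.compartment}: "
                f"{self.compartment}{self.level} (allowed {lo}..{hi})"
            )

    @classmethod
    def parse(cls, token: str) -> "UKPENCode":
        token = token.strip().upper()
        m = _CODE_RE.match(token)
        if not m:
            raise ValidationError(f"unparseable UKPEN token {token!r}")
        comp, level = m.group(1), m.group(2)
        if comp == "CC" and level == "":
            return cls("CC", 0)
        if level == "":
            raise ValidationError(f"UKPEN token {token!r} carries no level")
        return cls(comp, int(level))

    def __str__(self) -> str:
        return "CC" if self.compartment == "CC" else f"{self.compartment}{self.level}"


class ComplexityClass(str, Enum):
    CONVENTIONAL = "conventional"
    HIGH_COMPLEXITY = "high_complexity"


def classify_complexity(
    codes: Iterable[UKPENCode],
    historical_codes: Iterable[UKPENCode] = (),
) -> ComplexityClass:
    """Classify a resection as conventional or high-complexity PE.

    Historical conventional pelvic resections are merged into the working
    code set before the thresholds are applied, so staged surgery is
    classified on cumulative anatomical extent.  E5 codes and the
    coccygectomy-alone marker never influence the decision.
    """
    merged = set(codes) | set(historical_codes)
    if not merged:
        raise ValidationError("cannot classify an empty UKPEN code set")
    for code in merged:
        if code.compartment == "CC":
            continue
        if code.compartment == "E":
            if code.level in QUALIFYING_E_LEVELS:
                return ComplexityClass.HIGH_COMPLEXITY
            continue
        threshold = HIGH_COMPLEXITY_MIN.get(code.compartment)
        if threshold is not None and code.level >= threshold:
            return ComplexityClass.HIGH_COMPLEXITY
    return ComplexityClass.CONVENTIONAL


class Margin(str, Enum):
    R0 = "R0"
    R1_CONTINUOUS = "R1_continuous"
    R1_DISCONTINUOUS = "R1_discontinuous"
    R1_BOTH = "R1_both"
    R2 = "R2"
    NOT_APPLICABLE = "not_applicable"


CLAVIEN_DINDO_GRADES = ("1", "2", "3a", "3b", "4a", "4b", "5")
MAJOR_GRADES = frozenset({"3a", "3b", "4a", "4b", "5"})
COMPLICATION_PERIODS = ("index_admission", "later")


@dataclass(frozen=True)
class Complication:
    """A Clavien-Dindo graded complication and when it occurred."""

    grade: str
    period: str

    def __post_init__(self) -> None:
        if self.grade not in CLAVIEN_DINDO_GRADES:
            raise ValidationError(f"unknown Clavien-Dindo grade {self.grade!r}")
        if self.period not in COMPLICATION_PERIODS:
            raise ValidationError(f"unknown complication period {self.period!r}")

    @property
    def major(self) -> bool:
        return self.grade in MAJOR_GRADES


DIAGNOSES = ("colorectal", "urological", "gynaecological", "anal", "other")
EXENTERATION_LEVELS = ("supralevator", "infralevator")
RECONSTRUCTIONS = ("none", "biological_mesh", "myocutaneous_flap", "composite")


@dataclass
class PatientRecord:
    """One patient: classification, surgery, outcomes, resources, PROMs."""

    id: str
    codes: frozenset = frozenset()
    historical_codes: frozenset = frozenset()
    diagnosis: str = "colorectal"
    cancer_primary: bool = True
    cancer_recurrent: bool = False
    cancer_metastatic: bool = False
    exenteration_level: str = "supralevator"
    reconstruction: str = "none"
    survival_time: float = 0.0  # months from surgery
    survival_event: bool = False
    recurrence_time: Optional[float] = None
    recurrence_event: bool = False
    local_recurrence_time: Optional[float] = None
    local_recurrence_event: bool = False
    margin: Margin = Margin.R0
    benign_flag: bool = False
    complications: list = field(default_factory=list)
    resources: list = field(default_factory=list)  # list[ResourceLine]
    proms: list = field(default_factory=list)  # list[PromResponse]
    prom_participant: bool = False
    age: Optional[float] = None
    sex: Optional[str] = None
    bmi: Optional[float] = None
    asa: Optional[int] = None
    smoking: Optional[str] = None
    comorbidities: dict = field(default_factory=dict)
    group: Optional[ComplexityClass] = None  # derived, cached

    def __post_init__(self) -> None:
        self.validate()
        if self.group is None and (self.codes or self.historical_codes):
            self.group = classify_complexity(self.codes, self.historical_codes)

    def validate(self) -> None:
        if self.survival_time < 0:
            raise ValidationError(f"patient {self.id}: negative survival time")
        if (
            self.recurrence_time is not None
            and self.local_recurrence_time is not None
            and self.local_recurrence_time > self.recurrence_time
        ):
            raise ValidationError(
                f"patient {self.id}: local recurrence after distant/any recurrence"
            )
        if self.benign_flag and self.margin is not Margin.NOT_APPLICABLE:
            raise ValidationError(
                f"patient {self.id}: benign disease must carry margin not_applicable"
            )
        for code_set in (self.codes, self.historical_codes):
            seen: set = set()
            for code in code_set:
                if code.compartment in ("E", "CC"):
                    continue
                if code.compartment in seen:
                    raise ValidationError(
                        f"patient {self.id}: multiple codes in compartment {code.compartment}"
                    )
                seen.add(code.compartment)
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(f"patient {self.id}: unknown diagnosis {self.diagnosis!r}")
        if self.exenteration_level not in EXENTERATION_LEVELS:
            raise ValidationError(
                f"patient {self.id}: unknown exenteration level {self.exenteration_level!r}"
            )
        if self.reconstruction not in RECONSTRUCTIONS:
            raise ValidationError(
                f"patient {self.id}: unknown reconstruction {self.reconstruction!r}"
            )

    def has_major_complication(self, period: Optional[str] = None) -> bool:
        return any(
            c.major and (period is None or c.period == period) for c in self.complications
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # mann_whitney | t_test | fisher | chi_square | log_rank | anova

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")


def compare_continuous(
    a: Sequence[float], b: Sequence[float], alpha_normality: float = 0.05
) -> TestResult:
    """Two-group continuous comparison with Shapiro-Wilk routing.

    Each group is tested for normality; if either rejects at
    ``alpha_normality`` (or is constant, where normality is untestable),
    a two-sided Mann-Whitney U test is used, otherwise a two-sample
    t-test.  The tie-corrected normal approximation without continuity
    correction is used for Mann-Whitney so that identical samples yield
    p = 1 exactly.
    """
    xa = np.asarray([v for v in a if v is not None and not np.isnan(v)], dtype=float)
    xb = np.asarray([v for v in b if v is not None and not np.isnan(v)], dtype=float)
    if len(xa) < 3 or len(xb) < 3:
        raise ValidationError("each group needs >= 3 non-missing values")
    pooled = np.concatenate([xa, xb])
    if np.ptp(pooled) == 0:
        raise DegenerateSampleError("all values identical in both groups")

    def _nonnormal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return True  # constant sample: treat as non-normal
        return stats.shapiro(x).pvalue < alpha_normality

    if _nonnormal(xa) or _nonnormal(xb):
        res = stats.mannwhitneyu(
            xa, xb, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        return TestResult(float(res.statistic), float(res.pvalue), "mann_whitney")
    res = stats.ttest_ind(xa, xb, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "t_test")


def compare_categorical(table: Sequence[Sequence[float]]) -> TestResult:
    """Fisher's exact test (2x2 with any expected count < 5) or Pearson chi-square.

    Cochran's rule routes small-expected-count tables to the exact test.
    Exact testing is implemented for 2x2 tables; larger sparse tables
    fall back to the chi-square statistic.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValidationError("contingency table must be 2-dimensional")
    if (t < 0).any():
        raise ValidationError("contingency table contains negative counts")
    if (t.sum(axis=1) <= 0).any() or (t.sum(axis=0) <= 0).any():
        raise ValidationError("every margin of the table must be positive")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if t.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        return TestResult(float(odds), float(p), "fisher")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(float(chi2), float(p), "chi_square")


@dataclass
class MarginSummary:
    n_eligible: int
    counts: dict  # {"R0": int, "R1": int, "R2": int}
    percents: dict  # integer-rounded, same keys
    r1_continuous: int  # includes the both-margins patient
    r1_discontinuous: int  # includes the both-margins patient
    empty: bool = False


def summarize_margins(cohort: Sequence[PatientRecord]) -> MarginSummary:
    """Margin-status summary excluding benign / not-applicable patients.

    A patient whose single specimen carries both continuous and
    discontinuous R1 margins counts once in the R1 denominator but
    appears in both sub-splits.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    eligible = [
        p for p in cohort if not p.benign_flag and p.margin is not Margin.NOT_APPLICABLE
    ]
    n = len(eligible)
    if n == 0:
        return MarginSummary(0, {"R0": 0, "R1": 0, "R2": 0},
                             {"R0": 0, "R1": 0, "R2": 0}, 0, 0, empty=True)
    r0 = sum(p.margin is Margin.R0 for p in eligible)
    r1c = sum(p.margin is Margin.R1_CONTINUOUS for p in eligible)
    r1d = sum(p.margin is Margin.R1_DISCONTINUOUS for p in eligible)
    r1b = sum(p.margin is Margin.R1_BOTH for p in eligible)
    r2 = sum(p.margin is Margin.R2 for p in eligible)
    counts = {"R0": r0, "R1": r1c + r1d + r1b, "R2": r2}
    percents = {k: int(round(100.0 * v / n)) for k, v in counts.items()}
    return MarginSummary(n, counts, percents, r1c + r1b, r1d + r1b)


@dataclass
class MorbiditySummary:
    n: int
    index_count: int
    overall_count: int
    index_percent: int
    overall_percent: int


def summarize_morbidity(cohort: Sequence[PatientRecord]) -> MorbiditySummary:
    """Counts of patients with any Clavien-Dindo >= 3a complication.

    A patient counts once per period regardless of how many major
    complications occurred; overall = index admission or later.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    n = len(cohort)
    index = sum(p.has_major_complication("index_admission") for p in cohort)
    overall = sum(p.has_major_complication() for p in cohort)
    return MorbiditySummary(
        n, index, overall, int(round(100.0 * index / n)), int(round(100.0 * overall / n))
    )


def median_iqr(values: Sequence[float]) -> tuple[float, float]:
    """Median and IQR (Q3 - Q1, linear-interpolation quantiles)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return float("nan"), float("nan")
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return float(q2), float(q3 - q1)
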
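"""Seeded synthetic cohort generator.

Patient-level data from the study cohort are not released, so every
downstream stage is exercised on simulated cohorts whose statistical
structure matches the published group summaries: two groups
(64 conventional, 255 high-complexity), Weibull overall survival
calibrated jointly to the group medians (10.5 / 9.8 years) and 5-year
rates (72.1% / 70.9%), major-morbidity rates, margin and diagnosis
mixes, gamma perioperative cost marginals per category, and EQ5D-5L /
Decision Regret Scale trajectories with decline and (group-dependent)
recovery over 12 months.

Randomness is organised as named substreams: the draw sequence of one
component never depends on whether another component was sampled, and a
fixed (seed, spec) pair reproduces the cohort exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .cohort import (
    Complication,
    ComplexityClass,
    Margin,
    PatientRecord,
    UKPENCode,
    ValidationError,
)
from .costing import CATEGORIES, ResourceLine, UnitCostTable
from .proms import TIMEPOINTS, PromResponse, ValueSetTable, toy_valueset_5l


def stream(seed: int, label: str) -> np.random.Generator:
    """Named substream: same (seed, label) -> identical draw sequence."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# Model components
# ---------------------------------------------------------------------------


@dataclass
class SurvivalModel:
    """Parametric overall-survival model for one group.

    ``weibull`` solves shape and scale jointly from the median and the
    5-year survival fraction (two constraints, two parameters);
    ``exponential`` uses the median alone.
    """

    shape: str = "weibull"  # weibull | exponential
    median_years: float = 10.0
    five_year_survival: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape not in ("weibull", "exponential"):
            raise ValidationError(f"unknown survival shape {self.shape!r}")
        if self.median_years <= 0:
            raise ValidationError("median must be positive")
        if self.five_year_survival is not None and not 0 < self.five_year_survival < 1:
            raise ValidationError("five-year survival must lie in (0, 1)")

    def params(self) -> tuple[float, float]:
        """(k, lambda) of S(t) = exp(-(t / lambda)^k), t in years."""
        ln2 = np.log(2.0)
        if self.shape == "exponential" or self.five_year_survival is None:
            return 1.0, self.median_years / ln2
        if abs(self.median_years - 5.0) < 1e-9:
            raise ValidationError("median of exactly 5 years cannot pin the Weibull shape")
        # (m/5)^k = ln 2 / (-ln S5)  =>  closed form for k, then scale.
        k = np.log(ln2 / -np.log(self.five_year_survival)) / np.log(self.median_years / 5.0)
        if k <= 0:
            raise ValidationError("inconsistent median / 5-year survival pair")
        lam = self.median_years / ln2 ** (1.0 / k)
        return float(k), float(lam)

    def survival(self, t_years: float) -> float:
        k, lam = self.params()
        return float(np.exp(-((t_years / lam) ** k)))

    def sample_years(self, rng: np.random.Generator, n: int) -> np.ndarray:
        k, lam = self.params()
        return lam * rng.weibull(k, n)


@dataclass
class CostCategoryModel:
    """Gamma marginal for one cost category, parameterised by mean/SD (GBP)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValidationError("cost mean must be positive")
        if self.sd < 0:
            raise ValidationError("cost sd must be non-negative")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        shape = self.mean**2 / self.sd**2
        scale = self.sd**2 / self.mean
        return rng.gamma(shape, scale, n)


@dataclass
class PromTrajectoryModel:
    """Latent utility / regret trajectory over {0, 3, 6, 12} months.

    The latent utility at a timepoint is baseline mean minus the
    timepoint dip plus Gaussian noise, clamped to the attainable range of
    the active value set, then inverted to the nearest attainable EQ5D-5L
    state.  DRS items are drawn around the timepoint DRS mean.  The 0.80
    baseline is a placeholder convention, not an observed quantity.
    """

    baseline_mean: float = 0.80
    noise_sd: float = 0.10
    dips: dict = field(default_factory=lambda: {"baseline": 0.0, "m3": 0.12, "m6": 0.08, "m12": 0.0})
    drs_means: dict = field(default_factory=lambda: {"baseline": 12.0, "m3": 15.0, "m6": 14.0, "m12": 12.0})
    drs_sd: float = 10.0
    completion: dict = field(default_factory=lambda: {"baseline": 1.0, "m3": 0.85, "m6": 0.75, "m12": 0.65})

    def __post_init__(self) -> None:
        for tp in TIMEPOINTS:
            if not 0.0 <= self.completion.get(tp, 1.0) <= 1.0:
                raise ValidationError(f"completion probability for {tp} outside [0, 1]")
        if self.noise_sd < 0 or self.drs_sd < 0:
            raise ValidationError("noise SDs must be non-negative")


@dataclass
class GroupSpec:
    """Stochastic parameters for one complexity group."""

    label: str
    complexity: ComplexityClass
    n: int
    survival: SurvivalModel
    morbidity_index: float
    morbidity_overall: float
    benign_prob: float
    margin_probs: dict  # among non-benign: Margin -> prob
    diagnosis_mix: dict
    primary_prob: float
    metastatic_prob: float
    infralevator_frac: float
    reconstruction_mix: dict  # given infralevator
    costs: dict  # category -> CostCategoryModel
    prom: PromTrajectoryModel
    prom_participation: float
    recurrence_five_year_dfs: float = 0.6
    local_given_recurrence: float = 0.4

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("group size must be positive")
        for name, p in (
            ("morbidity_index", self.morbidity_index),
            ("morbidity_overall", self.morbidity_overall),
            ("benign_prob", self.benign_prob),
            ("prom_participation", self.prom_participation),
            ("infralevator_frac", self.infralevator_frac),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")
        if self.morbidity_overall < self.morbidity_index:
            raise ValidationError("overall morbidity cannot be below index morbidity")
        for mix_name, mix in (
            ("margin_probs", self.margin_probs),
            ("diagnosis_mix", self.diagnosis_mix),
            ("reconstruction_mix", self.reconstruction_mix),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in mix.values()):
                raise ValidationError(f"{mix_name} must be a probability distribution")


@dataclass
class GeneratorSpec:
    """Full two-group generator specification plus censoring model."""

    groups: list
    censoring_window_years: tuple = (0.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.censoring_window_years
        if lo < 0 or hi < lo:
            raise ValidationError("censoring window must satisfy 0 <= lo <= hi")

    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label or g.label.startswith(label):
                return g
        raise KeyError(f"no group labelled {label!r}")


def default_spec(seed: int = 0) -> GeneratorSpec:
    """Generator calibrated to the published two-group summaries.

    Group sizes 64/255; Weibull survival matching median 10.5/9.8 years
    and 5-year survival 72.1%/70.9% simultaneously; index/overall major
    morbidity 8%->16% and 20%->31%; margin, diagnosis, exenteration-level
    and reconstruction mixes from the baseline tables; per-category gamma
    costs with the published category means/SDs (the small residual
    between the overall mean and the category sum is absorbed into the
    admission category).  Censoring is uniform administrative over a
    14-year accrual window.
    """
    conventional = GroupSpec(
        label="conventional",
        complexity=ComplexityClass.CONVENTIONAL,
        n=64,
        survival=SurvivalModel("weibull", 10.5, 0.721),
        morbidity_index=5 / 64,
        morbidity_overall=10 / 64,
        benign_prob=4 / 64,
        margin_probs={
            Margin.R0: 52 / 60,
            Margin.R1_CONTINUOUS: 4 / 60,
            Margin.R1_DISCONTINUOUS: 3 / 60,
            Margin.R1_BOTH: 0.0,
            Margin.R2: 1 / 60,
        },
        diagnosis_mix={
            "colorectal": 45 / 64,
            "urological": 3 / 64,
            "gynaecological": 10 / 64,
            "anal": 1 / 64,
            "other": 5 / 64,
        },
        primary_prob=0.63,
        metastatic_prob=8 / 64,
        infralevator_frac=26 / 64,
        reconstruction_mix={
            "biological_mesh": 22 / 26,
            "myocutaneous_flap": 3 / 26,
            "composite": 0.0,
            "none": 1 / 26,
        },
        costs={
            "theatres": CostCategoryModel(18875.0, 6988.0),
            # category means sum to the printed overall mean 37,271
            "admission": CostCategoryModel(18143.0, 9910.0),
            "unplanned_radiology": CostCategoryModel(146.0, 170.0),
            "reintervention": CostCategoryModel(107.0, 487.0),
        },
        prom=PromTrajectoryModel(
            dips={"baseline": 0.0, "m3": 0.12, "m6": 0.08, "m12": 0.0},
            drs_means={"baseline": 12.0, "m3": 15.0, "m6": 14.0, "m12": 12.0},
        ),
        prom_participation=10 / 64,
        recurrence_five_year_dfs=0.65,
        local_given_recurrence=0.45,
    )
    high = GroupSpec(
        label="high_complexity",
        complexity=ComplexityClass.HIGH_COMPLEXITY,
        n=255,
        survival=SurvivalModel("weibull", 9.8, 0.709),
        morbidity_index=52 / 255,
        morbidity_overall=79 / 255,
        benign_prob=3 / 255,
        margin_probs={
            Margin.R0: 210 / 252,
            Margin.R1_CONTINUOUS: 27 / 252,
            Margin.R1_DISCONTINUOUS: 14 / 252,
            Margin.R1_BOTH: 1 / 252,
            Margin.R2: 0.0,
        },
        diagnosis_mix={
            "colorectal": 188 / 255,
            "urological": 38 / 255,
            "gynaecological": 13 / 255,
            "anal": 10 / 255,
            "other": 6 / 255,
        },
        primary_prob=0.61,
        metastatic_prob=65 / 255,
        infralevator_frac=100 / 255,
        reconstruction_mix={
            "biological_mesh": 61 / 100,
            "myocutaneous_flap": 22 / 100,
            "composite": 15 / 100,
            "none": 2 / 100,
        },
        costs={
            "theatres": CostCategoryModel(24858.0, 11326.0),
            "admission": CostCategoryModel(20454.0, 15490.0),
            "unplanned_radiology": CostCategoryModel(211.0, 270.0),
            "reintervention": CostCategoryModel(210.0, 1028.0),
        },
        prom=PromTrajectoryModel(
            dips={"baseline": 0.0, "m3": 0.12, "m6": 0.15, "m12": 0.05},
            drs_means={"baseline": 20.0, "m3": 14.0, "m6": 14.0, "m12": 12.0},
        ),
        prom_participation=50 / 255,
        recurrence_five_year_dfs=0.472,
        local_given_recurrence=0.35,
    )
    return GeneratorSpec(groups=[conventional, high], seed=seed)


# ---------------------------------------------------------------------------
# Component samplers
# ---------------------------------------------------------------------------


def sample_survival(
    model: SurvivalModel,
    rng: np.random.Generator,
    censor_window_years: tuple = (0.0, 14.0),
    n: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Event times (months) under administrative censoring.

    Returns (observed time in months, event flag); event = death observed
    before the uniform administrative censoring time.
    """
    lo, hi = censor_window_years
    t_event = model.sample_years(rng, n) * 12.0
    t_censor = rng.uniform(lo * 12.0, hi * 12.0, n) if hi > lo else np.full(n, lo * 12.0)
    event = t_event <= t_censor
    return np.minimum(t_event, t_censor), event


def sample_costs(
    costs: dict, rng: np.random.Generator, n: int = 1
) -> list:
    """Per-category gamma draws emitted as unit-priced resource lines.

    Each category's draw becomes one resource line with quantity equal to
    the drawn GBP amount and unit cost 1, so bottom-up totals equal the
    draws exactly.  Returns a list of per-patient resource-line lists.
    """
    draws = {cat: m.sample(rng, n) for cat, m in costs.items()}
    out = []
    for i in range(n):
        out.append(
            [
                ResourceLine(cat, f"{cat}_composite", float(draws[cat][i]))
                for cat in costs
            ]
        )
    return out


def synthetic_unit_costs(categories: Sequence[str] = CATEGORIES) -> UnitCostTable:
    """Unit-cost table pricing the generator's composite lines at 1 GBP."""
    return UnitCostTable(
        {f"{cat}_composite": (1.0, "GBP", "synthetic composite") for cat in categories}
    )


def sample_prom_trajectory(
    model: PromTrajectoryModel,
    rng: np.random.Generator,
    valueset: ValueSetTable,
) -> list:
    """One patient's PROM responses across the four timepoints.

    Latent utilities are clamped to the value set's attainable range and
    inverted to the nearest attainable state; dropout is applied
    independently per timepoint (missing completely at random).
    """
    responses = []
    u_min = valueset.min_utility()
    for tp in TIMEPOINTS:
        completed = rng.uniform() < model.completion.get(tp, 1.0)
        latent = model.baseline_mean - model.dips.get(tp, 0.0)
        if model.noise_sd > 0:
            latent += rng.normal(0.0, model.noise_sd)
        latent = float(np.clip(latent, u_min, 1.0))
        drs_latent = float(
            np.clip(rng.normal(model.drs_means.get(tp, 0.0), model.drs_sd), 0.0, 100.0)
        )
        if not completed:
            continue
        state = valueset.invert(latent)
        items = _drs_items_for_score(drs_latent, rng)
        responses.append(PromResponse(tp, eq5d=state, drs_items=items))
    return responses


def _drs_items_for_score(score: float, rng: np.random.Generator) -> tuple:
    """Item vector whose recoded mean scatters around a target 0-100 score."""
    target = score / 25.0 + 1.0  # recoded-item mean in [1, 5]
    recoded = np.clip(np.rint(rng.normal(target, 0.6, 5)), 1, 5).astype(int)
    raw = [6 - v if pos in (1, 3, 5) else v for pos, v in enumerate(recoded, start=1)]
    return tuple(int(v) for v in raw)


# ---------------------------------------------------------------------------
# UKPEN code assignment
# ---------------------------------------------------------------------------

_QUALIFYING_POOL = (
    # (codes to add, implies major bone, implies vessel resection), weight
    (("P2", "P3"), True, False, 0.17),
    (("A4", "A5"), True, False, 0.08),
    (("SV1", "SV2", "SV3"), False, True, 0.09),
    (("SN1", "SN2"), False, False, 0.15),
    (("PM2", "PM3"), False, False, 0.31),
    (("E1", "E2", "E3", "E4"), False, False, 0.20),
)


def _sample_codes(
    complexity: ComplexityClass, rng: np.random.Generator
) -> tuple[frozenset, bool, bool]:
    """Draw a lexicon code set consistent with the group label.

    Conventional sets stay at or below every threshold (a central C code
    is always present, optionally with sub-threshold P/A/PM codes or a
    non-qualifying E5); high-complexity sets add at least one qualifying
    code.  Returns (codes, major bone flag, vessel-resection flag).
    """
    codes = {UKPENCode("C", int(rng.integers(1, 4)))}
    if rng.uniform() < 0.5:
        codes.add(UKPENCode("P", 1))
    if rng.uniform() < 0.4:
        codes.add(UKPENCode("A", int(rng.integers(1, 4))))
    if rng.uniform() < 0.15:
        codes.add(UKPENCode("PM", 1))
    if rng.uniform() < 0.05:
        codes.add(UKPENCode("E", 5))
    if complexity is ComplexityClass.CONVENTIONAL:
        return frozenset(codes), False, False
    weights = np.array([w for *_, w in _QUALIFYING_POOL])
    idx = int(rng.choice(len(_QUALIFYING_POOL), p=weights / weights.sum()))
    pool, bone, vessel, _ = _QUALIFYING_POOL[idx]
    qualifying = UKPENCode.parse(str(rng.choice(pool)))
    # one code per non-E compartment: the qualifying code supersedes
    codes = {
        c for c in codes if c.compartment == "E" or c.compartment != qualifying.compartment
    }
    codes.add(qualifying)
    return frozenset(codes), bone, vessel


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def generate_cohort(
    spec: GeneratorSpec, valueset: Optional[ValueSetTable] = None
) -> list:
    """Generate the full two-group cohort (deterministic under the seed).

    Every record passes domain validation, and the complexity classifier
    recovers the generating group label from the assigned lexicon codes.
    """
    valueset = valueset or toy_valueset_5l()
    cohort: list[PatientRecord] = []
    for g in spec.groups:
        cohort.extend(_generate_group(g, spec, valueset))
    return cohort


def _generate_group(
    g: GroupSpec, spec: GeneratorSpec, valueset: ValueSetTable
) -> list:
    n = g.n
    s = lambda label: stream(spec.seed, f"{g.label}/{label}")

    t_months, events = sample_survival(
        g.survival, s("survival"), spec.censoring_window_years, n
    )

    rng_m = s("morbidity")
    index_flags = rng_m.uniform(size=n) < g.morbidity_index
    later_prob = (
        (g.morbidity_overall - g.morbidity_index) / (1.0 - g.morbidity_index)
        if g.morbidity_index < 1.0
        else 0.0
    )
    later_only = (~index_flags) & (rng_m.uniform(size=n) < later_prob)
    minor_flags = rng_m.uniform(size=n) < 0.35  # background minor complications

    rng_mar = s("margins")
    benign = rng_mar.uniform(size=n) < g.benign_prob
    margin_labels = list(g.margin_probs)
    margin_p = np.array([g.margin_probs[m] for m in margin_labels])
    margin_idx = rng_mar.choice(len(margin_labels), size=n, p=margin_p)

    rng_d = s("diagnosis")
    diag_labels = list(g.diagnosis_mix)
    diag_idx = rng_d.choice(
        len(diag_labels), size=n, p=np.array([g.diagnosis_mix[d] for d in diag_labels])
    )
    primary = rng_d.uniform(size=n) < g.primary_prob
    metastatic = rng_d.uniform(size=n) < g.metastatic_prob

    rng_s = s("surgery")
    infra = rng_s.uniform(size=n) < g.infralevator_frac
    recon_labels = list(g.reconstruction_mix)
    recon_idx = rng_s.choice(
        len(recon_labels),
        size=n,
        p=np.array([g.reconstruction_mix[r] for r in recon_labels]),
    )

    rng_rec = s("recurrence")
    # Exponential disease-free model pinned at the 5-year rate.
    lam_rec = -np.log(g.recurrence_five_year_dfs) / 5.0
    t_rec = rng_rec.exponential(1.0 / lam_rec, n) * 12.0
    local = rng_rec.uniform(size=n) < g.local_given_recurrence

    rng_cov = s("covariates")
    age = np.clip(np.rint(rng_cov.normal(64.0, 13.0, n)), 18, 92)
    female = rng_cov.uniform(size=n) < 0.5
    bmi = np.round(np.clip(rng_cov.normal(26.0, 5.0, n), 15, 55), 1)
    asa = rng_cov.choice([1, 2, 3, 4], size=n, p=[0.05, 0.55, 0.38, 0.02])
    smoking = rng_cov.choice(
        ["current", "ex", "never"], size=n, p=[0.08, 0.37, 0.55]
    )

    resources = sample_costs(g.costs, s("costs"), n)

    rng_codes = s("codes")
    rng_prom = s("proms")
    prom_participants = rng_prom.uniform(size=n) < g.prom_participation

    records = []
    for i in range(n):
        codes, bone, vessel = _sample_codes(g.complexity, rng_codes)
        complications = []
        if index_flags[i]:
            complications.append(Complication("3b", "index_admission"))
        if later_only[i]:
            complications.append(Complication("3a", "later"))
        if minor_flags[i]:
            complications.append(Complication("2", "index_admission"))

        recurrence_event = bool(events[i] or t_rec[i] <= t_months[i])
        recurrence_time = float(min(t_rec[i], t_months[i]))
        is_local = bool(local[i]) and recurrence_event and t_rec[i] <= t_months[i]

        proms = (
            sample_prom_trajectory(g.prom, rng_prom, valueset)
            if prom_participants[i]
            else []
        )

        records.append(
            PatientRecord(
                id=f"{g.label[:4]}-{i:05d}",
                codes=codes,
                diagnosis=diag_labels[diag_idx[i]],
                cancer_primary=bool(primary[i]) and not benign[i],
                cancer_recurrent=not bool(primary[i]) and not benign[i],
                cancer_metastatic=bool(metastatic[i]) and not benign[i],
                exenteration_level="infralevator" if infra[i] else "supralevator",
                reconstruction=recon_labels[recon_idx[i]] if infra[i] else "none",
                survival_time=float(t_months[i]),
                survival_event=bool(events[i]),
                recurrence_time=recurrence_time,
                recurrence_event=recurrence_event,
                local_recurrence_time=recurrence_time if is_local else None,
                local_recurrence_event=is_local,
                margin=Margin.NOT_APPLICABLE if benign[i] else margin_labels[margin_idx[i]],
                benign_flag=bool(benign[i]),
                complications=complications,
                resources=resources[i],
                proms=proms,
                prom_participant=bool(prom_participants[i]),
                age=float(age[i]),
                sex="female" if female[i] else "male",
                bmi=float(bmi[i]),
                asa=int(asa[i]),
                smoking=str(smoking[i]),
            )
        )
    return records
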
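"""Bottom-up micro-costing and group cost comparisons.

Each patient's perioperative resource use is recorded as quantity lines
(theatre minutes, bed days, scans, re-interventions) priced against a
unit-cost table; per-line costs aggregate into category totals and an
overall total per patient.  Group comparisons use Welch t-tests on
means, and the perineal-reconstruction sub-analysis uses one-way ANOVA
with Bonferroni-corrected pairwise contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TestResult, ValidationError

log = logging.getLogger(__name__)

CATEGORIES = ("theatres", "admission", "unplanned_radiology", "reintervention", "other")


class MissingPriceError(KeyError):
    """A resource line references an item absent from the unit-cost table."""


@dataclass(frozen=True)
class ResourceLine:
    category: str
    item: str
    quantity: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown resource category {self.category!r}")
        if self.quantity < 0:
            raise ValidationError(f"negative quantity for item {self.item!r}")


class UnitCostTable:
    """Maps item keys to (unit cost GBP, unit descriptor, source label)."""

    def __init__(self, entries: Mapping[str, tuple]) -> None:
        self.entries = {}
        for item, (cost, unit, source) in entries.items():
            if cost < 0:
                raise ValidationError(f"negative unit cost for {item!r}")
            self.entries[item] = (float(cost), unit, source)

    def price(self, item: str) -> float:
        try:
            return self.entries[item][0]
        except KeyError:
            raise MissingPriceError(f"no unit cost for item {item!r}") from None

    @classmethod
    def from_csv(cls, path) -> "UnitCostTable":
        df = pd.read_csv(path)
        return cls(
            {
                str(r.item): (float(r.unit_cost_gbp), str(r.unit), str(r.source))
                for r in df.itertuples()
            }
        )

    def to_csv(self, path) -> None:
        rows = [
            {"item": item, "unit": unit, "unit_cost_gbp": cost, "source": source}
            for item, (cost, unit, source) in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class CostBreakdown:
    """Per-category and overall bottom-up cost for one patient (GBP)."""

    by_category: dict
    patient_id: Optional[str] = None

    @property
    def total(self) -> float:
        return float(sum(self.by_category.values()))

    def __getitem__(self, category: str) -> float:
        return self.by_category.get(category, 0.0)


def cost_patient(
    resources: Iterable[ResourceLine],
    prices: UnitCostTable,
    patient_id: Optional[str] = None,
) -> CostBreakdown:
    """Price every resource line and sum by category (overall = category sum)."""
    by_cat = {c: 0.0 for c in CATEGORIES}
    for line in resources:
        by_cat[line.category] += line.quantity * prices.price(line.item)
    return CostBreakdown(by_cat, patient_id=patient_id)


def _welch_p(xa: np.ndarray, xb: np.ndarray) -> float:
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        # zero variance in both groups: identical means are indistinguishable
        return 1.0 if xa.mean() == xb.mean() else 0.0
    return float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)


def compare_two_group_costs(
    a: Sequence[CostBreakdown], b: Sequence[CostBreakdown]
) -> pd.DataFrame:
    """Per-category mean (SD), mean difference (b - a) and Welch t-test p.

    Includes an ``overall`` row on the per-patient totals.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 costed patients")
    rows = []
    for cat in list(CATEGORIES) + ["overall"]:
        xa = np.array([c.total if cat == "overall" else c[cat] for c in a])
        xb = np.array([c.total if cat == "overall" else c[cat] for c in b])
        rows.append(
            {
                "category": cat,
                "mean_a": xa.mean(),
                "sd_a": xa.std(ddof=1),
                "mean_b": xb.mean(),
                "sd_b": xb.std(ddof=1),
                "mean_difference": xb.mean() - xa.mean(),
                "p_value": _welch_p(xa, xb),
            }
        )
    return pd.DataFrame(rows)


def compare_reconstruction_costs(
    groups: Mapping[str, Sequence[CostBreakdown]]
) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA on overall costs plus Bonferroni pairwise contrasts.

    Groups with fewer than 2 patients are excluded with a logged warning.
    Pairwise Welch t-test p-values are multiplied by the number of
    comparisons and capped at 1.
    """
    usable = {}
    for name, breakdowns in groups.items():
        if len(breakdowns) < 2:
            log.warning("reconstruction group %r has n=%d < 2; excluded", name, len(breakdowns))
            continue
        usable[name] = np.array([c.total for c in breakdowns])
    if len(usable) < 2:
        raise ValidationError("need >= 2 groups with n >= 2 for ANOVA")
    names = list(usable)
    if np.ptp(np.concatenate(list(usable.values()))) == 0:
        anova = TestResult(0.0, 1.0, "anova")  # no variation anywhere
    else:
        f, p = stats.f_oneway(*usable.values())
        anova = TestResult(float(f), float(p), "anova")
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    k = len(pairs)
    rows = []
    for ga, gb in pairs:
        xa, xb = usable[ga], usable[gb]
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "mean_difference": xb.mean() - xa.mean(),
                "p_bonferroni": min(1.0, _welch_p(xa, xb) * k),
            }
        )
    return anova, pd.DataFrame(rows)
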
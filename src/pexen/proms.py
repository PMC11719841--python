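"""Patient-reported outcome scoring.

EQ5D-5L responses (five dimensions, five levels each) are valued to a
utility on the dead = 0 / full health = 1 scale under a pluggable value
set; utilities feed the cost-utility model after a 5L -> 3L crosswalk.
The Decision Regret Scale (DRS, five Likert items) is scored 0-100 with
0 = no decisional regret.

Value-set and crosswalk coefficients are licensed and are therefore not
bundled: CSV tables in the documented dialect are user-supplied.  Toy
tables with synthetic coefficients ship for testing and simulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import PatientRecord, ValidationError

TIMEPOINTS = ("baseline", "m3", "m6", "m12")
TIMEPOINT_MONTHS = {"baseline": 0.0, "m3": 3.0, "m6": 6.0, "m12": 12.0}
EQ5D_DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


class TableIncompleteError(KeyError):
    """A value-set or crosswalk table does not cover a requested state."""


@dataclass
class PromResponse:
    """One patient-timepoint response; either instrument may be absent."""

    timepoint: str
    eq5d: Optional[tuple] = None  # five ints in 1..5
    drs_items: Optional[tuple] = None  # five ints in 1..5

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown PROM timepoint {self.timepoint!r}")
        for name, vals, n_levels in (("eq5d", self.eq5d, 5), ("drs", self.drs_items, 5)):
            if vals is None:
                continue
            vals = tuple(int(v) for v in vals)
            if len(vals) != 5 or any(not 1 <= v <= n_levels for v in vals):
                raise ValidationError(f"{name} items must be five integers in 1..5: {vals}")
        if self.eq5d is not None:
            self.eq5d = tuple(int(v) for v in self.eq5d)
        if self.drs_items is not None:
            self.drs_items = tuple(int(v) for v in self.drs_items)

    @property
    def months(self) -> float:
        return TIMEPOINT_MONTHS[self.timepoint]


def _state_str(state: Sequence[int]) -> str:
    return "".join(str(int(v)) for v in state)


class ValueSetTable:
    """EQ5D value set: additive per-dimension decrements or full enumeration.

    Additive mode stores a decrement for every (dimension, level) pair
    (level 1 must carry decrement 0 so the 11111 full-health anchor is
    exactly 1.0); utility = 1 - sum of the five decrements.  Enumeration
    mode stores one utility per state.
    """

    def __init__(
        self,
        mode: str,
        entries: dict,
        levels: int = 5,
        anchor: float = 1.0,
    ) -> None:
        if mode not in ("additive_decrement", "full_enumeration"):
            raise ValidationError(f"unknown value-set mode {mode!r}")
        self.mode = mode
        self.entries = dict(entries)
        self.levels = levels
        self.anchor = anchor
        if mode == "additive_decrement":
            for dim in range(5):
                if self.entries.get((dim, 1), 0.0) != 0.0:
                    raise ValidationError("level-1 decrements must be 0 (full-health anchor)")
        else:
            full = "1" * 5
            if abs(self.entries.get(full, np.nan) - anchor) > 1e-12:
                raise ValidationError("enumeration table must value state 11111 at the anchor")
        self._attainable_cache: Optional[tuple] = None

    # -- scoring ---------------------------------------------------------
    def utility(self, state: Sequence[int]) -> float:
        state = tuple(int(v) for v in state)
        if len(state) != 5 or any(not 1 <= v <= self.levels for v in state):
            raise ValidationError(f"state must be five levels in 1..{self.levels}: {state}")
        if self.mode == "full_enumeration":
            key = _state_str(state)
            if key not in self.entries:
                raise TableIncompleteError(f"value set does not cover state {key}")
            return float(self.entries[key])
        total = 0.0
        for dim, level in enumerate(state):
            try:
                total += self.entries[(dim, level)]
            except KeyError:
                raise TableIncompleteError(
                    f"value set missing decrement for dimension "
                    f"{EQ5D_DIMENSIONS[dim]} level {level}"
                ) from None
        return self.anchor - total

    # -- inversion (utility -> nearest attainable state) ------------------
    def _attainable(self) -> tuple:
        """Sorted unique attainable utilities and, per utility, the
        lexicographically smallest state attaining it."""
        if self._attainable_cache is None:
            best: dict[float, tuple] = {}
            for state in itertools.product(range(1, self.levels + 1), repeat=5):
                try:
                    u = round(self.utility(state), 12)
                except TableIncompleteError:
                    continue
                if u not in best:  # product() iterates lexicographically
                    best[u] = state
            utils = np.array(sorted(best))
            states = [best[u] for u in utils]
            self._attainable_cache = (utils, states)
        return self._attainable_cache

    def invert(self, target: float) -> tuple:
        """Nearest attainable state to a latent utility; ties break to the
        lexicographically smallest state."""
        utils, states = self._attainable()
        i = int(np.searchsorted(utils, target))
        candidates = []
        for j in (i - 1, i):
            if 0 <= j < len(utils):
                candidates.append((abs(utils[j] - target), states[j]))
        dmin = min(d for d, _ in candidates)
        return min(s for d, s in candidates if d <= dmin + 1e-15)

    def invert_many(self, targets: np.ndarray) -> list:
        return [self.invert(float(t)) for t in np.asarray(targets, dtype=float)]

    def min_utility(self) -> float:
        return float(self._attainable()[0][0])

    # -- CSV dialect -----------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "ValueSetTable":
        df = pd.read_csv(path)
        cols = set(df.columns)
        if {"dimension", "level", "decrement"} <= cols:
            dim_index = {d: i for i, d in enumerate(EQ5D_DIMENSIONS)}
            entries = {
                (dim_index[str(r.dimension)], int(r.level)): float(r.decrement)
                for r in df.itertuples()
            }
            levels = int(df["level"].max())
            return cls("additive_decrement", entries, levels=levels)
        if {"state", "utility"} <= cols:
            entries = {str(r.state): float(r.utility) for r in df.itertuples()}
            levels = max(int(c) for s in entries for c in s)
            return cls("full_enumeration", entries, levels=levels)
        raise ValidationError(
            "value-set CSV needs (dimension, level, decrement) or (state, utility) columns"
        )

    def to_csv(self, path) -> None:
        if self.mode == "additive_decrement":
            rows = [
                {"dimension": EQ5D_DIMENSIONS[dim], "level": level, "decrement": dec}
                for (dim, level), dec in sorted(self.entries.items())
            ]
        else:
            rows = [{"state": s, "utility": u} for s, u in sorted(self.entries.items())]
        pd.DataFrame(rows).to_csv(path, index=False)


class CrosswalkTable:
    """5L -> 3L crosswalk: per-state 3L distribution, or precomputed utilities."""

    def __init__(
        self,
        distributions: Optional[dict] = None,
        valueset_3l: Optional[ValueSetTable] = None,
        precomputed: Optional[dict] = None,
    ) -> None:
        if (distributions is None) == (precomputed is None):
            raise ValidationError("supply exactly one of distributions / precomputed")
        if distributions is not None:
            if valueset_3l is None:
                raise ValidationError("distribution form requires a 3L value set")
            for state, dist in distributions.items():
                total = sum(p for _, p in dist)
                if abs(total - 1.0) > 1e-9:
                    raise ValidationError(
                        f"crosswalk distribution for {state} sums to {total}, not 1"
                    )
        self.distributions = distributions
        self.valueset_3l = valueset_3l
        self.precomputed = precomputed

    def utility(self, state5: Sequence[int]) -> float:
        key = _state_str(state5)
        if self.precomputed is not None:
            if key not in self.precomputed:
                raise TableIncompleteError(f"crosswalk does not cover 5L state {key}")
            return float(self.precomputed[key])
        if key not in self.distributions:
            raise TableIncompleteError(f"crosswalk does not cover 5L state {key}")
        return float(
            sum(p * self.valueset_3l.utility([int(c) for c in s3])
                for s3, p in self.distributions[key])
        )

    @classmethod
    def from_csv(cls, path, valueset_3l: Optional[ValueSetTable] = None) -> "CrosswalkTable":
        df = pd.read_csv(path, dtype={"state5l": str, "state3l": str})
        cols = set(df.columns)
        if {"state5l", "state3l", "probability"} <= cols:
            dists: dict[str, list] = {}
            for r in df.itertuples():
                dists.setdefault(str(r.state5l), []).append(
                    (str(r.state3l), float(r.probability))
                )
            return cls(distributions=dists, valueset_3l=valueset_3l)
        if {"state5l", "utility"} <= cols:
            return cls(precomputed={str(r.state5l): float(r.utility) for r in df.itertuples()})
        raise ValidationError(
            "crosswalk CSV needs (state5l, state3l, probability) or (state5l, utility) columns"
        )


# ---------------------------------------------------------------------------
# Toy tables (synthetic coefficients; real licensed tables are user-supplied)
# ---------------------------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def toy_valueset_5l() -> ValueSetTable:
    """Bundled synthetic 5L value set (NOT the licensed England set)."""
    return ValueSetTable.from_csv(_DATA_DIR / "toy_valueset_5l.csv")


def toy_valueset_3l() -> ValueSetTable:
    """Bundled synthetic 3L value set (NOT a licensed set)."""
    return ValueSetTable.from_csv(_DATA_DIR / "toy_valueset_3l.csv")


def toy_crosswalk(valueset_3l: Optional[ValueSetTable] = None) -> CrosswalkTable:
    """Deterministic synthetic crosswalk: 5L levels 1,2 -> 3L 1; 3 -> 2; 4,5 -> 3.

    Built programmatically (3125 states) so no large fixture ships; it is
    a stand-in for the published crosswalk, for testing and simulation only.
    """
    vs3 = valueset_3l or toy_valueset_3l()
    level_map = {1: 1, 2: 1, 3: 2, 4: 3, 5: 3}
    dists = {}
    for state in itertools.product(range(1, 6), repeat=5):
        s3 = "".join(str(level_map[v]) for v in state)
        dists[_state_str(state)] = [(s3, 1.0)]
    return CrosswalkTable(distributions=dists, valueset_3l=vs3)


# ---------------------------------------------------------------------------
# Scoring operations
# ---------------------------------------------------------------------------


def score_eq5d5l(response: PromResponse, valueset: ValueSetTable) -> float:
    """Utility of a 5L response under the active value set (<= 1.0)."""
    if response.eq5d is None:
        raise ValidationError("response carries no EQ5D levels")
    return valueset.utility(response.eq5d)


def crosswalk_5l_to_3l(response: PromResponse, crosswalk: CrosswalkTable) -> float:
    """Crosswalked 3L utility of a 5L response (expectation over mapped states)."""
    if response.eq5d is None:
        raise ValidationError("response carries no EQ5D levels")
    return crosswalk.utility(response.eq5d)


DEFAULT_REVERSE_ITEMS = (1, 3, 5)  # 1-based positions recoded as 6 - x


def score_drs(items: Sequence[int], reverse_items: Sequence[int] = DEFAULT_REVERSE_ITEMS) -> float:
    """Decision Regret Scale score in [0, 100]; 0 = no regret.

    Satisfaction-worded items (default positions 1, 3, 5) are recoded as
    6 - x, then score = (mean of recoded items - 1) * 25.
    """
    items = [int(v) for v in items]
    if len(items) != 5 or any(not 1 <= v <= 5 for v in items):
        raise ValidationError(f"DRS items must be five integers in 1..5: {items}")
    rev = set(reverse_items)
    recoded = [6 - v if (i + 1) in rev else v for i, v in enumerate(items)]
    return (float(np.mean(recoded)) - 1.0) * 25.0


# ---------------------------------------------------------------------------
# Longitudinal trajectory summaries
# ---------------------------------------------------------------------------


def summarize_trajectories(
    cohort: Sequence[PatientRecord],
    valueset: ValueSetTable,
    span: float = 0.75,
    grid: Optional[np.ndarray] = None,
    reverse_items: Sequence[int] = DEFAULT_REVERSE_ITEMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group, per-timepoint completion counts and means, plus LOESS curves.

    Completion counts are raw (no imputation); a timepoint with zero
    completions is reported with n = 0.  Curves are locally weighted
    (tricube, degree 1) regressions over the pooled (months, score)
    points, evaluated on a fixed monthly grid.
    """
    if grid is None:
        grid = np.linspace(0.0, 12.0, 25)
    points: dict = {}
    for p in cohort:
        if not p.proms:
            continue
        g = p.group.value if p.group is not None else "unknown"
        for r in p.proms:
            if r.eq5d is not None:
                points.setdefault((g, "utility"), []).append(
                    (r.months, score_eq5d5l(r, valueset))
                )
            if r.drs_items is not None:
                points.setdefault((g, "drs"), []).append(
                    (r.months, score_drs(r.drs_items, reverse_items))
                )
    groups = sorted({g for g, _ in points} | {
        p.group.value for p in cohort if p.group is not None and p.proms
    })

    rows = []
    for g in groups:
        for tp in TIMEPOINTS:
            m = TIMEPOINT_MONTHS[tp]
            utils = [u for t, u in points.get((g, "utility"), []) if t == m]
            drs = [d for t, d in points.get((g, "drs"), []) if t == m]
            rows.append(
                {
                    "group": g,
                    "timepoint": tp,
                    "months": m,
                    "n_eq5d": len(utils),
                    "mean_utility": float(np.mean(utils)) if utils else np.nan,
                    "n_drs": len(drs),
                    "mean_drs": float(np.mean(drs)) if drs else np.nan,
                }
            )
    table = pd.DataFrame(rows)

    curve_rows = []
    for g in groups:
        row: dict = {}
        for metric in ("utility", "drs"):
            pts = points.get((g, metric), [])
            if len(pts) >= 2:
                x = np.array([t for t, _ in pts])
                y = np.array([v for _, v in pts])
                if np.ptp(x) == 0:  # one observed timepoint: flat curve
                    smoothed = np.full_like(grid, float(y.mean()), dtype=float)
                else:
                    frac = max(span, min(1.0, 3.0 / len(pts)))
                    smoothed = lowess(
                        y, x, frac=frac, it=0, xvals=grid, return_sorted=False
                    )
                    bad = np.isnan(smoothed)
                    if bad.any() and (~bad).any():  # sparse windows: interpolate
                        smoothed[bad] = np.interp(grid[bad], grid[~bad], smoothed[~bad])
            elif len(pts) == 1:
                smoothed = np.full_like(grid, pts[0][1], dtype=float)
            else:
                smoothed = np.full_like(grid, np.nan, dtype=float)
            row[metric] = smoothed
        for i, m in enumerate(grid):
            curve_rows.append(
                {
                    "group": g,
                    "months": float(m),
                    "utility_smooth": float(row["utility"][i]),
                    "drs_smooth": float(row["drs"][i]),
                }
            )
    curves = pd.DataFrame(curve_rows)
    return table, curves
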
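"""Product-limit survival estimation and Markov transition hazards.

Kaplan-Meier estimation is implemented directly so the full risk table
(at-risk counts, events, censorings, Greenwood variance) is available to
the reporting layer and the cycle-hazard conversion; ``lifelines``
supplies the log-rank test and serves as an independent cross-check of
the estimator in the test suite.

Survival curves convert to per-cycle death probabilities for the
two-state Markov model: within observed follow-up from the step
function, beyond it by an exponential tail whose rate is matched to the
final third of the observed curve (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from lifelines.statistics import logrank_test

from .cohort import TestResult, ValidationError

Z_95 = 1.959963984540054


@dataclass
class KMEstimate:
    """Kaplan-Meier step function with risk table and Greenwood variance.

    ``times`` are the distinct observed times (months, ascending);
    ``survival[i]`` is S(times[i]) after processing events at that time
    (events before censorings at ties); ``greenwood_var[i]`` is the
    variance of the estimate at that step.
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t); S(0) = 1."""
        if t < 0:
            raise ValidationError("time must be non-negative")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def max_time(self) -> float:
        return float(self.times[-1])


def km_fit(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Product-limit estimate; at tied times events are processed first."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("no observations supplied")
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if (t < 0).any():
        raise ValidationError("negative survival times")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    n = t.size
    at_risk = np.empty(uniq.size, dtype=int)
    d = np.empty(uniq.size, dtype=int)
    c = np.empty(uniq.size, dtype=int)
    surv = np.empty(uniq.size)
    gw = np.empty(uniq.size)
    risk = n
    s = 1.0
    var_sum = 0.0  # Greenwood running sum of d / (n (n - d))
    for i, u in enumerate(uniq):
        mask = t == u
        di = int(e[mask].sum())
        ci = int(mask.sum() - di)
        at_risk[i] = risk
        d[i] = di
        c[i] = ci
        if di > 0:
            s *= 1.0 - di / risk
            if risk > di:
                var_sum += di / (risk * (risk - di))
        surv[i] = s
        gw[i] = s * s * var_sum if s > 0 else 0.0
        risk -= di + ci
    return KMEstimate(uniq, at_risk, d, c, surv, gw, n)


def median_survival(km: KMEstimate) -> Optional[float]:
    """Smallest observed time with S(t) <= 0.5; None if never reached."""
    below = np.nonzero(km.survival <= 0.5)[0]
    return float(km.times[below[0]]) if below.size else None


@dataclass
class SurvivalPoint:
    survival: float
    ci_lower: float
    ci_upper: float
    extrapolated: bool  # t lay beyond the last observed time


def survival_at(km: KMEstimate, t: float, alpha: float = 0.05) -> SurvivalPoint:
    """S(t) with a Greenwood log(-log) confidence interval.

    Beyond the last observed time the last value is carried forward and
    flagged; at S = 1 or S = 0 the interval is degenerate.
    """
    if t < 0:
        raise ValidationError("time must be non-negative")
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    extrapolated = t > km.max_time
    idx = np.searchsorted(km.times, min(t, km.max_time), side="right") - 1
    if idx < 0:
        return SurvivalPoint(1.0, 1.0, 1.0, extrapolated)
    s = float(km.survival[idx])
    v = float(km.greenwood_var[idx])
    if s <= 0.0 or s >= 1.0 or v <= 0.0:
        return SurvivalPoint(s, s, s, extrapolated)
    se_loglog = np.sqrt(v) / (s * abs(np.log(s)))
    lo = s ** np.exp(z * se_loglog)
    hi = s ** np.exp(-z * se_loglog)
    return SurvivalPoint(s, float(lo), float(hi), extrapolated)


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> TestResult:
    """Two-group log-rank test (1 df chi-square)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return TestResult(0.0, 1.0, "log_rank")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(float(res.test_statistic), float(res.p_value), "log_rank")


@dataclass(frozen=True)
class CycleHazard:
    cycle: int
    death_prob: float
    provenance: str  # observed | extrapolated

    def __post_init__(self) -> None:
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValidationError(f"cycle {self.cycle}: death probability outside [0, 1]")


def derive_cycle_death_probs(
    curve: Union[KMEstimate, Callable[[float], float]],
    cycle_length_years: float = 0.25,
    horizon_years: float = 15.0,
    extrapolation: str = "tail_third",
) -> list[CycleHazard]:
    """Per-cycle death probabilities p_k = 1 - S(t_{k+1}) / S(t_k).

    ``curve`` is a KM estimate (times in months) or a callable S(t months).
    Beyond observed follow-up an exponential tail is used with a rate
    fitted to the final third of the observed curve (``tail_third``,
    default) or to the whole curve (``full_curve``).  Once S reaches 0
    all subsequent probabilities are 1.
    """
    if cycle_length_years <= 0:
        raise ValidationError("cycle length must be positive")
    n_cycles = horizon_years / cycle_length_years
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        raise ValidationError("horizon must be a whole number of cycles")
    n_cycles = int(round(n_cycles))
    dt_months = cycle_length_years * 12.0

    if callable(curve):
        sfun, t_max = curve, np.inf
    else:
        sfun, t_max = curve.survival_at, curve.max_time
        if extrapolation not in ("tail_third", "full_curve"):
            raise ValidationError(f"unknown extrapolation token {extrapolation!r}")
        s_end = sfun(t_max)
        if s_end > 0 and t_max > 0:
            if extrapolation == "full_curve":
                lam = -np.log(s_end) / t_max  # per month
            else:
                t0 = (2.0 / 3.0) * t_max
                s0 = sfun(t0)
                lam = (np.log(s0) - np.log(s_end)) / (t_max - t0) if s0 > s_end else (
                    -np.log(s_end) / t_max
                )
        else:
            lam = np.inf
        p_tail = 1.0 if not np.isfinite(lam) else 1.0 - np.exp(-lam * dt_months)

    hazards = []
    for k in range(n_cycles):
        t_k, t_next = k * dt_months, (k + 1) * dt_months
        if t_next <= t_max:
            s_k, s_next = sfun(t_k), sfun(t_next)
            p = 1.0 if s_k <= 0 else min(1.0, max(0.0, 1.0 - s_next / s_k))
            hazards.append(CycleHazard(k, p, "observed"))
        else:
            s_k = sfun(min(t_k, t_max))
            p = 1.0 if s_k <= 0 else p_tail
            hazards.append(CycleHazard(k, p, "extrapolated"))
    return hazards
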
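"""Kaplan-Meier estimation, log-rank, and cycle-hazard derivation."""

import itertools

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from pexen.cohort import ValidationError
from pexen.survival import (
    derive_cycle_death_probs,
    km_fit,
    logrank,
    median_survival,
    survival_at,
)


def km_oracle(times, events):
    """Brute-force risk-set product-limit estimate at each distinct time."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for u in np.unique(times):
        at_risk = int((times >= u).sum())
        d = int(events[times == u].sum())
        if d:
            s *= 1 - d / at_risk
        out[float(u)] = s
    return out


def logrank_oracle(ta, ea, tb, eb):
    """Brute-force observed/expected accumulation over the pooled event times."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, bool)
    tb, eb = np.asarray(tb, float), np.asarray(eb, bool)
    pooled = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for u in pooled:
        n1 = int((ta >= u).sum())
        n2 = int((tb >= u).sum())
        d1 = int(ea[ta == u].sum())
        d2 = int(eb[tb == u].sum())
        n, d = n1 + n2, d1 + d2
        if n < 1 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


class TestKMFit:
    def test_all_events_stepwise_thirds(self):
        km = km_fit([1, 2, 3], [True, True, True])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert list(km.at_risk) == [3, 2, 1]

    def test_censoring_reduces_risk_set(self):
        km = km_fit([1, 2, 3], [False, True, True])
        assert km.survival_at(2) == pytest.approx(0.5)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        km = km_fit([5, 10, 15], [False, False, False])
        assert np.allclose(km.survival, 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_fit([], [])

    def test_exhaustive_small_datasets_match_risk_set_oracle(self):
        # every multiset of (time in {1,2,3}, event) observations up to n=5
        atoms = [(t, e) for t in (1.0, 2.0, 3.0) for e in (True, False)]
        count = 0
        for n in range(1, 6):
            for combo in itertools.combinations_with_replacement(atoms, n):
                times = [t for t, _ in combo]
                events = [e for _, e in combo]
                km = km_fit(times, events)
                oracle = km_oracle(times, events)
                for t, s in zip(km.times, km.survival):
                    assert s == pytest.approx(oracle[float(t)], abs=1e-12)
                count += 1
        assert count == 461  # all multisets of 6 atoms, sizes 1..5

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(3, 40)
            times = rng.integers(1, 15, n).astype(float)
            events = rng.uniform(size=n) < 0.7
            km = km_fit(times, events)
            kmf = KaplanMeierFitter().fit(times, events)
            for t in np.unique(times):
                assert km.survival_at(t) == pytest.approx(
                    float(kmf.predict(t)), abs=1e-10
                )


class TestMedianAndPointEstimates:
    def test_median_undefined_when_curve_stays_high(self):
        km = km_fit([1, 2, 3, 4], [True, False, False, False])
        assert median_survival(km) is None

    def test_median_of_three_events(self):
        km = km_fit([1, 2, 3], [True, True, True])
        assert median_survival(km) == 2.0

    def test_median_recovery_from_exponential_sample(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(12 / np.log(2), 10_000)
        km = km_fit(times, np.ones_like(times, dtype=bool))
        assert median_survival(km) == pytest.approx(12.0, rel=0.03)

    def test_survival_at_zero_and_before_first_event(self):
        km = km_fit([5, 8], [True, True])
        p0 = survival_at(km, 0.0)
        assert (p0.survival, p0.ci_lower, p0.ci_upper) == (1.0, 1.0, 1.0)
        assert survival_at(km, 4.9).survival == 1.0

    def test_survival_at_is_nonincreasing_in_t(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(20, 200)
        events = rng.uniform(size=200) < 0.8
        km = km_fit(times, events)
        ts = np.linspace(0, times.max() * 1.1, 50)
        vals = [survival_at(km, t).survival for t in ts]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_extrapolation_flagged_beyond_follow_up(self):
        km = km_fit([5, 8], [True, False])
        pt = survival_at(km, 20.0)
        assert pt.extrapolated
        assert pt.survival == km.survival_at(8)

    def test_loglog_ci_brackets_the_estimate(self):
        km = km_fit(list(range(1, 30)), [True, False] * 14 + [True])
        pt = survival_at(km, 10)
        assert pt.ci_lower < pt.survival < pt.ci_upper
        assert 0 < pt.ci_lower and pt.ci_upper < 1


class TestLogrank:
    def test_identical_groups_not_significant(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [True, True, False, True, False, True]
        res = logrank(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(21)
        a = rng.exponential(10, 100)
        res = logrank(a, np.ones(100, bool), 10 * a, np.ones(100, bool))
        assert res.p_value < 1e-6

    def test_no_events_returns_p_one_with_warning(self):
        with pytest.warns(UserWarning):
            res = logrank([1, 2], [False, False], [3, 4], [False, False])
        assert res.p_value == 1.0

    def test_matches_brute_force_oe_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            na, nb = rng.integers(3, 12, 2)
            ta = rng.integers(1, 8, na).astype(float)
            tb = rng.integers(1, 8, nb).astype(float)
            ea = rng.uniform(size=na) < 0.7
            eb = rng.uniform(size=nb) < 0.7
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank(ta, ea, tb, eb)
            assert res.statistic == pytest.approx(
                logrank_oracle(ta, ea, tb, eb), abs=1e-8
            )


class TestCycleHazards:
    def test_constant_hazard_from_exponential_curve(self):
        lam = np.log(2) / (10.5 * 12)  # per month, 10.5-year median
        probs = derive_cycle_death_probs(
            lambda t: np.exp(-lam * t), cycle_length_years=0.25, horizon_years=15
        )
        expected = 1 - 2 ** (-0.25 / 10.5)
        assert len(probs) == 60
        for h in probs:
            assert h.death_prob == pytest.approx(expected, abs=1e-12)
            assert h.provenance == "observed"

    def test_flat_curve_gives_zero_probs(self):
        probs = derive_cycle_death_probs(lambda t: 1.0)
        assert all(h.death_prob == 0.0 for h in probs)

    def test_recomposition_reproduces_step_function(self):
        rng = np.random.default_rng(17)
        times = rng.exponential(80, 400)
        events = rng.uniform(size=400) < 0.8
        km = km_fit(times, events)
        probs = derive_cycle_death_probs(km, 0.25, 15)
        s = 1.0
        for k, h in enumerate(probs):
            if h.provenance != "observed":
                break
            s *= 1 - h.death_prob
            assert s == pytest.approx(km.survival_at((k + 1) * 3.0), abs=1e-12)

    def test_constant_prob_recomposes_geometrically(self):
        s = [1.0]
        for _ in range(20):
            s.append(s[-1] * 0.9)
        # S(k cycles) = 0.9^k corresponds to p_k = 0.1 at every cycle
        probs = derive_cycle_death_probs(
            lambda t: 0.9 ** (t / 3.0), cycle_length_years=0.25, horizon_years=5
        )
        for h in probs:
            assert h.death_prob == pytest.approx(0.1, abs=1e-12)

    def test_extrapolated_cycles_marked_and_exponential(self):
        km = km_fit([6, 12, 24, 36], [True, True, True, False])
        probs = derive_cycle_death_probs(km, 0.25, 15)
        observed = [h for h in probs if h.provenance == "observed"]
        tail = [h for h in probs if h.provenance == "extrapolated"]
        assert observed and tail
        # exponential tail: constant per-cycle probability
        assert len({round(h.death_prob, 12) for h in tail}) == 1

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValidationError):
            derive_cycle_death_probs(lambda t: 1.0, 0.25, 15.1)
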
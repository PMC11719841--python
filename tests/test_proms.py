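"""EQ5D scoring, crosswalk, Decision Regret Scale, and trajectories."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pexen.cohort import PatientRecord, UKPENCode
from pexen.proms import (
    CrosswalkTable,
    PromResponse,
    TableIncompleteError,
    ValidationError,
    ValueSetTable,
    crosswalk_5l_to_3l,
    score_drs,
    score_eq5d5l,
    summarize_trajectories,
)


class TestScoreEQ5D:
    def test_full_health_anchor(self, vs5):
        assert score_eq5d5l(PromResponse("baseline", eq5d=(1, 1, 1, 1, 1)), vs5) == 1.0

    def test_single_decrement(self, vs5):
        assert score_eq5d5l(
            PromResponse("baseline", eq5d=(2, 1, 1, 1, 1)), vs5
        ) == pytest.approx(0.95)

    def test_sum_of_five_level3_decrements(self, vs5):
        assert score_eq5d5l(
            PromResponse("baseline", eq5d=(3, 3, 3, 3, 3)), vs5
        ) == pytest.approx(0.50)

    def test_missing_table_entry_raises(self):
        vs = ValueSetTable("additive_decrement", {(d, 1): 0.0 for d in range(5)})
        with pytest.raises(TableIncompleteError):
            vs.utility((2, 1, 1, 1, 1))

    @given(st.tuples(*[st.integers(1, 5)] * 5), st.integers(0, 4))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_nonincreasing_in_each_dimension(self, state, dim):
        from pexen.proms import toy_valueset_5l

        vs5 = toy_valueset_5l()
        if state[dim] == 5:
            return
        worse = tuple(v + 1 if i == dim else v for i, v in enumerate(state))
        assert vs5.utility(worse) <= vs5.utility(state)

    def test_invert_recovers_exact_states_lexicographic_ties(self, vs5):
        assert vs5.invert(1.0) == (1, 1, 1, 1, 1)
        # 0.95 is attainable by any single level-2; smallest state is last dim
        assert vs5.invert(0.95) == (1, 1, 1, 1, 2)
        assert vs5.utility(vs5.invert(0.512)) == pytest.approx(0.5)

    def test_csv_round_trip(self, vs5, tmp_path):
        path = tmp_path / "vs.csv"
        vs5.to_csv(path)
        again = ValueSetTable.from_csv(path)
        for state in [(1, 1, 1, 1, 1), (5, 4, 3, 2, 1), (2, 2, 2, 2, 2)]:
            assert again.utility(state) == pytest.approx(vs5.utility(state))


class TestCrosswalk:
    def test_degenerate_mapping_equals_target_utility(self, vs3):
        cw = CrosswalkTable(
            distributions={"11111": [("22222", 1.0)]}, valueset_3l=vs3
        )
        assert cw.utility((1, 1, 1, 1, 1)) == pytest.approx(vs3.utility((2, 2, 2, 2, 2)))

    def test_fifty_fifty_mix_is_expectation(self, vs3):
        # states valued 0.8 (21111 -> 1-0.1-0.1? no: single level-2 = 0.9)
        cw = CrosswalkTable(
            distributions={"11111": [("21111", 0.5), ("31111", 0.5)]}, valueset_3l=vs3
        )
        expected = 0.5 * vs3.utility((2, 1, 1, 1, 1)) + 0.5 * vs3.utility((3, 1, 1, 1, 1))
        assert cw.utility((1, 1, 1, 1, 1)) == pytest.approx(expected)

    def test_uniform_distribution_gives_valueset_mean(self, vs3):
        states3 = ["".join(map(str, s)) for s in itertools.product((1, 2, 3), repeat=5)]
        cw = CrosswalkTable(
            distributions={"11111": [(s, 1 / 243) for s in states3]}, valueset_3l=vs3
        )
        brute = np.mean([vs3.utility([int(c) for c in s]) for s in states3])
        assert cw.utility((1, 1, 1, 1, 1)) == pytest.approx(brute)

    def test_expectation_bounded_by_support(self, vs3, crosswalk):
        lo = min(vs3.utility(s) for s in itertools.product((1, 2, 3), repeat=5))
        for state in [(1, 2, 3, 4, 5), (5, 5, 5, 5, 5), (1, 1, 1, 1, 1)]:
            u = crosswalk.utility(state)
            assert lo <= u <= 1.0

    def test_uncovered_state_raises(self, vs3):
        cw = CrosswalkTable(distributions={"11111": [("11111", 1.0)]}, valueset_3l=vs3)
        with pytest.raises(TableIncompleteError):
            cw.utility((2, 1, 1, 1, 1))

    def test_bad_distribution_rejected(self, vs3):
        with pytest.raises(ValidationError):
            CrosswalkTable(
                distributions={"11111": [("11111", 0.6), ("21111", 0.6)]},
                valueset_3l=vs3,
            )

    def test_precomputed_csv_form(self, tmp_path):
        path = tmp_path / "cw.csv"
        path.write_text("state5l,utility\n11111,1.0\n21111,0.85\n")
        cw = CrosswalkTable.from_csv(path)
        assert cw.utility((2, 1, 1, 1, 1)) == pytest.approx(0.85)


def drs_oracle(items, reverse=(1, 3, 5)):
    recoded = [6 - v if i in reverse else v for i, v in enumerate(items, start=1)]
    return (sum(recoded) / 5.0 - 1.0) * 25.0


class TestScoreDRS:
    def test_scale_floor_no_regret(self):
        # satisfaction items fully endorsed, regret items fully rejected
        assert score_drs((5, 1, 5, 1, 5)) == 0.0

    def test_scale_ceiling_max_regret(self):
        assert score_drs((1, 5, 1, 5, 1)) == 100.0

    def test_midpoint(self):
        assert score_drs((3, 3, 3, 3, 3)) == 50.0

    def test_all_item_vectors_match_recode_and_average_oracle(self):
        for items in itertools.product(range(1, 6), repeat=5):
            assert score_drs(items) == pytest.approx(drs_oracle(items))

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValidationError):
            score_drs((0, 3, 3, 3, 3))

    @given(st.tuples(*[st.integers(1, 5)] * 5), st.integers(0, 4))
    @settings(derandomize=True, max_examples=150)
    def test_antitone_in_satisfaction_monotone_in_regret_items(self, items, pos):
        if items[pos] == 5:
            return
        bumped = tuple(v + 1 if i == pos else v for i, v in enumerate(items))
        delta = score_drs(bumped) - score_drs(items)
        if (pos + 1) in (1, 3, 5):  # satisfaction-worded: agreeing more lowers regret
            assert delta < 0
        else:
            assert delta > 0


class TestTrajectories:
    def _patient(self, pid, codes, proms):
        return PatientRecord(
            id=pid,
            codes=frozenset([UKPENCode.parse(c) for c in codes]),
            proms=proms,
            prom_participant=True,
        )

    def test_constant_data_gives_constant_curve(self, vs5):
        # utility 0.95 = one level-2 on the last dimension
        proms = [
            PromResponse(tp, eq5d=(1, 1, 1, 1, 2)) for tp in ("baseline", "m3", "m6", "m12")
        ]
        cohort = [self._patient("p0", ["C1"], proms)]
        table, curves = summarize_trajectories(cohort, vs5)
        grp = curves[curves.group == "conventional"]
        assert np.allclose(grp.utility_smooth, 0.95)

    def test_group_completion_counts_are_raw(self, vs5):
        conv = [
            self._patient(f"c{i}", ["C1"], [PromResponse("baseline", eq5d=(1, 1, 1, 1, 1))])
            for i in range(10)
        ]
        high = [
            self._patient(f"h{i}", ["P2"], [PromResponse("baseline", eq5d=(2, 1, 1, 1, 1))])
            for i in range(50)
        ]
        table, _ = summarize_trajectories(conv + high, vs5)
        base = table[table.timepoint == "baseline"].set_index("group")
        assert base.loc["conventional", "n_eq5d"] == 10
        assert base.loc["high_complexity", "n_eq5d"] == 50
        # zero-completion timepoints reported as n = 0, not dropped
        m12 = table[table.timepoint == "m12"]
        assert (m12.n_eq5d == 0).all()
        assert len(m12) == 2

    def test_full_span_loess_reproduces_linear_trend(self, vs5):
        # DRS scores lie exactly on a line in time; local linear smoothing
        # with full span must reproduce it
        pts = {0.0: 0.0, 3.0: 15.0, 6.0: 30.0, 12.0: 60.0}

        def items_for(score):
            # recoded item sum = score / 5 + 5; distribute greedily over items
            total = int(score / 5) + 5
            recoded = [1] * 5
            i = 0
            while sum(recoded) < total:
                if recoded[i] < 5:
                    recoded[i] += 1
                i = (i + 1) % 5
            return tuple(6 - v if p in (1, 3, 5) else v for p, v in enumerate(recoded, 1))

        cohort = []
        for i in range(3):
            proms = [
                PromResponse(tp, drs_items=items_for(pts[months]))
                for tp, months in (
                    ("baseline", 0.0), ("m3", 3.0), ("m6", 6.0), ("m12", 12.0),
                )
            ]
            cohort.append(self._patient(f"p{i}", ["C1"], proms))
        _, curves = summarize_trajectories(cohort, vs5, span=1.0, grid=np.array(list(pts)))
        grp = curves[curves.group == "conventional"]
        assert np.allclose(grp.drs_smooth.to_numpy(), list(pts.values()), atol=1e-6)
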
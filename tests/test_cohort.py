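"""Classifier, comparison statistics and cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from pexen.cohort import (
    ComplexityClass,
    Complication,
    DegenerateSampleError,
    Margin,
    PatientRecord,
    UKPENCode,
    ValidationError,
    classify_complexity,
    compare_categorical,
    compare_continuous,
    median_iqr,
    summarize_margins,
    summarize_morbidity,
)

CONV = ComplexityClass.CONVENTIONAL
HIGH = ComplexityClass.HIGH_COMPLEXITY


def codes(*tokens):
    return frozenset(UKPENCode.parse(t) for t in tokens)


class TestUKPENCode:
    def test_parse_and_str_roundtrip(self):
        for tok in ["P2", "A4", "SV0", "SN1", "PM2", "E5", "CC", "C3"]:
            assert str(UKPENCode.parse(tok)) == tok

    @pytest.mark.parametrize("bad", ["X2", "P9", "A8", "E0", "E6", "P", "2P"])
    def test_invalid_tokens_rejected(self, bad):
        with pytest.raises(ValidationError):
            UKPENCode.parse(bad)


class TestClassifyComplexity:
    @pytest.mark.parametrize(
        "toks, expected",
        [
            (("P1", "A3", "C3"), CONV),  # all at the conventional ceiling
            (("P1", "PM2"), HIGH),  # pelvic musculature above threshold
            (("P1", "E5"), CONV),  # E5 never counts
            (("P2",), HIGH),
            (("A4",), HIGH),
            (("SV1",), HIGH),
            (("SN1",), HIGH),
            (("E1",), HIGH),
            (("E4",), HIGH),
            (("C3", "SV0", "SN0", "PM1"), CONV),
            (("C1", "CC"), CONV),  # coccygectomy marker ignored
        ],
    )
    def test_threshold_rules(self, toks, expected):
        assert classify_complexity(codes(*toks)) is expected

    def test_historical_codes_merged_before_classification(self):
        assert classify_complexity(codes("C1"), historical_codes=codes("A4")) is HIGH

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            classify_complexity(frozenset())

    @given(
        st.sets(
            st.sampled_from(
                ["P0", "P1", "P2", "P3", "A1", "A3", "A4", "C1", "C3",
                 "SV0", "SV1", "SN0", "SN1", "PM1", "PM2", "E1", "E4", "E5", "CC"]
            ),
            min_size=1,
            max_size=6,
        ),
        st.sampled_from(["P2", "A4", "SV1", "SN1", "PM2", "E1"]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_adding_codes_never_downgrades(self, toks, extra):
        base = classify_complexity(codes(*toks))
        extra_code = UKPENCode.parse(extra)
        merged = {c for c in codes(*toks) if c.compartment != extra_code.compartment
                  or c.compartment == "E"} | {extra_code}
        assert classify_complexity(frozenset(merged)) is HIGH
        if base is HIGH:
            assert classify_complexity(codes(*toks) | codes("E5", "CC")) is HIGH

    @given(
        st.sets(
            st.sampled_from(
                ["P0", "P1", "P2", "A1", "A4", "C1", "C3", "SV1", "SN1", "PM1", "PM2", "E2"]
            ),
            min_size=1,
            max_size=5,
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_invariant_to_e5_and_coccygectomy(self, toks):
        base = classify_complexity(codes(*toks))
        assert classify_complexity(codes(*toks) | codes("E5", "CC")) is base


class TestCompareContinuous:
    def test_identical_nonnormal_samples_give_mann_whitney_p_one(self):
        a = [1.0, 1.0, 1.0, 2.0, 2.0, 9.0, 9.0, 9.0, 30.0, 30.0]
        res = compare_continuous(a, list(a))
        assert res.method == "mann_whitney"
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_samples_give_u_zero(self):
        # all 25 pairwise comparisons favour b, so U for group a is 0
        # (alpha_normality=1 forces the nonparametric route)
        res = compare_continuous(
            [1, 2, 3, 4, 5], [10, 20, 30, 40, 50], alpha_normality=1.0
        )
        assert res.method == "mann_whitney"
        assert res.statistic == 0.0

    def test_normal_samples_route_to_t_test(self):
        rng = np.random.default_rng(42)
        res = compare_continuous(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        assert res.method == "t_test"

    def test_t_test_rejection_rate_near_alpha_under_null(self):
        # repeated equal-mean normal samples: ~5% of p-values below 0.05
        rng = np.random.default_rng(7)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            res = compare_continuous(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
            rejections += res.p_value < 0.05
        assert 0.02 < rejections / n_reps < 0.09

    def test_degenerate_identical_constants_rejected(self):
        with pytest.raises(DegenerateSampleError):
            compare_continuous([5.0] * 5, [5.0] * 5)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            compare_continuous([1.0, 2.0], [1.0, 2.0, 3.0])


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestCompareCategorical:
    def test_homogeneous_table_p_one(self):
        res = compare_categorical([[10, 10], [10, 10]])
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_separation_fisher(self):
        res = compare_categorical([[5, 0], [0, 5]])
        assert res.method == "fisher"
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_large_table_uses_chi_square(self):
        res = compare_categorical([[52, 8], [210, 42]])
        assert res.method == "chi_square"
        assert res.p_value > 0.05  # margin status not significant

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            compare_categorical([[1, -1], [2, 3]])

    @given(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
    @settings(derandomize=True, max_examples=300)
    def test_fisher_matches_exact_enumeration_oracle(self, a, b, c, d):
        table = np.array([[a, b], [c, d]])
        if (table.sum(axis=0) <= 0).any() or (table.sum(axis=1) <= 0).any():
            return
        res = compare_categorical(table)
        if res.method == "fisher":
            assert res.p_value == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), abs=1e-9
            )

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 8))
    @settings(derandomize=True, max_examples=100)
    def test_proportional_rows_give_p_near_one(self, x, y, mult):
        res = compare_categorical([[x, y], [x * mult, y * mult]])
        assert res.p_value >= 0.999


def _patient(i, margin, benign=False, grades=()):
    return PatientRecord(
        id=f"p{i}",
        codes=frozenset([UKPENCode.parse("C1")]),
        margin=margin,
        benign_flag=benign,
        complications=[Complication(g, per) for g, per in grades],
    )


class TestSummaries:
    def test_margin_percentages_from_counts(self):
        cohort = (
            [_patient(i, Margin.R0) for i in range(52)]
            + [_patient(100 + i, Margin.R1_CONTINUOUS) for i in range(4)]
            + [_patient(200 + i, Margin.R1_DISCONTINUOUS) for i in range(3)]
            + [_patient(300, Margin.R2)]
            + [_patient(400 + i, Margin.NOT_APPLICABLE, benign=True) for i in range(4)]
        )
        s = summarize_margins(cohort)
        assert s.n_eligible == 60
        assert s.percents["R0"] == 87
        assert s.counts == {"R0": 52, "R1": 7, "R2": 1}
        # percentages over included patients sum to 100 within rounding
        assert abs(sum(s.percents.values()) - 100) <= 2

    def test_both_margins_patient_counted_once_but_in_both_splits(self):
        cohort = [
            _patient(0, Margin.R1_BOTH),
            _patient(1, Margin.R1_CONTINUOUS),
            _patient(2, Margin.R0),
        ]
        s = summarize_margins(cohort)
        assert s.counts["R1"] == 2
        assert s.r1_continuous == 2
        assert s.r1_discontinuous == 1

    def test_all_benign_cohort_flagged_empty(self):
        cohort = [_patient(i, Margin.NOT_APPLICABLE, benign=True) for i in range(3)]
        s = summarize_margins(cohort)
        assert s.empty and s.n_eligible == 0

    def test_morbidity_counts_once_per_period(self):
        cohort = [
            _patient(0, Margin.R0, grades=[("2", "index_admission"), ("3b", "index_admission")]),
            _patient(1, Margin.R0, grades=[("3a", "later")]),
            _patient(2, Margin.R0, grades=[("1", "index_admission")]),
            _patient(3, Margin.R0),
        ]
        s = summarize_morbidity(cohort)
        assert (s.index_count, s.overall_count) == (1, 2)
        assert (s.index_percent, s.overall_percent) == (25, 50)

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValidationError):
            Complication("6", "later")

    def test_median_iqr_linear_interpolation(self):
        med, iqr = median_iqr([1, 2, 3, 4])
        assert med == pytest.approx(2.5)
        assert iqr == pytest.approx(1.5)
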
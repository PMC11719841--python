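"""Descriptive/comparative cohort tables.

Builds the two-group baseline-characteristics and secondary-outcomes
tables as machine-readable DataFrames: continuous rows as median (IQR)
with normality-routed tests, categorical rows as n (%) with Fisher or
chi-square tests.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    ComplexityClass,
    DIAGNOSES,
    DegenerateSampleError,
    Margin,
    PatientRecord,
    RECONSTRUCTIONS,
    ValidationError,
    compare_categorical,
    compare_continuous,
    median_iqr,
    summarize_margins,
    summarize_morbidity,
)


def split_groups(cohort: Sequence[PatientRecord]) -> tuple[list, list]:
    conv = [p for p in cohort if p.group is ComplexityClass.CONVENTIONAL]
    high = [p for p in cohort if p.group is ComplexityClass.HIGH_COMPLEXITY]
    return conv, high


def _safe_categorical_p(table) -> float:
    try:
        return compare_categorical(table).p_value
    except (ValidationError, DegenerateSampleError):
        return float("nan")


def _safe_continuous_p(a, b) -> float:
    try:
        return compare_continuous(a, b).p_value
    except (ValidationError, DegenerateSampleError):
        return float("nan")


def _cat_rows(
    name: str, conv: list, high: list, levels: Sequence, key: Callable
) -> list[dict]:
    counts = {
        lvl: (sum(key(p) == lvl for p in conv), sum(key(p) == lvl for p in high))
        for lvl in levels
    }
    arr = np.array(
        [[counts[lvl][0] for lvl in levels], [counts[lvl][1] for lvl in levels]]
    )
    arr = arr[:, arr.sum(axis=0) > 0]  # drop unobserved levels before testing
    p = _safe_categorical_p(arr) if arr.shape[1] >= 2 else float("nan")
    rows = []
    for i, lvl in enumerate(levels):
        c, h = counts[lvl]
        rows.append(
            {
                "characteristic": f"{name}: {lvl}",
                "conventional": f"{c} ({0 if not conv else round(100 * c / len(conv))})",
                "high_complexity": f"{h} ({0 if not high else round(100 * h / len(high))})",
                "p_value": p if i == 0 else np.nan,
            }
        )
    return rows


def _cont_row(name: str, conv_vals, high_vals) -> dict:
    m1, iqr1 = median_iqr(conv_vals)
    m2, iqr2 = median_iqr(high_vals)
    return {
        "characteristic": name,
        "conventional": f"{m1:g} ({iqr1:g})",
        "high_complexity": f"{m2:g} ({iqr2:g})",
        "p_value": _safe_continuous_p(list(conv_vals), list(high_vals)),
    }


def baseline_table(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Baseline characteristics by complexity group with comparison p-values."""
    conv, high = split_groups(cohort)
    rows: list[dict] = [
        {
            "characteristic": "Sample size, n (%)",
            "conventional": f"{len(conv)} ({round(100 * len(conv) / len(cohort))})",
            "high_complexity": f"{len(high)} ({round(100 * len(high) / len(cohort))})",
            "p_value": np.nan,
        }
    ]
    rows += _cat_rows("Sex", conv, high, ["female", "male"], lambda p: p.sex)
    rows.append(_cont_row("Median age, years (IQR)",
                          [p.age for p in conv if p.age is not None],
                          [p.age for p in high if p.age is not None]))
    rows.append(_cont_row("BMI (IQR)",
                          [p.bmi for p in conv if p.bmi is not None],
                          [p.bmi for p in high if p.bmi is not None]))
    rows += _cat_rows("Diagnosis", conv, high, list(DIAGNOSES), lambda p: p.diagnosis)
    rows += _cat_rows(
        "Cancer status", conv, high, ["primary", "recurrent"],
        lambda p: "primary" if p.cancer_primary else "recurrent",
    )
    rows += _cat_rows(
        "Metastatic disease", conv, high, [True, False], lambda p: p.cancer_metastatic
    )
    rows += _cat_rows(
        "Type of exenteration", conv, high, ["supralevator", "infralevator"],
        lambda p: p.exenteration_level,
    )
    rows += _cat_rows(
        "Reconstruction", conv, high, list(RECONSTRUCTIONS), lambda p: p.reconstruction
    )
    return pd.DataFrame(rows)


def outcomes_table(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Secondary outcomes (margins, morbidity, follow-up) by complexity group."""
    conv, high = split_groups(cohort)
    rows: list[dict] = []

    mort = []
    for label, grp in (("conventional", conv), ("high_complexity", high)):
        mort.append(sum(1 for p in grp if p.survival_event and p.survival_time <= 3.0))
    rows.append(
        {
            "characteristic": "90-day mortality",
            "conventional": str(mort[0]),
            "high_complexity": str(mort[1]),
            "p_value": _safe_categorical_p(
                [[mort[0], len(conv) - mort[0]], [mort[1], len(high) - mort[1]]]
            ),
        }
    )

    ms_c, ms_h = summarize_margins(conv), summarize_margins(high)
    margin_p = _safe_categorical_p(
        [
            [ms_c.counts["R0"], ms_c.n_eligible - ms_c.counts["R0"]],
            [ms_h.counts["R0"], ms_h.n_eligible - ms_h.counts["R0"]],
        ]
    )
    for i, key in enumerate(("R0", "R1", "R2")):
        rows.append(
            {
                "characteristic": f"Margin status: {key}",
                "conventional": f"{ms_c.counts[key]} ({ms_c.percents[key]})",
                "high_complexity": f"{ms_h.counts[key]} ({ms_h.percents[key]})",
                "p_value": margin_p if i == 0 else np.nan,
            }
        )
    rows.append(
        {
            "characteristic": "Continuous R1",
            "conventional": str(ms_c.r1_continuous),
            "high_complexity": str(ms_h.r1_continuous),
            "p_value": _safe_categorical_p(
                [
                    [ms_c.r1_continuous, ms_c.r1_discontinuous],
                    [ms_h.r1_continuous, ms_h.r1_discontinuous],
                ]
            )
            if min(ms_c.counts["R1"], ms_h.counts["R1"]) > 0
            else np.nan,
        }
    )
    rows.append(
        {
            "characteristic": "Discontinuous R1",
            "conventional": str(ms_c.r1_discontinuous),
            "high_complexity": str(ms_h.r1_discontinuous),
            "p_value": np.nan,
        }
    )

    mo_c, mo_h = summarize_morbidity(conv), summarize_morbidity(high)
    for label, cc, hh in (
        ("Index admission major complications", mo_c.index_count, mo_h.index_count),
        ("Overall major complications", mo_c.overall_count, mo_h.overall_count),
    ):
        rows.append(
            {
                "characteristic": label,
                "conventional": f"{cc} ({round(100 * cc / mo_c.n)})",
                "high_complexity": f"{hh} ({round(100 * hh / mo_h.n)})",
                "p_value": _safe_categorical_p(
                    [[cc, mo_c.n - cc], [hh, mo_h.n - hh]]
                ),
            }
        )

    rows.append(
        _cont_row(
            "Median follow-up time, months (IQR)",
            [p.survival_time for p in conv],
            [p.survival_time for p in high],
        )
    )
    return pd.DataFrame(rows)
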
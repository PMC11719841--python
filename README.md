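# pexen

Outcomes and cost–utility analysis for pelvic exenteration (PE) cohorts,
comparing **conventional** against **high-complexity** PE.

Pelvic exenteration is a radical multi-organ resection for advanced pelvic
cancer. Modern practice extends the operation to pelvic bone, sidewall
nerves/vessels and beyond ("high-complexity" PE), raising questions about
morbidity, quality of life and cost-effectiveness relative to conventional
central-compartment surgery. `pexen` implements the full comparative
analysis pipeline for such cohorts, aimed at surgical-outcomes researchers
and health-economics analysts:

- **UKPEN complexity classification** — patients are labelled from their
  UKPEN lexicon codes: conventional iff all codes are at or below
  P1 / A3 / C3 / SV0 / SN0 / PM1; anything at P≥2, A≥4, SV≥1, SN≥1, PM≥2 or
  an E1–E4 component is high-complexity. E5 components and coccygectomy
  alone never count. Historical pelvic resections merge into the code set
  before classification.
- **Comparative tables** — median (IQR) with Shapiro–Wilk-routed
  Mann–Whitney/t tests for continuous rows; Fisher or chi-square
  (Cochran's rule) for categorical rows; margin-status and
  Clavien–Dindo ≥ 3a morbidity summaries.
- **PROM scoring** — EQ5D-5L utilities under a pluggable value set,
  5L→3L crosswalk for the economic model, Decision Regret Scale (0–100)
  scoring, and LOESS-smoothed longitudinal trajectories with raw
  completion counts (no imputation).
- **Bottom-up costing** — per-patient resource lines priced from a
  unit-cost table, aggregated by category (theatres, admission, unplanned
  radiology, re-interventions), Welch t-tests and Bonferroni-corrected
  ANOVA contrasts for the perineal-reconstruction sub-analysis.
- **Survival** — Kaplan–Meier estimation with Greenwood log(−log)
  confidence intervals, log-rank tests, and conversion of survival curves
  into per-cycle transition probabilities.
- **Markov cost–utility model** — a two-state (alive/dead) time-varying
  cohort model over a 15-year horizon in 3-month cycles with annual 3.5%
  discounting, a no-surgery comparator arm calibrated to published
  totals, incremental cost-effectiveness ratios

  ICER = (C_PE − C_noPE) / (Q_PE − Q_noPE)  [GBP per QALY],

  and one-at-a-time deterministic sensitivity analysis.
- **Synthetic cohort generator** — seeded simulation of the full
  two-group cohort (n = 64 conventional / 255 high-complexity by default)
  with Weibull survival calibrated jointly to group medians and 5-year
  rates, gamma cost marginals, morbidity/margin/diagnosis mixes and
  PROM trajectories, so the whole pipeline is testable without any
  patient-level data.

Value-set and crosswalk coefficients are licensed and therefore **not
bundled**; synthetic "toy" tables ship for testing, and real tables are
supplied as CSVs in the same dialect.

## Worked example

Run the cost–utility stage on a simulated default cohort (seed 1):

```bash
pexen cua --seed 1 --out demo_out
```

```
            arm  total_qalys  total_costs  cost_per_qaly  icer_vs_no_pe     status
   conventional     6.337995 39047.423230    6160.847834    1129.323967       icer
high_complexity     6.221950 44285.276604    7117.587749    2252.067907       icer
          no_pe     1.440000 33516.000000   23275.000000            NaN comparator
```

Each surgical arm's survival comes from the simulated cohort's
Kaplan–Meier curve (exponential tail beyond follow-up), its utility
vector from crosswalked EQ5D responses carried forward past 12 months,
and its cycle-0 lump cost from the bottom-up perioperative means. The
no-surgery arm is calibrated so the engine reproduces its published
totals (33,516 GBP, 1.44 QALYs). Discounted QALYs near 6 for surgery
against 1.44 without it put both ICERs in the low thousands of GBP per
QALY — far below the 30,000 GBP/QALY willingness-to-pay threshold —
with high-complexity PE costlier per QALY than conventional PE.

Other subcommands: `simulate`, `classify`, `tables`, `proms`, `costs`,
`survival`, `dsa`, and `all` (full bundle: CSV tables, KM risk tables,
Markov trace, DSA scenario table, and a JSON run manifest with the seed
and config hash for exact reproduction).

As a library:

```python
from pexen import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(out_dir="demo_out", seed=1))
print(bundle["cua"])          # Markov cost-utility summary
print(bundle["dsa"].max_icer) # worst-case ICERs under scenario stress
```

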
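# Methods

This note documents the models implemented in `pexen`, the defaults and
the reasoning behind them, what the synthetic generator does and does not
emulate, and the numerical conventions used throughout.

## Complexity classification

The UKPEN lexicon codes the anatomical extent of a pelvic exenteration
per compartment (P posterior, A anterior, C central, SV sidewall
vessels, SN sidewall nerves, PM pelvic musculature, E extra-pelvic).
A resection is **high-complexity** if the merged code set (current plus
any historical pelvic resections) contains P≥2, A≥4, SV≥1, SN≥1, PM≥2 or
an E1–E4 component; otherwise it is **conventional**. E5 components
(oligometastatic / incidental resections) and a coccygectomy-alone
marker (`CC`) are recorded but never influence the decision. The
classifier is monotone: adding codes can only move a patient towards
high-complexity.

The classifier validates tokens against configured level ranges
(P 0–4, A 0–7, C 0–3, SV/SN/PM 0–3, E 1–5). The full lexicon's ranges
live in its own publication; the configuration covers every code the
pipeline emits or consumes and rejects anything else by name.

## Comparative statistics

Continuous two-group rows use Shapiro–Wilk routing at α = 0.05: if
either group rejects normality (or is constant, where normality is
untestable), a two-sided Mann–Whitney U test is used, otherwise a Welch
t-test. The Mann–Whitney p-value uses the tie-corrected normal
approximation **without** continuity correction so that identical
samples yield p = 1 exactly; at the sample sizes of these tables the
difference from the exact distribution is negligible.

Categorical rows use Cochran's rule: Fisher's exact test when any
expected cell count is below 5, else Pearson chi-square (no Yates
correction). The exact test is implemented for 2×2 tables; larger
sparse tables fall back to the chi-square statistic — r×c exact tests
(Freeman–Halton) are not provided. The margin-status comparison pools to
R0 vs non-R0, a 2×2 test.

Margin summaries exclude benign / not-applicable patients from the
denominator. A specimen with both continuous and discontinuous R1
margins counts once in the R1 denominator but appears in both
sub-splits. Morbidity counts a patient once per period if **any**
Clavien–Dindo ≥ 3a complication occurred in that period; overall = index
admission ∪ later. Continuous summaries report median (IQR) with
IQR = Q3 − Q1 under linear-interpolation quantiles.

## PROM scoring

EQ5D-5L responses (five dimensions × five levels) are valued under a
pluggable value set in either *additive-decrement* form (utility = 1 −
sum of per-dimension decrements; level-1 decrements must be 0 so state
11111 anchors at 1.0) or *full-enumeration* form. For cost–utility
inputs, 5L responses are crosswalked to 3L utilities: either an expected
utility over a per-state 3L distribution, or a precomputed per-state
utility. Real (licensed) coefficient tables are user-supplied CSVs; the
bundled tables carry synthetic coefficients for testing only.

The Decision Regret Scale is scored per its manual convention: the
satisfaction-worded items (positions 1, 3, 5 by default, configurable)
are recoded as 6 − x, then score = (mean of recoded items − 1) × 25,
giving 0 (no regret) to 100 (maximal regret).

Longitudinal trajectories are summarised per group and timepoint with
raw completion counts (no imputation; a timepoint with zero completions
reports n = 0) and smoothed with locally weighted regression (tricube
weights, degree 1, default span 0.75, no robustness iterations) over the
pooled (months, score) points on a fixed monthly grid. With fewer than
three points per window the span widens automatically, and isolated
undefined grid values are filled by linear interpolation; a single
observed timepoint yields a flat curve.

## Bottom-up costing

Per-line cost = quantity × unit cost; lines aggregate into categories
(theatres, admission, unplanned radiology, re-intervention, other) and
the overall total is the category sum — an exact linear functional of
the resource quantities. Group comparisons use Welch t-tests (group SDs
differ markedly, so the unequal-variance form is the safer reading of a
"Student t-test"); the reconstruction sub-analysis uses one-way ANOVA on
overall costs plus pairwise Welch tests with Bonferroni multiplication
over the three contrasts, capped at 1. Zero-variance groups with equal
means return p = 1 by convention. Currency is exact GBP internally;
rounding happens only in rendered reports.

## Survival

Kaplan–Meier estimation processes events before censorings at tied
times and records the full risk table (at-risk, events, censorings) with
Greenwood variance. Point estimates carry log(−log S) confidence
intervals (degenerate at S = 0 or 1). Median survival is the smallest
observed time with S(t) ≤ 0.5, undefined if never reached. The log-rank
test is delegated to `lifelines`; the estimator itself is implemented
directly because the cycle-hazard conversion and the reporting layer
need the exact step table, and `lifelines` serves as an independent
cross-check in the test suite.

Survival curves convert to per-cycle death probabilities
p_k = 1 − S(t_{k+1})/S(t_k) within observed follow-up. Beyond follow-up
an exponential tail is used, with rate matched to the final third of the
observed curve by default (`tail_third`; `full_curve` matches the whole
curve). An exponential tail is the most conservative standard
extrapolation for health-technology assessment; the token is
configurable so parametric alternatives can be swapped in. Once S
reaches 0, all subsequent probabilities are 1.

## Markov cost–utility model

Two states (alive/dead), cycle length 0.25 years, horizon 15 years,
annual discount rate 3.5% applied identically to costs and QALYs, all
configurable. Occupancy follows a_0 = 1, a_{k+1} = a_k(1 − p_k). Per
cycle, QALYs accrue as occ_k · u_k · Δ · (1+r)^{−kΔ} and costs as
occ_k · c_k · (1+r)^{−kΔ}, with occupancy valued at cycle start by
default. Half-cycle correction (occ = adjacent average) is exposed as a
flag and **off** by default — cycle-start valuation reproduces the
published table arithmetic most directly — and the cycle-0 lump cost is
never half-cycled. Both discounted and undiscounted totals are
reported, since published totals do not state which convention they use.

Surgical arms are built from the cohort itself: death probabilities from
the group KM curve, a utility vector from the group's mean crosswalked
utilities at baseline/3/6/12 months (linear interpolation at unobserved
cycles, flat carry-forward beyond 12 months — post-operative HrQoL
plateaus toward a "new normal"), and a cycle-0 lump equal to the group's
mean bottom-up perioperative cost with a configurable follow-up cost per
cycle (default 0: the collected costs are perioperative). Missing
timepoint means are bridged by the same interpolation rule; this is a
documented local convention, as the upstream handling it stands in for
is not specified.

The no-surgery comparator is not observed at patient level. It is
calibrated so the engine reproduces externally published totals
(default 33,516 GBP and 1.44 QALYs) under a structural shape:
exponential survival with an 18-month median (untreated advanced pelvic
cancer survives roughly 12–18 months) and a utility profile declining
linearly from baseline to zero at the horizon (quality of life
deteriorates until death), with costs accruing uniformly per cycle while
alive. Two scale parameters — a utility scale (clipped at 1) and a cost
scale — are solved by bisection (`brentq`, xtol 1e-12/1e-9) and the
calibrated arm is verified by re-running the engine to within 0.1% of
both targets. Cost and QALY calibration are separable: doubling the
cost target doubles the cost schedule and leaves survival untouched.

Incremental comparisons report ICER = ΔC/ΔQ when ΔQ > 0 and ΔC > 0,
`dominant`/`dominated` tokens for the unambiguous quadrants,
`equivalent` when both increments are zero, and never divide by a zero
QALY increment. Deterministic sensitivity analysis applies one scenario
at a time to fresh copies of the arms — defaults: ±50% comparator
costs, ±20% surgical-arm utilities (clipped at 1), ±20% surgical-arm
costs — and tabulates scenario ICERs plus the per-arm maximum.

## Synthetic cohort generator

The generator emulates the *published group-level structure*, not the
source database: exact group sizes (64/255), Weibull overall survival
solved in closed form from two constraints per group (median 10.5/9.8
years **and** 5-year survival 72.1%/70.9% — an exponential cannot match
both, which is why Weibull is the default and exponential a degenerate
option), uniform administrative censoring over a 14-year accrual window,
index/overall major-morbidity rates (8%→16% and 20%→31%) with the
overall rate enforced exactly via the conditional later-complication
probability, margin and diagnosis mixes from the published counts,
infralevator fractions and reconstruction mixes, and per-category gamma
cost marginals (shape = mean²/sd², scale = sd²/mean; non-negative and
right-skewed like hospital costs) with the published means/SDs. The
small residual between the published overall mean cost and the category
sum in the conventional group (37,271 vs 37,272) is absorbed into the
admission category, the largest and least-specified one.

PROM trajectories use a latent-utility model: baseline mean 0.80 (a
placeholder convention — no baseline utility is published) minus
timepoint dips, Gaussian noise (SD 0.10), clamped to the value set's
attainable range and inverted to the nearest attainable EQ5D-5L state
(ties broken to the lexicographically smallest state). The
high-complexity group dips equally at 3 months but recovers less by 12
months, and its baseline anticipatory regret is higher, mirroring the
published trajectory shapes. Dropout is missing-completely-at-random
per timepoint; participation fractions (10/64 and 50/255) mirror the
published PROM sub-cohort.

Randomness is organised as named substreams (`SeedSequence` on
(seed, CRC32(label))): adding a sampler never perturbs another
component's draws, and a fixed seed reproduces the cohort exactly.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: correlation between cost categories
(the overall cost SD is therefore smaller than published, though
category SDs match); any dependence of survival, costs or PROMs on
covariates, margins or morbidity (all sampled independently);
informative PROM dropout (patients with worse outcomes may engage less —
the MCAR switch exists precisely to probe this); and within-lexicon
anatomical realism beyond what the classifier needs.

## Numerical conventions and test design

- Published summary tables are treated as *inputs* where the analysis
  is pure arithmetic on them (incremental ratios, cost differences,
  rate percentages); everything else is recomputed from simulated or
  supplied patient-level data.
- KM median recovery at n = 10,000/group has a relative standard error
  of about 1.8% (the hazard is nearly flat at the median), so the 3%
  recovery checks in the test suite run at a fixed seed.
- Exhaustive estimator checks enumerate all multisets of
  (time ∈ {1,2,3}, event) observations up to n = 8 (3,002 datasets)
  against a brute-force risk-set oracle; the log-rank statistic is
  checked against direct observed-minus-expected accumulation over all
  pairs of such datasets up to n = 3.
- Ties in value-set inversion break to the lexicographically smallest
  state; equidistant utilities compare candidate states directly.
- Quantiles are linear-interpolation; percentages in rendered tables are
  integer-rounded; all internal arithmetic is double precision.

## Limitations

- The comparator arm is illustrative: its shape (exponential survival,
  linearly declining utility, uniform costs) is a structural assumption
  calibrated to two scalar targets, not an observed cohort.
- The generator's independence assumptions understate real-world
  correlation; recovered joint statistics (e.g. cost–survival
  relationships) are not meaningful.
- No covariate adjustment, propensity scoring or Cox modelling is
  provided; the comparisons are unadjusted by design.
- The bundled value-set/crosswalk tables are synthetic. Utilities and
  downstream QALYs computed from them are internally consistent but not
  comparable to results under licensed tariffs.
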
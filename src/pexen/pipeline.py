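"""End-to-end orchestration.

``run_pipeline`` drives the full analysis: generate or load a cohort,
classify complexity, build the descriptive tables, score and summarise
PROMs, cost patients bottom-up and compare groups, estimate survival,
assemble the Markov arms, compute ICERs against the calibrated
no-surgery comparator, and run the deterministic sensitivity analysis.
All outputs are CSV plus a JSON run manifest (seed, config hash, stage
row counts) from which a run is exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cohort_io
from .cohort import ComplexityClass, PatientRecord, ValidationError
from .costing import (
    CostBreakdown,
    UnitCostTable,
    compare_reconstruction_costs,
    compare_two_group_costs,
    cost_patient,
)
from .markov import (
    ArmSpec,
    NoSurgeryShape,
    compute_icer,
    calibrate_no_pe_arm,
    default_scenarios,
    run_dsa,
    run_markov,
)
from .proms import (
    TIMEPOINT_MONTHS,
    TIMEPOINTS,
    CrosswalkTable,
    ValueSetTable,
    crosswalk_5l_to_3l,
    summarize_trajectories,
    toy_crosswalk,
    toy_valueset_5l,
)
from .survival import derive_cycle_death_probs, km_fit, logrank, median_survival, survival_at
from .synthetic import default_spec, generate_cohort, synthetic_unit_costs
from .tables import baseline_table, outcomes_table, split_groups

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of cohort_dir / use_generator."""

    out_dir: str = "pexen_out"
    seed: int = 0
    cohort_dir: Optional[str] = None
    use_generator: bool = True
    unit_cost_csv: Optional[str] = None
    valueset_csv: Optional[str] = None
    crosswalk_csv: Optional[str] = None
    half_cycle_correction: bool = False
    extrapolation: str = "tail_third"
    cycle_length_years: float = 0.25
    horizon_years: float = 15.0
    discount_rate_annual: float = 0.035
    followup_cost_per_cycle: float = 0.0
    no_pe_target_cost: float = 33516.0
    no_pe_target_qalys: float = 1.44
    no_pe_median_survival_months: float = 18.0

    def __post_init__(self) -> None:
        if bool(self.cohort_dir) == bool(self.use_generator):
            raise ValidationError(
                "supply exactly one of cohort_dir / use_generator"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def mean_crosswalked_utilities(
    cohort: Sequence[PatientRecord], crosswalk: CrosswalkTable
) -> dict:
    """Per-group mean crosswalked utility at each PROM timepoint (NaN if none)."""
    out: dict = {}
    for group in (ComplexityClass.CONVENTIONAL, ComplexityClass.HIGH_COMPLEXITY):
        vals = {tp: [] for tp in TIMEPOINTS}
        for p in cohort:
            if p.group is not group:
                continue
            for r in p.proms:
                if r.eq5d is not None:
                    vals[r.timepoint].append(crosswalk_5l_to_3l(r, crosswalk))
        out[group.value] = {
            tp: (float(np.mean(v)) if v else float("nan")) for tp, v in vals.items()
        }
    return out


def utility_vector(
    timepoint_means: dict,
    n_cycles: int,
    cycle_length_years: float,
) -> np.ndarray:
    """Per-cycle utility: observed timepoint means over the first year,
    linearly interpolated at unobserved cycles, carried forward flat to
    the horizon (post-operative plateau assumption)."""
    months = np.array([TIMEPOINT_MONTHS[tp] for tp in TIMEPOINTS])
    means = np.array([timepoint_means[tp] for tp in TIMEPOINTS], dtype=float)
    ok = ~np.isnan(means)
    if not ok.any():
        raise ValidationError("no completed EQ5D responses to build a utility vector")
    t_cycles = np.arange(n_cycles) * cycle_length_years * 12.0
    # linear interpolation inside the observed window, flat carry at tails
    u = np.interp(t_cycles, months[ok], means[ok])
    return np.clip(u, None, 1.0)


def build_pe_arm(
    label: str,
    patients: Sequence[PatientRecord],
    mean_cost: float,
    timepoint_utilities: dict,
    config: PipelineConfig,
) -> ArmSpec:
    """Markov arm for a surgical group from its own survival, utility, cost."""
    km = km_fit(
        [p.survival_time for p in patients], [p.survival_event for p in patients]
    )
    hazards = derive_cycle_death_probs(
        km,
        cycle_length_years=config.cycle_length_years,
        horizon_years=config.horizon_years,
        extrapolation=config.extrapolation,
    )
    n_cycles = len(hazards)
    utility = utility_vector(timepoint_utilities, n_cycles, config.cycle_length_years)
    cost = np.full(n_cycles, config.followup_cost_per_cycle, dtype=float)
    cost[0] += mean_cost  # perioperative lump
    return ArmSpec.from_hazards(
        label,
        hazards,
        utility,
        cost,
        cycle_length_years=config.cycle_length_years,
        horizon_years=config.horizon_years,
        discount_rate_annual=config.discount_rate_annual,
        half_cycle_correction=config.half_cycle_correction,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the result bundle and writes CSVs."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def _stage(name):
        log.info("stage %s at %.2fs", name, time.time() - t_start)

    # --- cohort ----------------------------------------------------------
    _stage("cohort")
    if config.use_generator:
        spec = default_spec(seed=config.seed)
        cohort = generate_cohort(spec)
        n_input = len(cohort)
        excluded = 0
    else:
        cohort = cohort_io.read_cohort(config.cohort_dir)
        n_input = len(cohort)
        excluded = 0  # loader rejects invalid rows outright
    manifest["stages"]["cohort"] = {
        "input": n_input,
        "excluded": excluded,
        "analyzed": len(cohort),
    }
    bundle["cohort"] = cohort
    conv, high = split_groups(cohort)

    valueset = (
        ValueSetTable.from_csv(config.valueset_csv)
        if config.valueset_csv
        else toy_valueset_5l()
    )
    crosswalk = (
        CrosswalkTable.from_csv(config.crosswalk_csv)
        if config.crosswalk_csv
        else toy_crosswalk()
    )
    unit_costs = (
        UnitCostTable.from_csv(config.unit_cost_csv)
        if config.unit_cost_csv
        else synthetic_unit_costs()
    )

    # --- tables ----------------------------------------------------------
    _stage("tables")
    bundle["baseline_table"] = baseline_table(cohort)
    bundle["outcomes_table"] = outcomes_table(cohort)
    bundle["baseline_table"].to_csv(out / "table_baseline.csv", index=False)
    bundle["outcomes_table"].to_csv(out / "table_outcomes.csv", index=False)

    # --- PROMs -----------------------------------------------------------
    _stage("proms")
    prom_table, prom_curves = summarize_trajectories(cohort, valueset)
    bundle["prom_table"], bundle["prom_curves"] = prom_table, prom_curves
    prom_table.to_csv(out / "prom_summary.csv", index=False)
    prom_curves.to_csv(out / "prom_curves.csv", index=False)
    manifest["stages"]["proms"] = {
        "participants": sum(p.prom_participant for p in cohort)
    }

    # --- costing ---------------------------------------------------------
    _stage("costing")
    breakdowns = {
        p.id: cost_patient(p.resources, unit_costs, patient_id=p.id)
        for p in cohort
        if p.resources
    }
    costed = [p for p in cohort if p.id in breakdowns]
    n_uncosted = len(cohort) - len(costed)
    if n_uncosted:
        log.warning("%d patients without resource lines excluded from costing", n_uncosted)
    manifest["stages"]["costing"] = {
        "input": len(cohort),
        "excluded": n_uncosted,
        "analyzed": len(costed),
    }
    cost_table = compare_two_group_costs(
        [breakdowns[p.id] for p in costed if p.group is ComplexityClass.CONVENTIONAL],
        [breakdowns[p.id] for p in costed if p.group is ComplexityClass.HIGH_COMPLEXITY],
    )
    bundle["cost_table"] = cost_table
    cost_table.to_csv(out / "costs_by_group.csv", index=False)

    recon_groups = {
        recon: [
            breakdowns[p.id]
            for p in costed
            if p.exenteration_level == "infralevator" and p.reconstruction == recon
        ]
        for recon in ("biological_mesh", "myocutaneous_flap", "composite")
    }
    try:
        anova, pairwise = compare_reconstruction_costs(recon_groups)
        bundle["reconstruction_anova"] = anova
        bundle["reconstruction_pairwise"] = pairwise
        pairwise.to_csv(out / "costs_reconstruction_pairwise.csv", index=False)
    except ValidationError as exc:
        log.warning("reconstruction sub-analysis skipped: %s", exc)

    # --- survival --------------------------------------------------------
    _stage("survival")
    km_rows = []
    survival_summary = {}
    for label, grp in (("conventional", conv), ("high_complexity", high)):
        km = km_fit([p.survival_time for p in grp], [p.survival_event for p in grp])
        med = median_survival(km)
        s5 = survival_at(km, 60.0)
        survival_summary[label] = {
            "median_months": med,
            "five_year_survival": s5.survival,
            "five_year_ci": (s5.ci_lower, s5.ci_upper),
            "km": km,
        }
        for i in range(km.times.size):
            km_rows.append(
                {
                    "group": label,
                    "time_months": km.times[i],
                    "at_risk": km.at_risk[i],
                    "events": km.events[i],
                    "censored": km.censored[i],
                    "survival": km.survival[i],
                }
            )
    pd.DataFrame(km_rows).to_csv(out / "km_curves.csv", index=False)
    survival_summary["logrank"] = logrank(
        [p.survival_time for p in conv],
        [p.survival_event for p in conv],
        [p.survival_time for p in high],
        [p.survival_event for p in high],
    )
    bundle["survival"] = survival_summary

    # --- Markov CUA ------------------------------------------------------
    _stage("markov")
    utilities = mean_crosswalked_utilities(cohort, crosswalk)
    mean_costs = {
        ComplexityClass.CONVENTIONAL: float(
            np.mean(
                [breakdowns[p.id].total for p in costed
                 if p.group is ComplexityClass.CONVENTIONAL]
            )
        ),
        ComplexityClass.HIGH_COMPLEXITY: float(
            np.mean(
                [breakdowns[p.id].total for p in costed
                 if p.group is ComplexityClass.HIGH_COMPLEXITY]
            )
        ),
    }
    arms = {
        "conventional": build_pe_arm(
            "conventional",
            conv,
            mean_costs[ComplexityClass.CONVENTIONAL],
            utilities["conventional"],
            config,
        ),
        "high_complexity": build_pe_arm(
            "high_complexity",
            high,
            mean_costs[ComplexityClass.HIGH_COMPLEXITY],
            utilities["high_complexity"],
            config,
        ),
        "no_pe": calibrate_no_pe_arm(
            config.no_pe_target_cost,
            config.no_pe_target_qalys,
            NoSurgeryShape(
                survival_median_months=config.no_pe_median_survival_months,
                cycle_length_years=config.cycle_length_years,
                horizon_years=config.horizon_years,
                discount_rate_annual=config.discount_rate_annual,
                half_cycle_correction=config.half_cycle_correction,
            ),
        ),
    }
    results = {label: run_markov(arm) for label, arm in arms.items()}
    cua_rows = []
    for label, res in results.items():
        ce = compute_icer(res, results["no_pe"]) if label != "no_pe" else None
        cua_rows.append(
            {
                "arm": label,
                "total_qalys": res.qalys,
                "total_costs": res.cost,
                "cost_per_qaly": res.cost_per_qaly,
                "icer_vs_no_pe": (
                    ce.icer if ce and ce.icer is not None else np.nan
                ),
                "status": ce.status if ce else "comparator",
                "total_qalys_undiscounted": res.qalys_undiscounted,
                "total_costs_undiscounted": res.cost_undiscounted,
            }
        )
    cua = pd.DataFrame(cua_rows)
    bundle["arms"], bundle["cua"] = arms, cua
    cua.to_csv(out / "cua_summary.csv", index=False)
    trace = pd.DataFrame(
        {f"alive_{label}": res.trace for label, res in results.items()}
    )
    trace.insert(0, "cycle", np.arange(len(trace)))
    trace.to_csv(out / "markov_trace.csv", index=False)

    # --- DSA -------------------------------------------------------------
    _stage("dsa")
    dsa = run_dsa(arms, default_scenarios())
    bundle["dsa"] = dsa
    dsa.table.to_csv(out / "dsa_scenarios.csv", index=False)

    manifest["runtime_seconds"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
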
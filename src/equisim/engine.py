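"""Trial orchestration.

A trial: calibrate the depression threshold on the baseline population,
then step forward applying the income intervention and letting agents act
on their networks, recomputing depression after each step, and finally
account incident and reduced cases against baseline.

The suite runs the four income-intervention trials (condition 1 with each
program) plus the eight income-by-network condition trials.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import (
    Agent,
    CohortParams,
    DisseminationArea,
    assign_networks,
    build_da_index,
    build_da_lookup,
    generate_cohort,
    generate_das,
)
from .depression import (
    CalibrationResult,
    CoefficientSet,
    calibrate_threshold,
    linear_predictor,
    probability,
)
from .interventions import (
    InterventionSchedule,
    acb_schedule,
    apply_intervention,
    ccb_schedule,
    min_wage_schedule,
    none_schedule,
    ubi_schedule,
)
from .networks import ConditionSpec, act, condition_table, network_offset
from .stats import pct_change, prevalence_test

__all__ = ["TrialResult", "run_trial", "run_suite", "predict_probabilities"]

log = logging.getLogger(__name__)

DEFAULT_TARGET_PREVALENCE = 0.3443


@dataclass
class TrialResult:
    """Accounting for one simulation condition."""

    condition_id: int
    intervention_kind: str
    n: int
    baseline_depressed: int
    followup_depressed: int
    incident_cases: int
    reduced_cases: int
    pct_change: float
    p_value: float
    seed: int
    tau: float = float("nan")
    achieved_baseline_prevalence: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("baseline_depressed", "followup_depressed", "incident_cases", "reduced_cases"):
            v = getattr(self, name)
            if not 0 <= v <= self.n:
                raise ValueError(f"{name}={v} out of [0, n={self.n}]")
        implied = self.baseline_depressed + self.incident_cases - self.reduced_cases
        if implied != self.followup_depressed:
            raise ValueError(
                f"accounting identity violated: {self.baseline_depressed} + "
                f"{self.incident_cases} - {self.reduced_cases} != {self.followup_depressed}"
            )

    def to_dict(self) -> dict:
        return {
            "condition_id": self.condition_id,
            "intervention_kind": self.intervention_kind,
            "n": self.n,
            "baseline_depressed": self.baseline_depressed,
            "followup_depressed": self.followup_depressed,
            "incident_cases": self.incident_cases,
            "reduced_cases": self.reduced_cases,
            "pct_change": self.pct_change,
            "p_value": self.p_value,
            "seed": self.seed,
            "tau": self.tau,
            "achieved_baseline_prevalence": self.achieved_baseline_prevalence,
        }


def predict_probabilities(
    agents: list[Agent],
    da_lookup: dict[int, DisseminationArea],
    coeffs: CoefficientSet,
    *,
    include_support: bool = False,
    include_network: bool = False,
) -> np.ndarray:
    """Depression probability for every agent under the active condition.

    ``agents`` must be indexable by agent_id when network terms are on.
    """
    probs = np.empty(len(agents))
    for i, a in enumerate(agents):
        offset = network_offset(a, agents, coeffs) if include_network else 0.0
        lp = linear_predictor(
            a, da_lookup[a.da_id], coeffs,
            include_support=include_support, network_offset=offset,
        )
        probs[i] = probability(lp)
    return probs


def _update_depression(
    agents: list[Agent],
    da_lookup: dict[int, DisseminationArea],
    coeffs: CoefficientSet,
    tau: float,
    *,
    include_support: bool,
    include_network: bool,
) -> None:
    """Synchronous recompute of p_depressed and the depressed flag."""
    probs = predict_probabilities(
        agents, da_lookup, coeffs,
        include_support=include_support, include_network=include_network,
    )
    for a, p in zip(agents, probs):
        a.p_depressed = float(p)
        a.depressed = bool(p >= tau)


def run_trial(
    agents: list[Agent],
    das: list[DisseminationArea],
    coeffs: CoefficientSet,
    schedule: InterventionSchedule,
    spec: ConditionSpec,
    n_steps: int | None = None,
    seed: int = 0,
    *,
    target_prevalence: float = DEFAULT_TARGET_PREVALENCE,
    method: str = "two_proportion_z",
    recompute_da_medians: bool = False,
) -> TrialResult:
    """Run one condition and return its accounting.

    The input cohort is not mutated.  ``n_steps`` defaults to the
    schedule's step count for a stepped minimum-wage trial and to a single
    step otherwise (benefits are granted once; pure-network trials act once).
    """
    spec.validate()
    schedule.validate()
    coeffs.validate()
    if schedule.kind != "none" and not spec.income_change:
        raise ValueError(
            f"condition {spec.condition_id} has no income change; use kind='none' "
            f"(got {schedule.kind!r})"
        )
    if n_steps is None:
        n_steps = schedule.n_steps if schedule.kind == "min_wage" else 1

    agents = [a.clone() for a in agents]
    for i, a in enumerate(agents):
        if a.agent_id != i:
            raise ValueError("agents must be ordered by agent_id")
        a.baseline_income = a.household_income
    das = [replace(da) for da in das]
    da_lookup = build_da_lookup(das)
    da_index = build_da_index(agents)
    rng = np.random.default_rng(seed)
    n = len(agents)

    include_support = spec.include_support_covariate
    include_network = spec.has_network_dynamics

    # Baseline case assignment.  The depressed-tie term depends on who is
    # depressed, which calibration itself decides; iterate prob -> threshold
    # -> flags to a fixed point (converges in a few rounds; capped).
    cal: CalibrationResult | None = None
    for _ in range(5 if include_network else 1):
        probs = predict_probabilities(
            agents, da_lookup, coeffs,
            include_support=include_support, include_network=include_network,
        )
        cal = calibrate_threshold(probs, target_prevalence)
        flags = probs >= cal.tau
        changed = False
        for a, p, flag in zip(agents, probs, flags):
            a.p_depressed = float(p)
            if a.depressed != flag:
                a.depressed = bool(flag)
                changed = True
        if not changed:
            break
    baseline_flags = [a.depressed for a in agents]
    baseline_depressed = sum(baseline_flags)
    log.info(
        "trial cond=%d kind=%s baseline: tau=%.6f prevalence=%.4f",
        spec.condition_id, schedule.name, cal.tau, cal.achieved_prevalence,
    )

    for step in range(1, n_steps + 1):
        if spec.income_change:
            apply_intervention(agents, schedule, step if schedule.kind == "min_wage" else None)
        if recompute_da_medians:
            _recompute_medians(agents, da_lookup)
        if include_network:
            order = rng.permutation(n)
            skipped = 0
            for idx in order:
                skipped += act(agents[idx], agents, spec, rng, da_index)
            if skipped:
                log.info("step %d: %d tie additions skipped (saturated DAs)", step, skipped)
        _update_depression(
            agents, da_lookup, coeffs, cal.tau,
            include_support=include_support, include_network=include_network,
        )
        log.info(
            "step=%d prevalence=%.4f mean_income=%.0f",
            step,
            sum(a.depressed for a in agents) / n,
            sum(a.household_income for a in agents) / n,
        )

    incident = sum(1 for a, base in zip(agents, baseline_flags) if a.depressed and not base)
    reduced = sum(1 for a, base in zip(agents, baseline_flags) if base and not a.depressed)
    followup_depressed = sum(a.depressed for a in agents)
    return TrialResult(
        condition_id=spec.condition_id,
        intervention_kind=schedule.name,
        n=n,
        baseline_depressed=baseline_depressed,
        followup_depressed=followup_depressed,
        incident_cases=incident,
        reduced_cases=reduced,
        pct_change=pct_change(baseline_depressed, followup_depressed),
        p_value=prevalence_test(
            baseline_depressed, followup_depressed, n, method,
            incident=incident, reduced=reduced,
        ),
        seed=seed,
        tau=cal.tau,
        achieved_baseline_prevalence=cal.achieved_prevalence,
    )


def _recompute_medians(agents: list[Agent], da_lookup: dict[int, DisseminationArea]) -> None:
    incomes: dict[int, list[float]] = {}
    for a in agents:
        incomes.setdefault(a.da_id, []).append(a.household_income)
    for da_id, vals in incomes.items():
        da_lookup[da_id].median_after_tax_income = statistics.median(vals)


def _derived_seed(master_seed: int, *path: int) -> int:
    return int(np.random.SeedSequence([master_seed, *path]).generate_state(1)[0])


def suite_plan(config) -> list[tuple[ConditionSpec, InterventionSchedule]]:
    """4 income-program trials (condition 1) + the 8 condition trials."""
    specs = condition_table(p_act=config.p_act, ties_added_per_act=config.ties_added_per_act)
    schedules = config.interventions
    plan = [(specs[0], schedules[k]) for k in ("min_wage", "acb", "ccb", "ubi")]
    plan += [
        (s, schedules["min_wage"] if s.income_change else none_schedule()) for s in specs
    ]
    return plan


def run_suite(config) -> list[TrialResult]:
    """Run the full suite from a :class:`equisim.config.Config`.

    Each trial regenerates its own cohort from a derived seed stream, so
    trials are independent yet the whole suite is reproducible from the
    master seed.
    """
    results = []
    for idx, (spec, schedule) in enumerate(suite_plan(config)):
        params = replace(config.cohort, seed=_derived_seed(config.seed, idx, 0))
        das = generate_das(params)
        agents = assign_networks(generate_cohort(das, params), params)
        results.append(
            run_trial(
                agents, das, config.coefficients, schedule, spec,
                seed=_derived_seed(config.seed, idx, 1),
                target_prevalence=config.target_prevalence,
                method=config.test_method,
                recompute_da_medians=config.recompute_da_medians,
            )
        )
    return results


def default_interventions() -> dict[str, InterventionSchedule]:
    return {
        "min_wage": min_wage_schedule(),
        "acb": acb_schedule(),
        "ccb": ccb_schedule(),
        "ubi": ubi_schedule(),
    }
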
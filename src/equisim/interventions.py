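"""Income transformations for the four inequality-reducing programs.

All transforms operate on a household's *baseline* income and never
decrease it:

* ``min_wage`` — floors income at the annual earnings of one full-time
  minimum-wage worker, with the wage stepped linearly from its start to
  its end value over the simulation;
* ``child_benefit`` — a fixed benefit linearly phased out above a net
  income threshold (covers both the federal and provincial programs via
  different parameters);
* ``ubi`` — a guaranteed-income top-up clawed back at a constant rate;
* ``none`` — identity.

Benefit amounts and phase-out rates were not published by the study;
defaults mirror the cited programs' public parameters and are config,
not facts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import Agent

__all__ = [
    "InterventionSchedule",
    "wage_at_step",
    "wage_floor_income",
    "child_benefit",
    "ubi_topup",
    "apply_intervention",
    "none_schedule",
    "min_wage_schedule",
    "acb_schedule",
    "ccb_schedule",
    "ubi_schedule",
]

KINDS = ("none", "min_wage", "child_benefit", "ubi")


@dataclass
class InterventionSchedule:
    """Parameters of one income transformation."""

    kind: str = "none"
    name: str = "none"
    # minimum wage path
    wage_start: float = 8.40
    wage_end: float = 15.00
    hours_per_week: float = 40.0
    weeks_per_year: float = 50.0
    n_steps: int = 10
    # child benefit phase-out
    benefit_max: float = 0.0
    phaseout_start: float = 0.0
    phaseout_rate: float = 0.0
    # guaranteed-income top-up
    ubi_guarantee: float = 0.0
    ubi_clawback: float = 0.5

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown intervention kind: {self.kind!r}")
        if self.wage_end < self.wage_start:
            raise ValueError("wage_end must be >= wage_start")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        for name in ("phaseout_rate", "ubi_clawback"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("benefit_max", "phaseout_start", "ubi_guarantee",
                     "hours_per_week", "weeks_per_year"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def none_schedule() -> InterventionSchedule:
    return InterventionSchedule(kind="none", name="none")


def min_wage_schedule(n_steps: int = 10) -> InterventionSchedule:
    return InterventionSchedule(kind="min_wage", name="min_wage", n_steps=n_steps)


def acb_schedule() -> InterventionSchedule:
    """Provincial child benefit: smaller benefit, lower phase-out start."""
    return InterventionSchedule(
        kind="child_benefit",
        name="acb",
        benefit_max=1128.0,
        phaseout_start=26141.0,
        phaseout_rate=0.075,
        n_steps=1,
    )


def ccb_schedule() -> InterventionSchedule:
    """Federal child benefit: larger benefit, higher phase-out start."""
    return InterventionSchedule(
        kind="child_benefit",
        name="ccb",
        benefit_max=6639.0,
        phaseout_start=31120.0,
        phaseout_rate=0.07,
        n_steps=1,
    )


def ubi_schedule() -> InterventionSchedule:
    """Guaranteed-income pilot design: single-person guarantee, 50% clawback."""
    return InterventionSchedule(
        kind="ubi",
        name="ubi",
        ubi_guarantee=16989.0,
        ubi_clawback=0.5,
        n_steps=1,
    )


def wage_at_step(schedule: InterventionSchedule, step: int) -> float:
    """Hourly wage after ``step`` equal increments from start to end."""
    if not 0 <= step <= schedule.n_steps:
        raise ValueError(f"step must be in [0, {schedule.n_steps}], got {step}")
    if step == schedule.n_steps:
        return schedule.wage_end
    return schedule.wage_start + step * (schedule.wage_end - schedule.wage_start) / schedule.n_steps


def wage_floor_income(income: float, wage: float, schedule: InterventionSchedule) -> float:
    """Annual income floored at one full-time worker's earnings at ``wage``."""
    if income < 0:
        raise ValueError("income must be >= 0")
    floor = wage * schedule.hours_per_week * schedule.weeks_per_year
    return max(income, floor)


def child_benefit(income: float, schedule: InterventionSchedule) -> float:
    """Benefit amount: full below the phase-out start, then linearly reduced."""
    if income < 0:
        raise ValueError("income must be >= 0")
    if schedule.benefit_max <= 0:
        raise ValueError("benefit_max must be > 0")
    if income < schedule.phaseout_start:
        return schedule.benefit_max
    return max(0.0, schedule.benefit_max - schedule.phaseout_rate * (income - schedule.phaseout_start))


def ubi_topup(income: float, schedule: InterventionSchedule) -> float:
    """Top-up amount: guarantee minus clawback of income, floored at zero."""
    if income < 0:
        raise ValueError("income must be >= 0")
    return max(0.0, schedule.ubi_guarantee - schedule.ubi_clawback * income)


def transform_income(income: float, schedule: InterventionSchedule, step: int | None = None) -> float:
    """Apply one schedule to a single baseline income."""
    if schedule.kind == "none":
        return income
    if schedule.kind == "min_wage":
        wage = wage_at_step(schedule, schedule.n_steps if step is None else step)
        return wage_floor_income(income, wage, schedule)
    if schedule.kind == "child_benefit":
        return income + child_benefit(income, schedule)
    if schedule.kind == "ubi":
        return income + ubi_topup(income, schedule)
    raise ValueError(f"unknown intervention kind: {schedule.kind!r}")


def apply_intervention(
    agents: list[Agent], schedule: InterventionSchedule, step: int | None = None
) -> list[Agent]:
    """Set every agent's current income to the transform of her baseline income.

    Baseline incomes must have been stored by the caller (engine), so the
    operation is idempotent at any given step and benefits never compound.
    """
    schedule.validate()
    for agent in agents:
        if agent.baseline_income is None:
            raise ValueError("baseline incomes not set; store baseline_income before applying")
        agent.household_income = transform_income(agent.baseline_income, schedule, step)
    return agents
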
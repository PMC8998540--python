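"""Agent decisions about social networks and their effect on the logit.

Eight experimental conditions combine income change with three network
mechanisms: controlling for baseline social support, dropping ties to
currently depressed agents, and growing the network with new within-DA
ties.  The network enters the depression logit through a two-term linear
offset: a protective per-tie effect plus a smaller adverse per-depressed-tie
effect, the minimal form under which a larger network is beneficial but
severing a depressed tie is a net loss.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohort import Agent
from .depression import CoefficientSet

__all__ = ["ConditionSpec", "condition_table", "act", "network_offset"]


@dataclass(frozen=True)
class ConditionSpec:
    """One of the eight simulation conditions."""

    condition_id: int
    income_change: bool
    include_support_covariate: bool
    remove_depressed_ties: bool
    add_ties: bool
    p_act: float = 1.0
    ties_added_per_act: int = 1

    @property
    def has_network_dynamics(self) -> bool:
        return self.remove_depressed_ties or self.add_ties

    def validate(self) -> None:
        if not 1 <= self.condition_id <= 8:
            raise ValueError("condition_id must be 1..8")
        if not 0.0 <= self.p_act <= 1.0:
            raise ValueError("p_act must be in [0, 1]")
        if self.ties_added_per_act < 0:
            raise ValueError("ties_added_per_act must be >= 0")


# (income_change, include_support_covariate, remove_depressed_ties, add_ties)
_CONDITION_FLAGS = {
    1: (True, False, False, False),
    2: (True, True, False, False),
    3: (True, False, True, False),
    4: (True, False, False, True),
    5: (True, False, True, True),
    6: (False, False, True, False),
    7: (False, False, True, True),
    8: (False, False, False, True),
}


def condition_table(p_act: float = 1.0, ties_added_per_act: int = 1) -> list[ConditionSpec]:
    """The eight conditions, in canonical order."""
    specs = [
        ConditionSpec(cid, *flags, p_act=p_act, ties_added_per_act=ties_added_per_act)
        for cid, flags in sorted(_CONDITION_FLAGS.items())
    ]
    for s in specs:
        s.validate()
    return specs


def get_condition(condition_id: int, p_act: float = 1.0, ties_added_per_act: int = 1) -> ConditionSpec:
    if condition_id not in _CONDITION_FLAGS:
        raise ValueError(f"condition_id must be 1..8, got {condition_id}")
    return ConditionSpec(
        condition_id, *_CONDITION_FLAGS[condition_id],
        p_act=p_act, ties_added_per_act=ties_added_per_act,
    )


def act(
    agent: Agent,
    population: list[Agent],
    spec: ConditionSpec,
    rng: np.random.Generator,
    da_index: dict[int, list[int]] | None = None,
) -> int:
    """One agent's network decision for one step.

    With probability ``p_act`` the agent first severs every tie to a
    currently depressed agent (if the condition allows removal), then adds
    ``ties_added_per_act`` new ties to same-DA agents she is not already
    tied to (if the condition allows growth).  All changes are applied
    symmetrically.  Returns the number of additions skipped for lack of an
    eligible partner.

    ``population`` must be indexable by agent_id (agents in id order).
    """
    if rng.random() >= spec.p_act:
        return 0
    skipped = 0
    if spec.remove_depressed_ties:
        for other_id in sorted(agent.ties):
            if population[other_id].depressed:
                agent.ties.discard(other_id)
                population[other_id].ties.discard(agent.agent_id)
    if spec.add_ties and spec.ties_added_per_act > 0:
        if da_index is not None:
            members = da_index[agent.da_id]
        else:
            members = [a.agent_id for a in population if a.da_id == agent.da_id]
        for _ in range(spec.ties_added_per_act):
            new_id = _draw_partner(agent, members, rng)
            if new_id is None:
                skipped += 1
                continue
            agent.ties.add(new_id)
            population[new_id].ties.add(agent.agent_id)
    return skipped


def _draw_partner(agent: Agent, members: list[int], rng: np.random.Generator) -> int | None:
    """Uniform draw of an eligible same-DA partner, or None if saturated.

    Rejection sampling with a bounded number of attempts, falling back to
    an exhaustive scan so saturation is detected exactly.
    """
    m = len(members)
    if m <= 1:
        return None
    for _ in range(16):
        cand = members[int(rng.integers(m))]
        if cand != agent.agent_id and cand not in agent.ties:
            return cand
    eligible = [i for i in members if i != agent.agent_id and i not in agent.ties]
    if not eligible:
        return None
    return eligible[int(rng.integers(len(eligible)))]


def network_offset(agent: Agent, population: list[Agent], coeffs: CoefficientSet) -> float:
    """Network contribution to the logit:
    ``beta_network_size * |ties| + beta_depressed_ties * #depressed ties``."""
    if not agent.ties:
        return 0.0
    n_depressed = sum(1 for t in agent.ties if population[t].depressed)
    return coeffs.beta_network_size * len(agent.ties) + coeffs.beta_depressed_ties * n_depressed
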
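"""Synthetic cohort generation.

Builds a population of expectant-mother agents distributed over
dissemination areas (DAs), with marginal distributions matching the
published baseline characteristics of the source cohort, plus
within-DA baseline social networks.

The real cohort and census data are restricted; this module stands in
for them.  All distributional choices that are not pinned down by the
published marginals (continuous income within bands, DA covariates,
network topology) are configurable through :class:`CohortParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

__all__ = [
    "EDUCATION_LEVELS",
    "DisseminationArea",
    "Agent",
    "CohortParams",
    "generate_das",
    "generate_cohort",
    "assign_networks",
    "build_da_lookup",
    "build_da_index",
]

EDUCATION_LEVELS = (
    "high_school_or_less",
    "some_or_completed_postsecondary",
    "some_or_completed_graduate",
)


class ConfigurationError(ValueError):
    """Raised when generator parameters are invalid."""


@dataclass
class DisseminationArea:
    """Neighborhood context for a group of agents.

    ``median_after_tax_income`` defines each resident's relative income;
    the three fraction covariates enter the depression model directly.
    """

    da_id: int
    median_after_tax_income: float
    pct_lico: float
    pct_shelter_over_30: float
    pct_recent_immigrants: float

    def validate(self) -> None:
        if self.median_after_tax_income <= 0:
            raise ConfigurationError("median_after_tax_income must be > 0")
        for name in ("pct_lico", "pct_shelter_over_30", "pct_recent_immigrants"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class Agent:
    """One expectant mother.

    ``household_income`` is after-tax and is the only field interventions
    mutate; ``baseline_income`` is set by the engine at trial start so
    every intervention transforms from the same base.  ``income_band`` is
    generation bookkeeping (0/1/2 for the three published bands, keyed on
    the before-tax draw).
    """

    agent_id: int
    da_id: int
    age: float
    education: str
    born_in_canada: bool
    white: bool
    household_income: float
    gov_support: bool
    prenatal_care_access: bool
    safety: float
    crime: float
    social_support_present: bool = False
    ties: set[int] = field(default_factory=set)
    depressed: bool = False
    p_depressed: float = 0.0
    income_band: int = 0
    income_before_tax: float = 0.0
    baseline_income: float | None = None

    def clone(self) -> "Agent":
        return replace(self, ties=set(self.ties))


@dataclass
class CohortParams:
    """Every knob of the synthetic generator, with published defaults.

    Category probabilities come from the published baseline table; the
    remaining parameters (band income shapes, DA covariates, network
    mean degree) are unpublished and documented as free choices.
    """

    n_mothers: int = 3387
    n_agents: int = 17865
    n_das: int = 183
    # age: truncated normal
    age_mean: float = 30.60
    age_sd: float = 4.55
    age_min: float = 18.0
    age_max: float = 47.0
    # categorical marginals
    p_education: tuple[float, float, float] = (0.1094, 0.7329, 0.1577)
    p_born_in_canada: float = 0.7826
    p_white: float = 0.7864
    p_income_bands: tuple[float, float, float] = (0.0917, 0.2206, 0.6877)
    p_gov_support: float = 0.0538
    p_prenatal_access: float = 0.90
    # before-tax income: per-band truncated lognormal
    income_band_edges: tuple[float, float] = (40_000.0, 80_000.0)
    income_band_mu: tuple[float, float, float] = (
        math.log(30_000.0),
        math.log(58_000.0),
        math.log(108_000.0),
    )
    income_band_sigma: tuple[float, float, float] = (0.35, 0.25, 0.35)
    after_tax_factor: float = 0.80
    # perception scores: Beta(a, b)
    safety_beta: tuple[float, float] = (8.0, 2.0)
    crime_beta: tuple[float, float] = (2.0, 8.0)
    # DA covariates
    da_median_income_mu: float = math.log(65_000.0)
    da_median_income_sigma: float = 0.30
    da_lico_beta: tuple[float, float] = (2.0, 18.0)
    da_shelter_beta: tuple[float, float] = (4.0, 12.0)
    da_recent_immigrants_beta: tuple[float, float] = (2.0, 18.0)
    # networks: within-DA random ties
    mean_degree: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_das <= 0:
            raise ConfigurationError("n_das must be positive")
        if self.n_agents < self.n_das:
            raise ConfigurationError("n_agents must be >= n_das")
        if self.n_mothers <= 0 or self.n_agents <= 0:
            raise ConfigurationError("population sizes must be positive")
        for name in ("p_education", "p_income_bands"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs):
                raise ConfigurationError(f"{name} entries must be >= 0")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 within 1e-9")
        for name in ("p_born_in_canada", "p_white", "p_gov_support", "p_prenatal_access"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not self.age_min <= self.age_mean <= self.age_max:
            raise ConfigurationError("age_mean must lie inside [age_min, age_max]")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")
        if self.mean_degree < 0:
            raise ConfigurationError("mean_degree must be >= 0")
        if not 0.0 < self.after_tax_factor <= 1.0:
            raise ConfigurationError("after_tax_factor must be in (0, 1]")
        lo, hi = self.income_band_edges
        if not 0.0 < lo < hi:
            raise ConfigurationError("income_band_edges must be increasing and positive")


def _rng(params: CohortParams, stream: int) -> np.random.Generator:
    # one independent stream per generator stage so stages are individually
    # reproducible under a fixed params.seed
    return np.random.default_rng([params.seed, stream])


def generate_das(params: CohortParams) -> list[DisseminationArea]:
    """Draw ``n_das`` dissemination areas from the configured distributions."""
    params.validate()
    rng = _rng(params, 1)
    n = params.n_das
    medians = rng.lognormal(params.da_median_income_mu, params.da_median_income_sigma, n)
    lico = rng.beta(*params.da_lico_beta, n)
    shelter = rng.beta(*params.da_shelter_beta, n)
    recent = rng.beta(*params.da_recent_immigrants_beta, n)
    das = [
        DisseminationArea(
            da_id=i,
            median_after_tax_income=float(medians[i]),
            pct_lico=float(lico[i]),
            pct_shelter_over_30=float(shelter[i]),
            pct_recent_immigrants=float(recent[i]),
        )
        for i in range(n)
    ]
    for da in das:
        da.validate()
    return das


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Lognormal(mu, sigma) conditioned on (lo, hi) via the log-scale truncated normal."""
    a = -np.inf if lo <= 0 else (math.log(lo) - mu) / sigma
    b = np.inf if not math.isfinite(hi) else (math.log(hi) - mu) / sigma
    z = sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)
    return np.exp(z)


def generate_cohort(das: list[DisseminationArea], params: CohortParams) -> list[Agent]:
    """Generate ``params.n_agents`` agents assigned round-robin to ``das``.

    Marginal frequencies converge to the configured probabilities as the
    population grows.  Depression state is left unset; it is assigned by
    prevalence-threshold calibration at trial start.
    """
    params.validate()
    if not das:
        raise ConfigurationError("das must be nonempty")
    rng = _rng(params, 2)
    n = params.n_agents

    a = (params.age_min - params.age_mean) / params.age_sd
    b = (params.age_max - params.age_mean) / params.age_sd
    ages = sps.truncnorm.rvs(
        a, b, loc=params.age_mean, scale=params.age_sd, size=n, random_state=rng
    )
    education = rng.choice(3, size=n, p=np.asarray(params.p_education, float))
    born = rng.random(n) < params.p_born_in_canada
    white = rng.random(n) < params.p_white
    gov = rng.random(n) < params.p_gov_support
    prenatal = rng.random(n) < params.p_prenatal_access
    safety = rng.beta(*params.safety_beta, n)
    crime = rng.beta(*params.crime_beta, n)

    bands = rng.choice(3, size=n, p=np.asarray(params.p_income_bands, float))
    edges = (0.0, params.income_band_edges[0], params.income_band_edges[1], math.inf)
    income_pre = np.empty(n)
    for k in range(3):
        idx = np.flatnonzero(bands == k)
        if idx.size:
            income_pre[idx] = _truncated_lognormal(
                rng,
                params.income_band_mu[k],
                params.income_band_sigma[k],
                edges[k],
                edges[k + 1],
                idx.size,
            )

    n_das = len(das)
    agents = [
        Agent(
            agent_id=i,
            da_id=das[i % n_das].da_id,
            age=float(ages[i]),
            education=EDUCATION_LEVELS[education[i]],
            born_in_canada=bool(born[i]),
            white=bool(white[i]),
            household_income=float(income_pre[i] * params.after_tax_factor),
            gov_support=bool(gov[i]),
            prenatal_care_access=bool(prenatal[i]),
            safety=float(safety[i]),
            crime=float(crime[i]),
            income_band=int(bands[i]),
            income_before_tax=float(income_pre[i]),
        )
        for i in range(n)
    ]
    return agents


def assign_networks(agents: list[Agent], params: CohortParams) -> list[Agent]:
    """Draw symmetric within-DA random ties with the configured mean degree.

    Each DA is an Erdős–Rényi graph with edge probability
    ``mean_degree / (size - 1)`` (capped at 1).  Social support presence is
    defined as having at least one tie.  Mutates and returns ``agents``.
    """
    params.validate()
    rng = _rng(params, 3)
    for agent in agents:
        agent.ties = set()
    groups: dict[int, list[int]] = {}
    for pos, agent in enumerate(agents):
        groups.setdefault(agent.da_id, []).append(pos)
    for members in groups.values():
        m = len(members)
        if m < 2 or params.mean_degree == 0:
            continue
        p = min(1.0, params.mean_degree / (m - 1))
        iu, ju = np.triu_indices(m, k=1)
        hit = rng.random(iu.size) < p
        for i, j in zip(iu[hit], ju[hit]):
            a, b = agents[members[i]], agents[members[j]]
            a.ties.add(b.agent_id)
            b.ties.add(a.agent_id)
    for agent in agents:
        agent.social_support_present = len(agent.ties) >= 1
    return agents


def build_da_lookup(das: list[DisseminationArea]) -> dict[int, DisseminationArea]:
    return {da.da_id: da for da in das}


def build_da_index(agents: list[Agent]) -> dict[int, list[int]]:
    """Map da_id -> agent_ids resident there (for tie-formation candidate sets)."""
    index: dict[int, list[int]] = {}
    for agent in agents:
        index.setdefault(agent.da_id, []).append(agent.agent_id)
    return index
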
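"""Logistic depression risk model with prevalence-threshold calibration.

The linear predictor uses relative income (household income minus the DA
median after-tax income) as the primary exposure plus individual- and
DA-level covariates.  Because the original model's coefficients were fit
on restricted data, a documented default :class:`CoefficientSet` is
shipped; miscalibration is absorbed by the probability threshold, which
is chosen so the predicted-depressed share matches a target prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

try:  # newer statsmodels warns instead of raising
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
except ImportError:  # pragma: no cover
    class PerfectSeparationWarning(UserWarning):
        pass

from .cohort import EDUCATION_LEVELS, Agent, DisseminationArea

__all__ = [
    "CoefficientSet",
    "CalibrationResult",
    "SeparationError",
    "relative_income",
    "linear_predictor",
    "probability",
    "calibrate_threshold",
    "fit_logistic",
]

#: covariates that must be present (non-None) on every agent
REQUIRED_COVARIATES = (
    "age",
    "education",
    "born_in_canada",
    "white",
    "household_income",
    "gov_support",
    "prenatal_care_access",
    "safety",
    "crime",
)

# relative income enters the fitting design divided by this to keep the
# Hessian well-conditioned; coefficients are rescaled back on return
_REL_INCOME_SCALE = 1e4


class SeparationError(RuntimeError):
    """Perfect separation during logistic fitting."""


@dataclass
class CoefficientSet:
    """Logit-scale coefficients of the depression model.

    Default magnitudes are free modelling choices tuned so the default
    synthetic population lands near the target prevalence before
    calibration; default *signs* follow the risk-factor literature:
    higher relative income, education, safety, network size and social
    support are protective; crime, government-support receipt and the
    DA deprivation covariates are adverse.  Depressed ties partially
    offset the per-tie benefit (|beta_depressed_ties| < |beta_network_size|),
    so removing a depressed tie is a net loss.
    """

    intercept: float = 0.05
    beta_relative_income: float = -1.0e-5
    beta_edu_postsecondary: float = -0.20
    beta_edu_graduate: float = -0.35
    beta_age: float = -0.010
    beta_white: float = -0.15
    beta_born_in_canada: float = 0.05
    beta_gov_support: float = 0.30
    beta_prenatal_care_access: float = -0.20
    beta_safety: float = -0.30
    beta_crime: float = 0.30
    beta_social_support_present: float = -0.40
    beta_pct_lico: float = 1.00
    beta_pct_shelter_over_30: float = 0.50
    beta_pct_recent_immigrants: float = 0.50
    beta_median_income: float = 0.0
    beta_network_size: float = -0.30
    beta_depressed_ties: float = 0.10

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"coefficient {f.name} must be finite")


@dataclass
class CalibrationResult:
    """Outcome of prevalence-threshold calibration."""

    tau: float
    achieved_prevalence: float
    target_prevalence: float


def relative_income(agent: Agent, da: DisseminationArea) -> float:
    """Household income minus the DA median after-tax income (signed)."""
    if agent.da_id != da.da_id:
        raise ValueError(
            f"agent {agent.agent_id} lives in DA {agent.da_id}, not DA {da.da_id}"
        )
    return agent.household_income - da.median_after_tax_income


def _check_covariates(agent: Agent) -> None:
    for name in REQUIRED_COVARIATES:
        if getattr(agent, name) is None:
            raise ValueError(f"missing covariate: {name}")
    if agent.education not in EDUCATION_LEVELS:
        raise ValueError(f"missing covariate: education (got {agent.education!r})")


def linear_predictor(
    agent: Agent,
    da: DisseminationArea,
    coeffs: CoefficientSet,
    *,
    include_support: bool = False,
    network_offset: float = 0.0,
) -> float:
    """Logit of depression for one agent.

    ``include_support`` adds the baseline social-support covariate (used
    only by the condition that controls for it); ``network_offset`` carries
    the network-size / depressed-tie terms when the active condition has
    network dynamics (see :func:`equisim.networks.network_offset`).
    """
    _check_covariates(agent)
    lp = (
        coeffs.intercept
        + coeffs.beta_relative_income * relative_income(agent, da)
        + coeffs.beta_age * agent.age
        + (coeffs.beta_edu_postsecondary if agent.education == EDUCATION_LEVELS[1] else 0.0)
        + (coeffs.beta_edu_graduate if agent.education == EDUCATION_LEVELS[2] else 0.0)
        + coeffs.beta_white * agent.white
        + coeffs.beta_born_in_canada * agent.born_in_canada
        + coeffs.beta_gov_support * agent.gov_support
        + coeffs.beta_prenatal_care_access * agent.prenatal_care_access
        + coeffs.beta_safety * agent.safety
        + coeffs.beta_crime * agent.crime
        + coeffs.beta_pct_lico * da.pct_lico
        + coeffs.beta_pct_shelter_over_30 * da.pct_shelter_over_30
        + coeffs.beta_pct_recent_immigrants * da.pct_recent_immigrants
        + coeffs.beta_median_income * da.median_after_tax_income
    )
    if include_support:
        lp += coeffs.beta_social_support_present * agent.social_support_present
    return lp + network_offset


def probability(logit: float) -> float:
    """Inverse logit, 1 / (1 + exp(-logit))."""
    return float(expit(logit))


def calibrate_threshold(probs, target: float) -> CalibrationResult:
    """Pick the probability cut-point tau whose predicted-depressed share
    (fraction of ``probs`` >= tau) is closest to ``target``.

    Ties in achievable shares equidistant from the target break toward the
    share at or above it.  With continuous probabilities the achieved
    prevalence is within 1/n of the target.
    """
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValueError("probs must be nonempty")
    if not 0.0 <= target <= 1.0:
        raise ValueError("target must be in [0, 1]")
    n = p.size
    p_sorted = np.sort(p)
    values = np.unique(p_sorted)
    # thresholds at each distinct prob value, plus one just above the max
    # (achieving a count of zero)
    taus = np.append(values, np.nextafter(values[-1], np.inf))
    counts = n - np.searchsorted(p_sorted, taus, side="left")
    shares = counts / n
    dist = np.abs(shares - target)
    best = np.min(dist)
    tied = np.flatnonzero(dist <= best + 1e-15)
    at_or_above = tied[shares[tied] >= target]
    pick = int(at_or_above[0]) if at_or_above.size else int(tied[0])
    return CalibrationResult(
        tau=float(taus[pick]),
        achieved_prevalence=float(shares[pick]),
        target_prevalence=float(target),
    )


def design_matrix(
    agents: list[Agent],
    da_lookup: dict[int, DisseminationArea],
    *,
    include_support: bool = True,
) -> pd.DataFrame:
    """Design matrix matching :func:`linear_predictor`'s covariate set.

    ``relative_income`` is scaled down by 1e4 for numerical conditioning;
    :func:`fit_logistic` rescales the coefficient back.
    """
    rows = []
    for a in agents:
        _check_covariates(a)
        da = da_lookup[a.da_id]
        rows.append(
            {
                "const": 1.0,
                "relative_income": relative_income(a, da) / _REL_INCOME_SCALE,
                "edu_postsecondary": float(a.education == EDUCATION_LEVELS[1]),
                "edu_graduate": float(a.education == EDUCATION_LEVELS[2]),
                "age": a.age,
                "white": float(a.white),
                "born_in_canada": float(a.born_in_canada),
                "gov_support": float(a.gov_support),
                "prenatal_care_access": float(a.prenatal_care_access),
                "safety": a.safety,
                "crime": a.crime,
                "pct_lico": da.pct_lico,
                "pct_shelter_over_30": da.pct_shelter_over_30,
                "pct_recent_immigrants": da.pct_recent_immigrants,
                **(
                    {"social_support_present": float(a.social_support_present)}
                    if include_support
                    else {}
                ),
            }
        )
    return pd.DataFrame(rows)


_PARAM_TO_COEFF = {
    "const": "intercept",
    "relative_income": "beta_relative_income",
    "edu_postsecondary": "beta_edu_postsecondary",
    "edu_graduate": "beta_edu_graduate",
    "age": "beta_age",
    "white": "beta_white",
    "born_in_canada": "beta_born_in_canada",
    "gov_support": "beta_gov_support",
    "prenatal_care_access": "beta_prenatal_care_access",
    "safety": "beta_safety",
    "crime": "beta_crime",
    "pct_lico": "beta_pct_lico",
    "pct_shelter_over_30": "beta_pct_shelter_over_30",
    "pct_recent_immigrants": "beta_pct_recent_immigrants",
    "social_support_present": "beta_social_support_present",
}


def fit_logistic(
    agents: list[Agent],
    outcomes,
    da_lookup: dict[int, DisseminationArea],
    *,
    include_support: bool = True,
    penalize: bool = False,
    details: bool = False,
):
    """Maximum-likelihood logistic fit of outcomes on the model covariates.

    Used for parameter-recovery validation and the optional real-data
    path; the simulation itself runs on a configured CoefficientSet.
    Returns a :class:`CoefficientSet` (network betas zero), or a
    ``(CoefficientSet, details)`` pair when ``details=True`` where
    ``details`` holds per-parameter standard errors and 95% confidence
    intervals on the natural (unscaled) coefficient scale.
    """
    y = np.asarray(outcomes, dtype=float)
    if y.size != len(agents):
        raise ValueError("outcomes length must match agents")
    if np.unique(y).size < 2:
        raise ValueError("all outcomes identical: need both outcome classes to fit")
    X = design_matrix(agents, da_lookup, include_support=include_support)
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            if penalize:
                res = model.fit_regularized(alpha=1.0, disp=0)
            else:
                res = model.fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(
            "perfect separation detected; re-fit with penalize=True"
        ) from exc

    params = dict(res.params)
    coeffs = CoefficientSet(beta_network_size=0.0, beta_depressed_ties=0.0)
    for col, name in _PARAM_TO_COEFF.items():
        if col in params:
            value = params[col]
            if col == "relative_income":
                value /= _REL_INCOME_SCALE
            setattr(coeffs, name, float(value))
    if not details:
        return coeffs

    bse = dict(res.bse)
    conf = res.conf_int(alpha=0.05)
    info = {}
    for col in X.columns:
        scale = _REL_INCOME_SCALE if col == "relative_income" else 1.0
        lo, hi = float(conf.loc[col, 0]) / scale, float(conf.loc[col, 1]) / scale
        info[_PARAM_TO_COEFF[col]] = {
            "stderr": float(bse[col]) / scale,
            "ci": (lo, hi),
            "pvalue": float(res.pvalues[col]),
        }
    return coeffs, info
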
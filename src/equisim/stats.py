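"""Summary quantities and significance tests for trial outcomes."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

__all__ = [
    "pct_change",
    "prevalence",
    "prevalence_test",
    "followup_from_accounting",
    "gini",
]


def pct_change(baseline_depressed: int, followup_depressed: int) -> float:
    """Percent reduction in prevalence from baseline to follow-up.

    Signed: negative means prevalence rose.  Rounded to 2 decimals, the
    precision at which results tables are reported.
    """
    if baseline_depressed <= 0:
        raise ValueError("baseline_depressed must be > 0")
    return round((baseline_depressed - followup_depressed) / baseline_depressed * 100.0, 2)


def prevalence(count: int, n: int) -> float:
    """Share of a population of size ``n`` with ``count`` cases."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= count <= n:
        raise ValueError("count must be in [0, n]")
    return count / n


def prevalence_test(
    baseline_depressed: int,
    followup_depressed: int,
    n: int,
    method: str = "two_proportion_z",
    *,
    incident: int | None = None,
    reduced: int | None = None,
) -> float:
    """Two-sided p-value for the baseline vs follow-up prevalence change.

    ``two_proportion_z`` is the pooled-variance z test on the two
    prevalences (treating the samples as independent).  ``mcnemar`` is the
    exact binomial test on the discordant pair counts (incident, reduced),
    which must be supplied.  Both are symmetric in direction.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    for count in (baseline_depressed, followup_depressed):
        if not 0 <= count <= n:
            raise ValueError("counts must be in [0, n]")
    if method == "two_proportion_z":
        if baseline_depressed == followup_depressed:
            return 1.0
        p1 = baseline_depressed / n
        p2 = followup_depressed / n
        pooled = (baseline_depressed + followup_depressed) / (2 * n)
        se = math.sqrt(pooled * (1.0 - pooled) * 2.0 / n)
        z = (p1 - p2) / se
        return float(2.0 * sps.norm.sf(abs(z)))
    if method == "mcnemar":
        if incident is None or reduced is None:
            raise ValueError("mcnemar requires incident and reduced discordant counts")
        if incident < 0 or reduced < 0:
            raise ValueError("discordant counts must be >= 0")
        n_disc = incident + reduced
        if n_disc == 0:
            return 1.0
        return float(min(1.0, 2.0 * sps.binom.cdf(min(incident, reduced), n_disc, 0.5)))
    raise ValueError(f"unknown method: {method!r}")


def followup_from_accounting(baseline_depressed: int, incident: int, reduced: int) -> int:
    """Follow-up depressed count implied by baseline + incident - reduced."""
    if min(baseline_depressed, incident, reduced) < 0:
        raise ValueError("counts must be >= 0")
    followup = baseline_depressed + incident - reduced
    if followup < 0:
        raise ValueError("accounting yields a negative follow-up count")
    return followup


def gini(incomes) -> float:
    """Gini coefficient via the sorted-rank formula (O(n log n)).

    Equals the mean absolute pairwise difference divided by twice the mean.
    """
    x = np.sort(np.asarray(incomes, dtype=float))
    if x.size == 0:
        raise ValueError("incomes must be nonempty")
    if np.any(x < 0):
        raise ValueError("incomes must be >= 0")
    total = x.sum()
    if total == 0:
        return 0.0
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * np.sum(ranks * x) - (n + 1) * total) / (n * total))
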
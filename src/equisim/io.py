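"""Schema'd CSV/JSON readers and writers for cohorts, DAs and results."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import Agent, DisseminationArea
from .engine import TrialResult

__all__ = [
    "write_das",
    "read_das",
    "write_cohort",
    "read_cohort",
    "write_results",
    "read_results_json",
]

DA_COLUMNS = [
    "da_id",
    "median_after_tax_income",
    "pct_lico",
    "pct_shelter_over_30",
    "pct_recent_immigrants",
]

COHORT_COLUMNS = [
    "agent_id",
    "da_id",
    "age",
    "education",
    "born_in_canada",
    "white",
    "household_income",
    "gov_support",
    "prenatal_care_access",
    "safety",
    "crime",
    "social_support_present",
    "ties",
    "depressed",
    "p_depressed",
    "income_band",
    "income_before_tax",
]

RESULT_COLUMNS = [
    "condition_id",
    "intervention_kind",
    "n",
    "baseline_depressed",
    "baseline_pct_depressed",
    "followup_depressed",
    "followup_pct_depressed",
    "incident_cases",
    "reduced_cases",
    "pct_change",
    "p_value",
    "seed",
]


def write_das(das: list[DisseminationArea], path: str | Path) -> None:
    pd.DataFrame(
        [[da.da_id, da.median_after_tax_income, da.pct_lico,
          da.pct_shelter_over_30, da.pct_recent_immigrants] for da in das],
        columns=DA_COLUMNS,
    ).to_csv(path, index=False)


def read_das(path: str | Path) -> list[DisseminationArea]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DA_COLUMNS, path)
    das = [
        DisseminationArea(
            da_id=int(r.da_id),
            median_after_tax_income=float(r.median_after_tax_income),
            pct_lico=float(r.pct_lico),
            pct_shelter_over_30=float(r.pct_shelter_over_30),
            pct_recent_immigrants=float(r.pct_recent_immigrants),
        )
        for r in df.itertuples()
    ]
    for da in das:
        da.validate()
    return das


def write_cohort(agents: list[Agent], path: str | Path) -> None:
    rows = []
    for a in agents:
        rows.append([
            a.agent_id, a.da_id, a.age, a.education,
            int(a.born_in_canada), int(a.white), a.household_income,
            int(a.gov_support), int(a.prenatal_care_access),
            a.safety, a.crime, int(a.social_support_present),
            ";".join(str(t) for t in sorted(a.ties)),
            int(a.depressed), a.p_depressed, a.income_band, a.income_before_tax,
        ])
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[Agent]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require_columns(df, COHORT_COLUMNS, path)
    agents = []
    for r in df.itertuples():
        ties = set() if r.ties == "" else {int(t) for t in str(r.ties).split(";")}
        agents.append(
            Agent(
                agent_id=int(r.agent_id),
                da_id=int(r.da_id),
                age=float(r.age),
                education=str(r.education),
                born_in_canada=bool(int(r.born_in_canada)),
                white=bool(int(r.white)),
                household_income=float(r.household_income),
                gov_support=bool(int(r.gov_support)),
                prenatal_care_access=bool(int(r.prenatal_care_access)),
                safety=float(r.safety),
                crime=float(r.crime),
                social_support_present=bool(int(r.social_support_present)),
                ties=ties,
                depressed=bool(int(r.depressed)),
                p_depressed=float(r.p_depressed),
                income_band=int(r.income_band),
                income_before_tax=float(r.income_before_tax),
            )
        )
    return agents


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def write_results(results: list[TrialResult], path: str | Path, format: str = "csv") -> None:
    """Write trial results as CSV (results-table column order, percentages
    to 2 decimals) or JSON (full fields including seed)."""
    if not results:
        raise ValueError("results must be nonempty")
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps([r.to_dict() for r in results], indent=2))
        return
    if format != "csv":
        raise ValueError(f"unknown format: {format!r}")
    rows = []
    for r in results:
        rows.append([
            r.condition_id, r.intervention_kind, r.n,
            r.baseline_depressed,
            f"{100.0 * r.baseline_depressed / r.n:.2f}",
            r.followup_depressed,
            f"{100.0 * r.followup_depressed / r.n:.2f}",
            r.incident_cases, r.reduced_cases,
            f"{r.pct_change:.2f}",
            f"{r.p_value:.3g}",
            r.seed,
        ])
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def read_results_json(path: str | Path) -> list[TrialResult]:
    data = json.loads(Path(path).read_text())
    return [TrialResult(**item) for item in data]
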
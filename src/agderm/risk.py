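"""Risk characterization: body-weight-normalized intakes and RCRs.

The intake accumulated over one simulated horizon (at most 24 h) is treated as
the daily dose, normalized by body weight and divided by the DNEL to give the
risk characterization ratio (RCR); RCR > 1 flags inadequately controlled risk.
Mass reaching the stratum corneum is conservatively assumed to enter systemic
circulation completely, and ingested mass is retained completely (F_ret = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .kinetics import MassTrajectory, simulate
from .scenarios import ExposureScenario, OralEvent, Subject

__all__ = [
    "RiskResult",
    "rcr",
    "inadvertent_oral_intake",
    "risk_records",
    "risk_table",
    "write_risk_csv",
]

NG_PER_MG = 1e6

ROUTES = ("stratum_corneum", "oral")


@dataclass(frozen=True)
class RiskResult:
    """Daily intake, body-weight-normalized intake, and RCR for one route."""

    intake_ng_per_day: float
    intake_ng_per_kg_day: float
    rcr: float
    dnel_mg_per_kg_day: float
    route: str = "stratum_corneum"


def rcr(
    intake_ng_per_day: float,
    subject: Subject = Subject(),
    route: str = "stratum_corneum",
) -> RiskResult:
    """Risk characterization ratio for a daily intake.

    ``rcr = (intake / bw, converted ng -> mg) / DNEL``.
    """
    if intake_ng_per_day < 0:
        raise ValueError(f"intake must be >= 0, got {intake_ng_per_day}")
    if route not in ROUTES:
        raise ValueError(f"route must be one of {ROUTES}, got {route!r}")
    per_bw = intake_ng_per_day / subject.body_weight_kg
    ratio = (per_bw / NG_PER_MG) / subject.dnel_mg_per_kg_day
    return RiskResult(
        intake_ng_per_day=intake_ng_per_day,
        intake_ng_per_kg_day=per_bw,
        rcr=ratio,
        dnel_mg_per_kg_day=subject.dnel_mg_per_kg_day,
        route=route,
    )


def inadvertent_oral_intake(
    skin_load_ng_cm2: float, event: OralEvent, n_events: int | None = None
) -> float:
    """Ingested mass (ng) from hand/finger-to-mouth contact.

    ``intake = load * contact_area * TF * n_events * F_ret``; with complete
    retention (F_ret = 1) everything mouthed is ingested.
    """
    if skin_load_ng_cm2 < 0:
        raise ValueError("skin load must be >= 0")
    n = event.n_events if n_events is None else n_events
    return (
        skin_load_ng_cm2
        * event.contact_area
        * event.transfer_efficiency
        * n
        * event.retention
    )


def _scenario_risk_rows(
    scenario: ExposureScenario, trajectory: MassTrajectory
) -> list[dict[str, object]]:
    rows = []
    for route, intake in (
        ("stratum_corneum", trajectory.sc_intake),
        ("oral", trajectory.oral_intake),
    ):
        result = rcr(intake, scenario.subject, route)
        rows.append(
            {
                "label": scenario.label,
                "family": scenario.family or scenario.label,
                "skin": scenario.skin_condition or "",
                "route": route,
                "intake_ng": result.intake_ng_per_day,
                "intake_ng_per_kg_day": result.intake_ng_per_kg_day,
                "rcr": result.rcr,
                "dnel_mg_kg_day": result.dnel_mg_per_kg_day,
            }
        )
    return rows


RISK_CSV_COLUMNS = [
    "label",
    "family",
    "skin",
    "route",
    "intake_ng",
    "intake_ng_per_kg_day",
    "rcr",
    "dnel_mg_kg_day",
]


def risk_records(scenarios: Sequence[ExposureScenario], dt: float = 0.1) -> pd.DataFrame:
    """Simulate each scenario and return a long-format risk table.

    One row per scenario and route, with intake (ng), body-weight-normalized
    intake and RCR columns.  Deterministic input order is preserved.
    """
    rows: list[dict[str, object]] = []
    for scenario in scenarios:
        trajectory = simulate(scenario, dt=dt)
        rows.extend(_scenario_risk_rows(scenario, trajectory))
    return pd.DataFrame(rows, columns=RISK_CSV_COLUMNS)


def risk_table(scenarios: Sequence[ExposureScenario], dt: float = 0.1) -> pd.DataFrame:
    """Wide summary: one row per textile family, columns per skin type.

    Stratum-corneum intakes (ng) and the corresponding RCRs, ordered by first
    appearance of family and skin type.  The RCR columns follow strictly from
    the intake, body weight and DNEL; see the package docs for why they do not
    match some published RCR tabulations.
    """
    records = risk_records(scenarios, dt=dt)
    records = records[records["route"] == "stratum_corneum"]
    if records.empty:
        return pd.DataFrame(
            columns=pd.MultiIndex.from_tuples([], names=["quantity", "skin"])
        )
    fam_order = list(dict.fromkeys(records["family"]))
    skin_order = list(dict.fromkeys(records["skin"]))
    intake = records.pivot_table(
        index="family", columns="skin", values="intake_ng", sort=False
    ).reindex(index=fam_order, columns=skin_order)
    ratios = records.pivot_table(
        index="family", columns="skin", values="rcr", sort=False
    ).reindex(index=fam_order, columns=skin_order)
    table = pd.concat({"intake_ng": intake, "rcr": ratios}, axis=1)
    table.columns.names = ["quantity", "skin"]
    return table


def write_risk_csv(records: pd.DataFrame | Iterable[ExposureScenario], path: str | Path) -> None:
    """Write a long-format risk table to CSV ('.' decimals, UTF-8, header row)."""
    if not isinstance(records, pd.DataFrame):
        records = risk_records(list(records))
    records.to_csv(path, index=False, encoding="utf-8")
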
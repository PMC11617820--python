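"""Declarative exposure scenarios consumed by the kinetics engine.

A scenario bundles a textile product, the rate constants, a wear schedule
(intervals during which the garment is on the skin and releasing), optional
discrete mouthing events, an optional washing time and the exposed subject.
Builders are provided for the reference scenarios: 8-h face-mask wear, the
reasonable-worst-case full-body suit, glove wear followed by finger mouthing,
and the 60-min sweaty sport scenario used for cross-model comparison.

When a wear interval ends without washing, the garment (and its residual Ag)
leaves the skin, but the deposit already on the skin surface remains and keeps
feeding the stratum corneum until the simulation horizon.  Washing, when
scheduled, removes the skin-surface deposit at the stated time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import params
from .kinetics import RateConstants, TextileProduct

__all__ = [
    "Subject",
    "OralEvent",
    "IndirectContactEvent",
    "ExposureScenario",
    "wear_schedule",
    "face_mask_scenario",
    "full_body_scenario",
    "glove_mouthing_scenario",
    "indirect_contact_load",
    "sport_scenario",
    "load_scenario_config",
    "MissingSupplementaryData",
]


@dataclass(frozen=True)
class Subject:
    """Exposed person: body weight and the DNEL used for risk characterization."""

    body_weight_kg: float = params.DEFAULT_BODY_WEIGHT_KG
    dnel_mg_per_kg_day: float = params.DEFAULT_DNEL_MG_PER_KG_DAY

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError(f"body weight must be > 0 kg, got {self.body_weight_kg}")
        if self.dnel_mg_per_kg_day <= 0:
            raise ValueError(f"DNEL must be > 0, got {self.dnel_mg_per_kg_day}")


@dataclass(frozen=True)
class OralEvent:
    """A discrete hand/finger-to-mouth transfer.

    At ``time_min`` the skin areal load over ``contact_area`` cm^2 is moved to
    the oral compartment with efficiency ``transfer_efficiency`` and retention
    ``retention`` (1 = complete ingestion), ``n_events`` times.
    """

    time_min: float
    contact_area: float
    transfer_efficiency: float
    retention: float = 1.0
    n_events: int = 1
    events_per_hour: float | None = None

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("event time must be >= 0")
        if self.contact_area < 0:
            raise ValueError("contact area must be >= 0")
        if not 0.0 <= self.transfer_efficiency <= 1.0:
            raise ValueError(
                f"transfer efficiency must lie in [0, 1], got {self.transfer_efficiency}"
            )
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError(f"retention must lie in [0, 1], got {self.retention}")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass(frozen=True)
class IndirectContactEvent:
    """Skin contact with a contaminated surface (instant application source)."""

    surface_contamination: float  # ng/cm^2
    contact_area: float  # cm^2
    transfer_efficiency: float

    def __post_init__(self) -> None:
        if self.surface_contamination < 0 or self.contact_area < 0:
            raise ValueError("surface contamination and contact area must be >= 0")
        if not 0.0 <= self.transfer_efficiency <= 1.0:
            raise ValueError(
                f"transfer efficiency must lie in [0, 1], got {self.transfer_efficiency}"
            )


def indirect_contact_load(event: IndirectContactEvent) -> float:
    """Mass (ng) instantaneously transferred to skin from a contaminated surface."""
    return event.surface_contamination * event.contact_area * event.transfer_efficiency


@dataclass(frozen=True)
class ExposureScenario:
    """A fully specified exposure run for the kinetics engine."""

    product: TextileProduct
    rates: RateConstants
    wear_intervals: tuple[tuple[float, float], ...]  # minutes
    horizon_min: float
    oral_events: tuple[OralEvent, ...] = ()
    subject: Subject = field(default_factory=Subject)
    wash_at_min: float | None = None
    initial_skin_mass: float = 0.0  # ng, e.g. from an indirect contact
    sc_lag_min: float = 0.0  # optional permeation lag before k_sc activates
    label: str = ""
    family: str | None = None
    skin_condition: str | None = None

    def __post_init__(self) -> None:
        if self.horizon_min < 0:
            raise ValueError(f"horizon must be >= 0, got {self.horizon_min}")
        prev_end = None
        for start, end in self.wear_intervals:
            if start < 0 or end > self.horizon_min + 1e-9:
                raise ValueError(
                    f"wear interval ({start}, {end}) min lies outside [0, {self.horizon_min}]"
                )
            if end <= start:
                raise ValueError(f"wear interval ({start}, {end}) min is empty or reversed")
            if prev_end is not None and start < prev_end:
                raise ValueError("wear intervals must be ordered and non-overlapping")
            prev_end = end
        for ev in self.oral_events:
            if ev.time_min > self.horizon_min + 1e-9:
                raise ValueError(f"oral event at {ev.time_min} min lies beyond the horizon")
        if self.wash_at_min is not None and not 0 <= self.wash_at_min <= self.horizon_min:
            raise ValueError("washing time must lie within [0, horizon]")
        if self.initial_skin_mass < 0:
            raise ValueError("initial skin mass must be >= 0")
        if self.sc_lag_min < 0:
            raise ValueError("permeation lag must be >= 0")


def wear_schedule(total_horizon_h: float, wear_h: float) -> tuple[tuple[float, float], ...]:
    """Wear intervals (minutes) for a single wear period starting at t=0.

    The garment is worn for ``wear_h`` hours of a ``total_horizon_h``-hour
    horizon; after the garment comes off, the skin deposit remains (no
    washing) and keeps feeding the loss compartments until the horizon.
    """
    if total_horizon_h < 0 or wear_h < 0:
        raise ValueError("durations must be >= 0")
    if wear_h > total_horizon_h + 1e-12:
        raise ValueError(
            f"wear time {wear_h} h exceeds the simulation horizon {total_horizon_h} h"
        )
    if wear_h == 0:
        return ()
    return ((0.0, wear_h * 60.0),)


def _family_product(family: str, area_cm2: float, label: str) -> TextileProduct:
    if family not in params.TEXTILE_FAMILIES:
        raise ValueError(
            f"unknown textile family {family!r}; expected one of {params.TEXTILE_FAMILIES}"
        )
    return TextileProduct(
        areal_load=params.FAMILY_MEAN_LOAD[family],
        contact_area=area_cm2,
        label=label,
    )


def _skin_rate(skin_condition: str) -> float:
    try:
        return params.REPORTED_KSC_PER_H[skin_condition]
    except KeyError:
        raise ValueError(
            f"unknown skin condition {skin_condition!r}; expected one of "
            f"{sorted(params.REPORTED_KSC_PER_H)}"
        ) from None


def _wear_scenario(
    family: str,
    skin_condition: str,
    wear_hours: float,
    area_cm2: float,
    horizon_hours: float | None,
    label: str,
    subject: Subject,
) -> ExposureScenario:
    horizon = wear_hours if horizon_hours is None else horizon_hours
    return ExposureScenario(
        product=_family_product(family, area_cm2, label),
        rates=RateConstants(
            k_p=params.FAMILY_MEAN_KP[family],
            k_sc_per_h=_skin_rate(skin_condition),
        ),
        wear_intervals=wear_schedule(horizon, wear_hours),
        horizon_min=horizon * 60.0,
        subject=subject,
        label=label,
        family=family,
        skin_condition=skin_condition,
    )


def face_mask_scenario(
    textile_family: str,
    skin_condition: str,
    wear_hours: float = 8.0,
    horizon_hours: float | None = None,
    subject: Subject = Subject(),
) -> ExposureScenario:
    """8-h (default) wear of a coated face mask, contact area 555 cm^2.

    Family-average areal load and abrasion release constant are used; the
    stratum-corneum constant comes from the skin-condition permeation table.
    ``horizon_hours`` defaults to the wear time; set it longer to keep the
    skin deposit absorbing after the mask comes off.
    """
    return _wear_scenario(
        textile_family,
        skin_condition,
        wear_hours,
        params.FACE_MASK_AREA_CM2,
        horizon_hours,
        f"face-mask {textile_family} {skin_condition} {wear_hours}h",
        subject,
    )


def full_body_scenario(
    textile_family: str,
    skin_condition: str,
    wear_hours: float = 8.0,
    horizon_hours: float | None = None,
    subject: Subject = Subject(),
) -> ExposureScenario:
    """Reasonable-worst-case full-body suit, contact area 20 000 cm^2 (2 m^2)."""
    return _wear_scenario(
        textile_family,
        skin_condition,
        wear_hours,
        params.FULL_BODY_AREA_CM2,
        horizon_hours,
        f"full-body {textile_family} {skin_condition} {wear_hours}h",
        subject,
    )


def glove_mouthing_scenario(
    textile_family: str = "AgCur",
    wear_hours: float = 1.0,
    fingertip_area: float = params.THREE_FINGERTIPS_AREA_CM2,
    transfer_efficiency: float = 0.1,
    skin_condition: str = "fresh",
    hand_area: float = params.HAND_AREA_CM2,
    subject: Subject = Subject(),
) -> ExposureScenario:
    """Glove wear followed by mouthing three fingertips at the end of wear.

    The dermal phase runs on both hands (900 cm^2 by default); a single oral
    event at the end of wear transfers the skin areal load on
    ``fingertip_area`` cm^2 with the given transfer efficiency and complete
    retention.  The default transfer efficiency of 0.1 is an inferred
    calibration, not a measured value, and is exposed as an argument.
    """
    if fingertip_area > hand_area:
        raise ValueError(
            f"fingertip contact area {fingertip_area} cm^2 exceeds the exposed "
            f"hand area {hand_area} cm^2"
        )
    horizon = wear_hours * 60.0
    return ExposureScenario(
        product=_family_product(textile_family, hand_area, "gloves"),
        rates=RateConstants(
            k_p=params.FAMILY_MEAN_KP[textile_family],
            k_sc_per_h=_skin_rate(skin_condition),
        ),
        wear_intervals=wear_schedule(wear_hours, wear_hours),
        horizon_min=horizon,
        oral_events=(
            OralEvent(
                time_min=horizon,
                contact_area=fingertip_area,
                transfer_efficiency=transfer_efficiency,
            ),
        ),
        subject=subject,
        label=f"gloves {textile_family} {wear_hours}h + finger mouthing",
        family=textile_family,
        skin_condition=skin_condition,
    )


class MissingSupplementaryData(ValueError):
    """Raised when a scenario needs parameters not printed in the main tables."""


def sport_scenario(config: dict[str, Any], subject: Subject = Subject()) -> list[ExposureScenario]:
    """60-min sweaty sport scenario (T-shirt + trousers), one scenario per garment.

    Garment Ag contents (mg/kg) and immersion release constants are published;
    the garment weights are not printed in the main tables and must be supplied
    via ``config`` as ``{"garment_masses_kg": {"t-shirt": ..., "trousers": ...}}``
    (they live in the study's supplementary Table S1).  Dermal exposure is the
    summed cumulative emission at 60 min; intake uses fresh-skin permeation.
    """
    masses = (config or {}).get("garment_masses_kg")
    if not masses:
        raise MissingSupplementaryData(
            "the sport scenario requires garment masses (kg) from supplementary "
            "Table S1; pass config={'garment_masses_kg': {'t-shirt': ..., "
            "'trousers': ...}}"
        )
    duration_h = float((config or {}).get("duration_h", 1.0))
    scenarios = []
    for garment, (ag_mg_per_kg, *_fractions, k_reported) in params.IMMERSION_GARMENTS.items():
        if garment not in masses:
            raise MissingSupplementaryData(
                f"garment mass for {garment!r} missing from config (Table S1 value)"
            )
        k_p = float((config or {}).get("release_constants_per_min", {}).get(garment, k_reported))
        m0_ng = ag_mg_per_kg * float(masses[garment]) * 1e6  # mg -> ng
        scenarios.append(
            ExposureScenario(
                product=TextileProduct(areal_load=m0_ng, contact_area=1.0, label=garment),
                rates=RateConstants(k_p=k_p, k_sc_per_h=params.REPORTED_KSC_PER_H["fresh"]),
                wear_intervals=wear_schedule(duration_h, duration_h),
                horizon_min=duration_h * 60.0,
                subject=subject,
                label=f"sport {garment}",
            )
        )
    return scenarios


# --- YAML scenario configs ---------------------------------------------------

_SCHEMA: dict[str, dict[str, tuple[bool, type]]] = {
    "product": {"load_ng_cm2": (True, float), "area_cm2": (True, float), "fa": (False, float)},
    "rates": {
        "kp_per_min": (True, float),
        "ksc_per_h": (True, float),
        "ko_per_min": (False, float),
        "kww_per_min": (False, float),
    },
    "schedule": {"horizon_h": (True, float), "wear_h": (True, float), "wash_at_h": (False, float)},
    "oral": {
        "time_h": (True, float),
        "area_cm2": (True, float),
        "tf": (True, float),
        "fret": (False, float),
    },
    "subject": {"bw_kg": (False, float), "dnel_mg_kg_day": (False, float)},
}
_OPTIONAL_SECTIONS = {"oral", "subject"}


def _validate_section(name: str, raw: Any) -> dict[str, float]:
    spec = _SCHEMA[name]
    if not isinstance(raw, dict):
        raise ValueError(f"config section '{name}' must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(spec)
    if unknown:
        raise ValueError(f"config section '{name}' has unknown keys {sorted(unknown)}")
    out: dict[str, float] = {}
    for key, (required, typ) in spec.items():
        if key not in raw:
            if required:
                raise ValueError(f"config section '{name}' is missing required key '{key}'")
            continue
        try:
            out[key] = typ(raw[key])
        except (TypeError, ValueError):
            raise ValueError(
                f"config key '{name}.{key}' must be a number, got {raw[key]!r}"
            ) from None
    return out


def load_scenario_config(source: str | Path | dict[str, Any]) -> ExposureScenario:
    """Build a scenario from a YAML file (or an equivalent mapping).

    Schema (sections ``oral`` and ``subject`` optional)::

        product:  {load_ng_cm2, area_cm2, fa}
        rates:    {kp_per_min, ksc_per_h, ko_per_min, kww_per_min}
        schedule: {horizon_h, wear_h, wash_at_h}
        oral:     {time_h, area_cm2, tf, fret}
        subject:  {bw_kg, dnel_mg_kg_day}
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        origin = str(source)
    else:
        raw, origin = source, "<dict>"
    if not isinstance(raw, dict):
        raise ValueError(f"{origin}: scenario config must be a mapping")
    unknown = set(raw) - set(_SCHEMA) - {"label"}
    if unknown:
        raise ValueError(f"{origin}: unknown config sections {sorted(unknown)}")
    for section in set(_SCHEMA) - _OPTIONAL_SECTIONS:
        if section not in raw:
            raise ValueError(f"{origin}: missing required config section '{section}'")

    product_cfg = _validate_section("product", raw["product"])
    rates_cfg = _validate_section("rates", raw["rates"])
    schedule_cfg = _validate_section("schedule", raw["schedule"])

    product = TextileProduct(
        areal_load=product_cfg["load_ng_cm2"],
        contact_area=product_cfg["area_cm2"],
        available_fraction=product_cfg.get("fa", 1.0),
        label=str(raw.get("label", "")),
    )
    rates = RateConstants(
        k_p=rates_cfg["kp_per_min"],
        k_sc_per_h=rates_cfg["ksc_per_h"],
        k_o=rates_cfg.get("ko_per_min", 0.0),
        k_ww=rates_cfg.get("kww_per_min", 0.0),
    )
    oral_events: tuple[OralEvent, ...] = ()
    if "oral" in raw:
        oral_cfg = _validate_section("oral", raw["oral"])
        oral_events = (
            OralEvent(
                time_min=oral_cfg["time_h"] * 60.0,
                contact_area=oral_cfg["area_cm2"],
                transfer_efficiency=oral_cfg["tf"],
                retention=oral_cfg.get("fret", 1.0),
            ),
        )
    subject = Subject()
    if "subject" in raw:
        subj_cfg = _validate_section("subject", raw["subject"])
        subject = Subject(
            body_weight_kg=subj_cfg.get("bw_kg", params.DEFAULT_BODY_WEIGHT_KG),
            dnel_mg_per_kg_day=subj_cfg.get(
                "dnel_mg_kg_day", params.DEFAULT_DNEL_MG_PER_KG_DAY
            ),
        )
    wash = schedule_cfg.get("wash_at_h")
    return ExposureScenario(
        product=product,
        rates=rates,
        wear_intervals=wear_schedule(schedule_cfg["horizon_h"], schedule_cfg["wear_h"]),
        horizon_min=schedule_cfg["horizon_h"] * 60.0,
        oral_events=oral_events,
        subject=subject,
        wash_at_min=None if wash is None else wash * 60.0,
        label=str(raw.get("label", "")),
    )


def with_subject(scenario: ExposureScenario, subject: Subject) -> ExposureScenario:
    """Return a copy of ``scenario`` for a different subject."""
    return replace(scenario, subject=subject)
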
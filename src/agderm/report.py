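"""Recompute the published modelling results from in-text parameters.

Every quantity here is recomputed at run time from the parameter tables in
:mod:`agderm.params` by running the estimation and simulation code — nothing
is looked up.  The registry drives both the ``agderm reproduce-paper`` command
and the acceptance checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from . import params
from .kinetics import cumulative_intake_closed_form, flux_to_rate_constant, simulate, source_emission
from .release import ReleaseExperiment, aggregate_group, estimate_rate_constant
from .risk import rcr
from .scenarios import Subject, face_mask_scenario, full_body_scenario

__all__ = [
    "Check",
    "round_sig",
    "abrasion_estimates",
    "family_mean_k",
    "scenario_intake_ng",
    "wear_time_reduction_ng",
    "table4_comparison",
    "run_checks",
    "CAVEATS",
]


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class Check:
    """One computed-vs-published comparison."""

    check_id: str
    description: str
    computed: float
    published: float
    units: str
    tolerance: str  # human-readable statement of the comparison applied
    passed: bool


# --- estimation-side quantities ----------------------------------------------

def abrasion_estimates() -> dict[str, float]:
    """Per-sample abrasion release constants (1/min) from the 10-s releases."""
    out = {}
    for sample, (load, release) in params.ABRASION_RELEASES.items():
        exp = ReleaseExperiment(
            duration_min=params.ABRASION_DURATION_MIN,
            donor_initial=load,
            receptor_mass=release,
            medium="abrasion-sweat",
            sample_label=sample,
        )
        out[sample] = estimate_rate_constant(exp).k
    return out


def family_mean_k(family: str) -> float:
    """Family mean abrasion release constant (1/min)."""
    estimates = [
        estimate_rate_constant(
            ReleaseExperiment(
                duration_min=params.ABRASION_DURATION_MIN,
                donor_initial=load,
                receptor_mass=release,
                sample_label=sample,
            )
        )
        for sample, (load, release) in params.ABRASION_RELEASES.items()
        if params.family_of(sample) == family
    ]
    return aggregate_group(estimates).k_mean


# --- simulation-side quantities ----------------------------------------------

def scenario_intake_ng(
    family: str, skin: str, area: str = "face-mask", dt: float = 0.1
) -> float:
    """8-h stratum-corneum intake (ng) for a wear scenario."""
    builder = face_mask_scenario if area == "face-mask" else full_body_scenario
    return simulate(builder(family, skin, wear_hours=8.0), dt=dt).sc_intake


def wear_time_reduction_ng(wear_h: float, dt: float = 0.1) -> float:
    """Intake lost (ng) when AgCur face-mask wear is shortened from 8 h.

    Both runs keep the 8-h horizon and fresh skin; the skin deposit is
    retained (no washing) after the mask comes off.
    """
    full = simulate(face_mask_scenario("AgCur", "fresh", wear_hours=8.0), dt=dt)
    short = simulate(
        face_mask_scenario("AgCur", "fresh", wear_hours=wear_h, horizon_hours=8.0), dt=dt
    )
    return full.sc_intake - short.sc_intake


#: published 8-h intake numerals (their printed column header reads ug; the
#: values are only consistent with ng — see CAVEATS)
PUBLISHED_TABLE4_NG: dict[tuple[str, str, str], float] = {
    ("face-mask", "AgCur", "fresh"): 12,
    ("face-mask", "AgCur", "cryopreserved"): 18,
    ("face-mask", "AgCur", "glycerolized"): 225,
    ("face-mask", "AgHEC6.4", "fresh"): 13,
    ("face-mask", "AgHEC6.4", "cryopreserved"): 19,
    ("face-mask", "AgHEC6.4", "glycerolized"): 245,
    ("face-mask", "AgHEC", "fresh"): 11,
    ("face-mask", "AgHEC", "cryopreserved"): 17,
    ("face-mask", "AgHEC", "glycerolized"): 212,
    ("full-body", "AgCur", "fresh"): 429,
    ("full-body", "AgCur", "cryopreserved"): 643,
    ("full-body", "AgCur", "glycerolized"): 8099,
    ("full-body", "AgHEC6.4", "fresh"): 468,
    ("full-body", "AgHEC6.4", "cryopreserved"): 702,
    ("full-body", "AgHEC6.4", "glycerolized"): 8835,
    ("full-body", "AgHEC", "fresh"): 405,
    ("full-body", "AgHEC", "cryopreserved"): 607,
    ("full-body", "AgHEC", "glycerolized"): 7647,
}


def table4_comparison(dt: float = 0.1) -> pd.DataFrame:
    """Computed vs published 8-h intakes for all 18 scenario cells."""
    rows = []
    for (area, family, skin), published in PUBLISHED_TABLE4_NG.items():
        computed = scenario_intake_ng(family, skin, area, dt=dt)
        rel = abs(computed - published) / published
        rows.append(
            {
                "scenario": area,
                "family": family,
                "skin": skin,
                "computed_ng": computed,
                "published_ng": published,
                "rel_diff": rel,
                "within_2pct": rel <= 0.02,
            }
        )
    return pd.DataFrame(rows)


CAVEATS = [
    "The published intake column is headed '[ug]' but its numerals are only "
    "consistent with nanograms: 12 ng over 8 h on fresh skin is 0.0014% of the "
    "face-mask load, matching the quoted penetration percentage, whereas 12 ug "
    "would exceed the entire 0.85-mg donor mass. Intakes are reported here in ng.",
    "The published RCR columns (0.001-0.9) cannot be derived from the printed "
    "intakes with the stated normalization (bw 60 kg, DNEL 0.01 mg/kg-bw/day) "
    "under any unit reading of the intake column; e.g. 12 ng/day gives "
    "RCR 2e-6, and 12 ug/day gives 2e-5. The RCR column computed here follows "
    "strictly from the stated formula and is NOT expected to match the "
    "published RCR tabulation. The 60-min sport-comparison chain "
    "(2.6 ng -> 0.043 ng/kg-bw -> RCR 4.3e-6) is internally consistent and is "
    "reproduced.",
    "Permeation lag times are ignored (the published 8-h intakes are only "
    "obtainable with zero lag); a lag can be enabled per scenario.",
    "The intact-skin permeation row does not reproduce from its own flux and "
    "donor load (0.02 / 70000 = 0.29e-6 1/h, published as 0.27e-6); the "
    "conversion check for that row is expected to flag a mismatch.",
]


def run_checks(dt: float = 0.1) -> list[Check]:
    """Run every desk-scale computed-vs-published comparison."""
    checks: list[Check] = []

    # Permeation flux -> rate-constant conversions, exact at printed precision.
    for cond, printed in params.REPORTED_KSC_PER_H.items():
        computed = flux_to_rate_constant(params.SKIN_PERMEATION[cond])
        checks.append(
            Check(
                f"ksc_{cond}",
                f"permeation rate constant, {cond} skin",
                computed,
                printed,
                "1/h",
                "equal after rounding to 2 significant figures",
                round_sig(computed, 2) == printed,
            )
        )

    # Single-sample abrasion constant and the three family means.
    k_a = abrasion_estimates()["AgCurA"]
    checks.append(
        Check(
            "abrasion_k_AgCurA",
            "abrasion release constant, sample AgCurA",
            k_a,
            params.REPORTED_ABRASION_K["AgCurA"],
            "1/min",
            "equal after rounding to 2 significant figures",
            round_sig(k_a, 2) == params.REPORTED_ABRASION_K["AgCurA"],
        )
    )
    for family, printed in params.FAMILY_MEAN_KP.items():
        mean_k = family_mean_k(family)
        checks.append(
            Check(
                f"abrasion_k_mean_{family}",
                f"mean abrasion release constant, {family}",
                mean_k,
                printed,
                "1/min",
                "equal after rounding to 2 significant figures",
                round_sig(mean_k, 2) == printed,
            )
        )

    # First-hour release fraction of the face-mask source.
    _, cumulative = source_emission(60.0, params.FAMILY_MEAN_KP["AgCur"], 1.0)
    released_pct = 100.0 * cumulative
    checks.append(
        Check(
            "first_hour_release_pct",
            "textile Ag released during the first hour of wear (AgCur)",
            released_pct,
            99.0,
            "%",
            "at least the published percentage",
            released_pct >= 99.0,
        )
    )

    # 8-h fresh-skin penetration fraction and the skin-type ratios.
    fresh = scenario_intake_ng("AgCur", "fresh", dt=dt)
    m_p0 = params.FAMILY_MEAN_LOAD["AgCur"] * params.FACE_MASK_AREA_CM2
    pen_pct = 100.0 * fresh / m_p0
    checks.append(
        Check(
            "fresh_penetration_pct",
            "fraction of Ag in stratum corneum after 8-h wear, fresh skin",
            pen_pct,
            0.0014,
            "%",
            "equal after rounding to 2 significant figures",
            round_sig(pen_pct, 2) == 0.0014,
        )
    )
    cryo = scenario_intake_ng("AgCur", "cryopreserved", dt=dt)
    gly = scenario_intake_ng("AgCur", "glycerolized", dt=dt)
    checks.append(
        Check(
            "cryo_fresh_ratio",
            "cryopreserved / fresh 8-h absorption ratio",
            cryo / fresh,
            1.5,
            "fold",
            "equal to 1 decimal place",
            round(cryo / fresh, 1) == 1.5,
        )
    )
    checks.append(
        Check(
            "glycerolized_fresh_ratio",
            "glycerolized / fresh 8-h absorption ratio",
            gly / fresh,
            19.0,
            "fold",
            "equal after rounding to the nearest integer",
            round(gly / fresh) == 19,
        )
    )

    # Representative 8-h intake numerals (face mask and full body).
    checks.append(
        Check(
            "facemask_AgCur_glycerolized_ng",
            "8-h face-mask intake, AgCur, glycerolized skin",
            gly,
            225.0,
            "ng",
            "within 2% of the published numeral",
            abs(gly - 225.0) / 225.0 <= 0.02,
        )
    )
    full_body = scenario_intake_ng("AgHEC6.4", "glycerolized", area="full-body", dt=dt)
    checks.append(
        Check(
            "fullbody_AgHEC6.4_glycerolized_ng",
            "8-h full-body intake, AgHEC6.4, glycerolized skin",
            full_body,
            8835.0,
            "ng",
            "within 2% of the published numeral",
            abs(full_body - 8835.0) / 8835.0 <= 0.02,
        )
    )

    # Wear-time effect: 30-min wear loses ~1 ng over the 8-h horizon.
    reduction = wear_time_reduction_ng(0.5, dt=dt)
    checks.append(
        Check(
            "wear_30min_reduction_ng",
            "intake reduction for 30-min wear vs 8-h wear, fresh skin",
            reduction,
            1.0,
            "ng",
            "equal after rounding to the nearest ng",
            round(reduction) == 1,
        )
    )
    reduction_2h = wear_time_reduction_ng(2.0, dt=dt)
    full_intake = simulate(face_mask_scenario("AgCur", "fresh", wear_hours=8.0), dt=dt).sc_intake
    checks.append(
        Check(
            "wear_2h_similarity_pct",
            "relative intake difference, 2-h vs 8-h wear, fresh skin",
            100.0 * reduction_2h / full_intake,
            0.0,
            "%",
            "within 1% (published: 'similar intake levels')",
            abs(reduction_2h / full_intake) <= 0.01,
        )
    )

    # Internally consistent RCR chain from the 60-min sport comparison.
    result = rcr(2.6, Subject())
    checks.append(
        Check(
            "sport_rcr",
            "RCR for a 2.6 ng daily intake (bw 60 kg, DNEL 0.01 mg/kg-bw/day)",
            result.rcr,
            4.3e-6,
            "-",
            "equal after rounding to 2 significant figures",
            round_sig(result.rcr, 2) == 4.3e-6,
        )
    )

    # Closed-form cross-check of the integrator on the worst-case cell.
    closed = cumulative_intake_closed_form(
        8.0, params.FAMILY_MEAN_LOAD["AgHEC6.4"] * params.FULL_BODY_AREA_CM2, 0.12, 34e-6
    )
    checks.append(
        Check(
            "ode_vs_closed_form_pct",
            "ODE vs closed-form intake discrepancy, worst-case scenario",
            100.0 * abs(full_body - closed) / closed,
            0.1,
            "%",
            "below 0.1%",
            abs(full_body - closed) / closed < 1e-3,
        )
    )
    return checks


def checks_frame(dt: float = 0.1) -> pd.DataFrame:
    """The check registry as a DataFrame (one row per comparison)."""
    return pd.DataFrame([c.__dict__ for c in run_checks(dt=dt)])
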
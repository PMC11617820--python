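"""Published model parameters for the Ag-nanoparticle textile assessment.

These constants are the measured/reported inputs of the exposure model:
Franz-cell permeation measurements per skin condition, per-sample textile Ag
loads, the 10-second crock-meter abrasion releases used to derive textile
release-rate constants, family-average scenario parameters, and the regulatory
defaults (body weight, DNEL) used for risk characterization.
"""

from __future__ import annotations

from .kinetics import SkinPermeationParams

# --- skin permeation (Franz diffusion cell, synthetic sweat) -----------------
# flux ng/cm^2/h, donor load ug/cm^2, lag h.  For intact and damaged skin the
# reported lag is only an upper bound (< 1 h); stored as 1.0.
SKIN_PERMEATION: dict[str, SkinPermeationParams] = {
    "fresh": SkinPermeationParams(0.2, 113.0, 8.2, "fresh"),
    "cryopreserved": SkinPermeationParams(0.3, 113.0, 10.9, "cryopreserved"),
    "glycerolized": SkinPermeationParams(3.8, 113.0, 6.3, "glycerolized"),
    "intact": SkinPermeationParams(0.02, 70.0, 1.0, "intact"),
    "damaged": SkinPermeationParams(0.10, 70.0, 1.0, "damaged"),
}

#: published rounded k_sc values (1/h) corresponding to SKIN_PERMEATION; these
#: rounded constants are the scenario defaults (they are what the reported
#: scenario results were computed with).
REPORTED_KSC_PER_H: dict[str, float] = {
    "fresh": 1.8e-6,
    "cryopreserved": 2.7e-6,
    "glycerolized": 34e-6,
    "intact": 0.27e-6,
    "damaged": 1.4e-6,
}

# --- textile Ag loads per coated sample (ICP-MS), ng/cm^2 --------------------
# sample code -> (mean, sd)
TEXTILE_LOADS: dict[str, tuple[float, float]] = {
    "AgCurA": (849.0, 31.0),
    "AgCurB": (1444.0, 203.0),
    "AgCurC": (1530.0, 151.0),
    "AgCurC(P)": (1147.0, 165.0),
    "AgCurD": (1957.0, 22.0),
    "AgCurE": (2258.0, 14.0),
    "AgHEC6.4A": (1149.0, 144.0),
    "AgHEC6.4B": (1222.0, 49.0),
    "AgHEC6.4C": (1538.0, 41.0),
    "AgHEC6.4C(P)": (1529.0, 82.0),
    "AgHEC6.4D": (1861.0, 96.0),
    "AgHEC6.4E": (2651.0, 399.0),
    "AgHECC": (1311.0, 671.0),
    "AgHECC(P)": (1406.0, 318.0),
    "AgHECD": (1574.0, 302.0),
}

TEXTILE_FAMILIES: tuple[str, ...] = ("AgCur", "AgHEC6.4", "AgHEC")


def family_of(sample: str) -> str:
    """Map a coated-sample code (e.g. ``AgCurC(P)``) to its textile family."""
    for fam in sorted(TEXTILE_FAMILIES, key=len, reverse=True):
        if sample.startswith(fam):
            return fam
    raise ValueError(f"unknown textile sample code {sample!r}")


# --- 10-second sweaty abrasion releases, unwashed textiles -------------------
# sample -> (initial load ng/cm^2, release to receptor ng/cm^2)
ABRASION_RELEASES: dict[str, tuple[float, float]] = {
    "AgCurA": (849.0, 17.6),
    "AgCurB": (1444.0, 12.6),
    "AgCurC": (1530.0, 19.1),
    "AgCurC(P)": (1147.0, 17.9),
    "AgCurD": (1957.0, 27.6),
    "AgCurE": (2258.0, 31.7),
    "AgHEC6.4A": (1149.0, 25.0),
    "AgHEC6.4B": (1222.0, 33.1),
    "AgHEC6.4C": (1538.0, 34.1),
    "AgHEC6.4C(P)": (1529.0, 16.4),
    "AgHEC6.4D": (1861.0, 40.7),
    "AgHEC6.4E": (2651.0, 47.3),
    "AgHECC": (1311.0, 35.9),
    "AgHECC(P)": (1406.0, 23.3),
    "AgHECD": (1574.0, 49.7),
}

#: abrasion contact duration: 10 rubbing cycles of 1 s
ABRASION_DURATION_MIN: float = 10.0 / 60.0

#: published per-sample abrasion release constants k_a (1/min) and release %
REPORTED_ABRASION_K: dict[str, float] = {
    "AgCurA": 0.13,
    "AgCurB": 0.053,
    "AgCurC": 0.075,
    "AgCurC(P)": 0.094,
    "AgCurD": 0.085,
    "AgCurE": 0.085,
    "AgHEC6.4A": 0.13,
    "AgHEC6.4B": 0.17,
    "AgHEC6.4C": 0.13,
    "AgHEC6.4C(P)": 0.065,
    "AgHEC6.4D": 0.13,
    "AgHEC6.4E": 0.11,
    "AgHECC": 0.17,
    "AgHECC(P)": 0.10,
    "AgHECD": 0.19,
}

REPORTED_ABRASION_RELEASE_PCT: dict[str, float] = {
    "AgCurA": 2.1,
    "AgCurB": 0.9,
    "AgCurC": 1.2,
    "AgCurC(P)": 1.6,
    "AgCurD": 1.4,
    "AgCurE": 1.4,
    "AgHEC6.4A": 2.2,
    "AgHEC6.4B": 2.7,
    "AgHEC6.4C": 2.2,
    "AgHEC6.4C(P)": 1.1,
    "AgHEC6.4D": 2.2,
    "AgHEC6.4E": 1.8,
    "AgHECC": 2.7,
    "AgHECC(P)": 1.7,
    "AgHECD": 3.2,
}

# --- family-average scenario parameters --------------------------------------
#: family mean abrasion release constant (1/min), used in wear scenarios
FAMILY_MEAN_KP: dict[str, float] = {"AgCur": 0.086, "AgHEC6.4": 0.12, "AgHEC": 0.15}
#: family mean initial Ag areal load (ng/cm^2)
FAMILY_MEAN_LOAD: dict[str, float] = {"AgCur": 1530.0, "AgHEC6.4": 1658.0, "AgHEC": 1430.0}

# --- scenario geometry --------------------------------------------------------
FACE_MASK_AREA_CM2: float = 555.0
FULL_BODY_AREA_CM2: float = 20_000.0
HAND_AREA_CM2: float = 900.0  # both hands, adult male upper range
THREE_FINGERTIPS_AREA_CM2: float = 11.5  # adult, per hand

# --- subject / regulatory defaults -------------------------------------------
DEFAULT_BODY_WEIGHT_KG: float = 60.0
#: lowest systemic DNEL for the general population, mg/kg-bw/day
DEFAULT_DNEL_MG_PER_KG_DAY: float = 0.01

# --- sweat-immersion comparison garments (30-min immersion releases) ---------
#: garment -> (Ag content mg/kg, acidic-sweat release fraction,
#:             alkaline-sweat release fraction, reported mean k 1/min)
IMMERSION_GARMENTS: dict[str, tuple[float, float, float, float]] = {
    "t-shirt": (183.0, 0.068, 0.050, 0.0017),
    "trousers": (41.0, 0.132, 0.140, 0.0050),
}
IMMERSION_DURATION_MIN: float = 30.0
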
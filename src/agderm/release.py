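"""First-order release-rate estimation from release experiments.

When the source term is off and a single removal process ``x`` dominates, the
donor mass decays exponentially and the rate constant follows from one
(donor, receptor) mass pair::

    k_x = -(1/t) * ln(1 - m_x(t) / m(0))

Areal concentrations (ng/cm^2) may be used directly in place of masses because
the exposed area does not change during a release test.  Replicates are
aggregated by averaging the per-sample rate constants (not the fractions).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReleaseExperiment",
    "RateEstimate",
    "GroupStatistics",
    "estimate_rate_constant",
    "aggregate_group",
    "immersion_constants_from_fractions",
    "read_release_csv",
    "write_release_csv",
]

RELEASE_MEDIA = (
    "abrasion-sweat",
    "immersion-acid-sweat",
    "immersion-alkaline-sweat",
    "washing",
)


@dataclass(frozen=True)
class ReleaseExperiment:
    """One release measurement: donor load before, receptor mass after.

    ``duration_min`` is the contact time in minutes; ``donor_initial`` and
    ``receptor_mass`` share one unit (ng or ng/cm^2).
    """

    duration_min: float
    donor_initial: float
    receptor_mass: float
    medium: str = "abrasion-sweat"
    sample_label: str = ""

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError(f"duration must be > 0 min, got {self.duration_min}")
        if self.receptor_mass < 0:
            raise ValueError(f"receptor mass must be >= 0, got {self.receptor_mass}")
        if self.receptor_mass >= self.donor_initial:
            raise ValueError(
                "receptor mass must be smaller than the initial donor mass "
                f"(got {self.receptor_mass} >= {self.donor_initial}); the "
                "log-decay estimator is undefined at complete release"
            )


@dataclass(frozen=True)
class RateEstimate:
    """Estimated first-order rate constant for one sample."""

    k: float  # 1/min
    release_fraction: float
    sample_label: str = ""
    medium: str = ""


@dataclass(frozen=True)
class GroupStatistics:
    """Replicate-group summary: mean and sample (n-1) standard deviation.

    For a single replicate the standard deviation is reported as 0.0 by
    convention (no spread observable).
    """

    n: int
    k_mean: float
    k_sd: float
    fraction_mean: float
    fraction_sd: float


def estimate_rate_constant(experiment: ReleaseExperiment) -> RateEstimate:
    """Estimate the first-order rate constant of one release experiment.

    Returns the constant in 1/min together with the observed release fraction.
    """
    fraction = experiment.receptor_mass / experiment.donor_initial
    k = -math.log(1.0 - fraction) / experiment.duration_min
    return RateEstimate(
        k=k,
        release_fraction=fraction,
        sample_label=experiment.sample_label,
        medium=experiment.medium,
    )


def aggregate_group(estimates: Sequence[RateEstimate]) -> GroupStatistics:
    """Mean and sample standard deviation of k and release fraction."""
    if len(estimates) == 0:
        raise ValueError("cannot aggregate an empty group of estimates")
    ks = np.array([e.k for e in estimates])
    fr = np.array([e.release_fraction for e in estimates])
    if len(estimates) == 1:
        return GroupStatistics(1, float(ks[0]), 0.0, float(fr[0]), 0.0)
    return GroupStatistics(
        n=len(estimates),
        k_mean=float(ks.mean()),
        k_sd=float(ks.std(ddof=1)),
        fraction_mean=float(fr.mean()),
        fraction_sd=float(fr.std(ddof=1)),
    )


def immersion_constants_from_fractions(
    release_fractions: Iterable[float], duration_min: float
) -> float:
    """Mean rate constant (1/min) from a set of release fractions.

    Each fraction is treated as a unit-donor experiment and fed through the
    log-decay estimator; the per-fraction constants are then averaged.
    """
    ks = []
    for fraction in release_fractions:
        exp = ReleaseExperiment(
            duration_min=duration_min,
            donor_initial=1.0,
            receptor_mass=float(fraction),
            medium="immersion-acid-sweat",
        )
        ks.append(estimate_rate_constant(exp).k)
    if not ks:
        raise ValueError("at least one release fraction is required")
    return float(np.mean(ks))


# --- CSV dialect --------------------------------------------------------------
CSV_COLUMNS = ("sample", "medium", "duration_s", "load_ng_cm2", "release_ng_cm2")


def read_release_csv(path: str | Path) -> list[ReleaseExperiment]:
    """Read release experiments from CSV.

    Required header: ``sample,medium,duration_s,load_ng_cm2,release_ng_cm2``
    (UTF-8, '.' decimal separator).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected header {','.join(CSV_COLUMNS)}")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        experiments = []
        for i, row in enumerate(reader, start=2):
            try:
                experiments.append(
                    ReleaseExperiment(
                        duration_min=float(row["duration_s"]) / 60.0,
                        donor_initial=float(row["load_ng_cm2"]),
                        receptor_mass=float(row["release_ng_cm2"]),
                        medium=row["medium"],
                        sample_label=row["sample"],
                    )
                )
            except ValueError as err:
                raise ValueError(f"{path}: line {i}: {err}") from err
    if not experiments:
        raise ValueError(f"{path}: no data rows")
    return experiments


def write_release_csv(experiments: Iterable[ReleaseExperiment], path: str | Path) -> None:
    """Write release experiments in the same dialect :func:`read_release_csv` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for exp in experiments:
            writer.writerow(
                [
                    exp.sample_label,
                    exp.medium,
                    repr(exp.duration_min * 60.0),
                    repr(exp.donor_initial),
                    repr(exp.receptor_mass),
                ]
            )
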
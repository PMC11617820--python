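"""Single-compartment skin-surface mass balance with first-order source and losses.

The model tracks the mass of (nano)particles on the skin surface during wear of
a coated product.  The product donor releases first-order with rate constant
``k_p``; the skin-surface mass ``m(t)`` then feeds three absorbing receiving
compartments — stratum corneum (``k_sc``), inadvertent oral transfer (``k_o``)
and wear-and-wash removal (``k_ww``)::

    dm/dt = S_p(t) - (k_sc + k_o + k_ww) * m(t),      S_p(t) = k_p * m_textile(t)

All rate constants are net rates: back-transfer from a receiving compartment to
its donor is neglected.  The internal unit system is ng, cm^2, min.  The
stratum-corneum constant is measured (and stored) in its native 1/h and is
converted to 1/min exactly once, when a simulation is assembled.

The ODE is integrated with a fixed-step classical 4th-order Runge-Kutta scheme;
because the right-hand side sums to zero over the five compartments, every
Runge-Kutta step conserves total mass to round-off, which makes conservation
auditing trivial.  A closed-form solution is provided as an independent
cross-check for the wear phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - avoid a runtime cycle with scenarios
    from .scenarios import ExposureScenario

__all__ = [
    "RateConstants",
    "TextileProduct",
    "SkinPermeationParams",
    "MassTrajectory",
    "flux_to_rate_constant",
    "source_emission",
    "simulate",
    "cumulative_intake_closed_form",
]

#: exact conversion between the native 1/h of permeation measurements and the
#: internal 1/min time base; applied once at simulation assembly.
MINUTES_PER_HOUR = 60.0


@dataclass(frozen=True)
class RateConstants:
    """First-order rate constants of the mass balance.

    Parameters
    ----------
    k_p : float
        Release (textile -> skin surface) rate constant, 1/min.
    k_sc_per_h : float
        Stratum-corneum transfer rate constant in its native unit, 1/h.
    k_o : float
        Continuous oral-transfer rate constant, 1/min.  Discrete mouthing
        events are modelled separately (:class:`~agderm.scenarios.OralEvent`).
    k_ww : float
        Wear-and-wash removal rate constant, 1/min.
    """

    k_p: float
    k_sc_per_h: float
    k_o: float = 0.0
    k_ww: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_p", "k_sc_per_h", "k_o", "k_ww"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {value}")

    @property
    def k_sc_per_min(self) -> float:
        """Stratum-corneum rate on the internal 1/min time base."""
        return self.k_sc_per_h / MINUTES_PER_HOUR

    @property
    def total_loss_per_min(self) -> float:
        """Sum of all skin-surface loss rates, 1/min."""
        return self.k_sc_per_min + self.k_o + self.k_ww


@dataclass(frozen=True)
class TextileProduct:
    """A coated textile in contact with skin.

    The initial donor mass is ``areal_load * contact_area * available_fraction``
    (ng); the available fraction defaults to 1 (all particles reachable).
    """

    areal_load: float  # ng/cm^2
    contact_area: float  # cm^2
    available_fraction: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.areal_load < 0:
            raise ValueError(f"areal_load must be >= 0, got {self.areal_load}")
        if self.contact_area < 0:
            raise ValueError(f"contact_area must be >= 0, got {self.contact_area}")
        if not 0.0 <= self.available_fraction <= 1.0:
            raise ValueError(
                f"available_fraction must lie in [0, 1], got {self.available_fraction}"
            )

    @property
    def initial_mass(self) -> float:
        """Initial donor mass m_p,0 in ng."""
        return self.areal_load * self.contact_area * self.available_fraction


@dataclass(frozen=True)
class SkinPermeationParams:
    """A Franz-diffusion-cell permeation measurement.

    ``flux`` is the steady-state penetration flux (ng/cm^2/h), ``donor_load``
    the donor-solution surface load (ug/cm^2) and ``lag_time`` the delay (h)
    before steady-state flux is established.  Dividing flux by donor load
    yields a first-order transfer rate constant (1/h).
    """

    flux: float  # ng/cm^2/h
    donor_load: float  # ug/cm^2
    lag_time: float = 0.0  # h
    condition: str = ""

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ValueError(f"flux must be >= 0, got {self.flux}")
        if self.donor_load <= 0:
            raise ValueError(f"donor_load must be > 0, got {self.donor_load}")
        if self.lag_time < 0:
            raise ValueError(f"lag_time must be >= 0, got {self.lag_time}")

    @property
    def rate_constant_per_h(self) -> float:
        return flux_to_rate_constant(self)


def flux_to_rate_constant(permeation: SkinPermeationParams) -> float:
    """Convert a permeation flux measurement into a first-order rate constant.

    k_sc = J / L with the donor load converted from ug/cm^2 to ng/cm^2, so the
    result is in 1/h.  Pure function, no rounding.
    """
    if permeation.donor_load <= 0:
        raise ValueError("donor load must be positive to derive a rate constant")
    return permeation.flux / (permeation.donor_load * 1000.0)


def source_emission(t, k_p: float, m_p0: float):
    """Emission from a first-order donor at time ``t`` (minutes).

    Returns ``(rate, cumulative)`` where ``rate = k_p * m_p0 * exp(-k_p t)``
    (ng/min) and ``cumulative = m_p0 * (1 - exp(-k_p t))`` (ng); the rate
    integrates exactly to the cumulative.  ``t`` may be a scalar or array.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    if k_p < 0:
        raise ValueError("k_p must be >= 0")
    if m_p0 < 0:
        raise ValueError("m_p0 must be >= 0")
    decay = np.exp(-k_p * t_arr)
    rate = k_p * m_p0 * decay
    cumulative = m_p0 * (1.0 - decay)
    if np.isscalar(t):
        return float(rate), float(cumulative)
    return rate, cumulative


@dataclass
class MassTrajectory:
    """Time-resolved compartment masses of one simulated exposure.

    All masses are ng, the time grid is minutes starting at 0.  The sum over
    the five compartments equals the initial donor mass at every time point
    (relative tolerance 1e-6); cumulative receiving compartments are
    non-decreasing and the textile donor non-increasing.
    """

    time_min: np.ndarray
    m_textile: np.ndarray
    m_skin: np.ndarray
    m_sc: np.ndarray
    m_oral: np.ndarray
    m_ww: np.ndarray
    m_p0: float
    label: str = ""
    #: conservation tolerance used by :meth:`validate`
    rtol: float = field(default=1e-6, repr=False)

    @property
    def sc_intake(self) -> float:
        """Final cumulative stratum-corneum intake (ng)."""
        return float(self.m_sc[-1])

    @property
    def oral_intake(self) -> float:
        """Final cumulative oral intake (ng)."""
        return float(self.m_oral[-1])

    def total(self) -> np.ndarray:
        return self.m_textile + self.m_skin + self.m_sc + self.m_oral + self.m_ww

    def conservation_residual(self) -> float:
        """Largest relative mass-balance residual over the trajectory."""
        scale = self.m_p0 if self.m_p0 > 0 else 1.0
        return float(np.max(np.abs(self.total() - self.m_p0)) / scale)

    def validate(self) -> None:
        """Raise ``ValueError`` if any trajectory invariant is violated."""
        if self.time_min[0] != 0 or np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time grid must start at 0 and be strictly increasing")
        if self.conservation_residual() > self.rtol:
            raise ValueError(
                f"mass balance violated: residual {self.conservation_residual():.3e}"
            )
        slack = self.rtol * max(self.m_p0, 1.0)
        for name in ("m_textile", "m_skin", "m_sc", "m_oral", "m_ww"):
            if np.any(getattr(self, name) < -slack):
                raise ValueError(f"{name} has negative mass")
        for name in ("m_sc", "m_oral", "m_ww"):
            if np.any(np.diff(getattr(self, name)) < -slack):
                raise ValueError(f"cumulative compartment {name} decreases")
        if np.any(np.diff(self.m_textile) > slack):
            raise ValueError("donor compartment m_textile increases")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "m_textile_ng": self.m_textile,
                "m_skin_ng": self.m_skin,
                "m_sc_ng": self.m_sc,
                "m_oral_ng": self.m_oral,
                "m_ww_ng": self.m_ww,
            }
        )


def _rk4_segment(y0, k_p, lam, k_sc_m, k_o, k_ww, t0, t1, dt):
    """Integrate one piecewise-constant regime with fixed-step RK4.

    Returns (times, states) including both endpoints; the step is shrunk so it
    divides the segment exactly.
    """
    span = t1 - t0
    n = max(1, int(math.ceil(span / dt - 1e-12)))
    h = span / n

    def rhs(y):
        source = k_p * y[0]
        loss = lam * y[1]
        return np.array(
            [
                -source,
                source - loss,
                k_sc_m * y[1],
                k_o * y[1],
                k_ww * y[1],
            ]
        )

    times = np.empty(n + 1)
    states = np.empty((n + 1, 5))
    times[0] = t0
    states[0] = y0
    y = np.array(y0, dtype=float)
    for i in range(n):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        times[i + 1] = t0 + (i + 1) * h
        states[i + 1] = y
    return times, states


def simulate(scenario: "ExposureScenario", dt: float = 0.1) -> MassTrajectory:
    """Numerically integrate the mass balance for one exposure scenario.

    The source is active only during the scenario's wear intervals; outside
    wear the residual textile mass is frozen (the garment is off the skin) but
    the skin-surface deposit keeps feeding the loss compartments.  Discrete
    oral events and an optional washing time are applied as instantaneous
    transfers at their scheduled times, which are grid points by construction.

    Parameters
    ----------
    scenario : ExposureScenario
        Product, rate constants, wear schedule, oral events and subject.
    dt : float
        Integration step in minutes (default 0.1).  Must be positive and not
        larger than the shortest wear interval.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    horizon = scenario.horizon_min
    if horizon is None or horizon <= 0:
        raise ValueError("scenario horizon must be positive; nothing to simulate")
    intervals = list(scenario.wear_intervals)
    for start, end in intervals:
        if end - start < dt - 1e-12:
            raise ValueError(
                f"dt={dt} min is larger than the wear interval ({start}, {end}) min"
            )

    rates = scenario.rates
    k_sc_m = rates.k_sc_per_min  # single, exact 1/h -> 1/min conversion
    lam = k_sc_m + rates.k_o + rates.k_ww
    lag = scenario.sc_lag_min

    event_times = [ev.time_min for ev in scenario.oral_events]
    breaks = {0.0, float(horizon)}
    for start, end in intervals:
        breaks.update((float(start), float(end)))
    breaks.update(float(t) for t in event_times)
    if scenario.wash_at_min is not None:
        breaks.add(float(scenario.wash_at_min))
    if lag > 0:
        breaks.add(float(lag))
    breaks = sorted(b for b in breaks if 0.0 <= b <= horizon)

    def wearing(t_mid: float) -> bool:
        return any(start - 1e-9 <= t_mid <= end + 1e-9 for start, end in intervals)

    area = scenario.product.contact_area
    y = np.array([scenario.product.initial_mass, scenario.initial_skin_mass, 0.0, 0.0, 0.0])
    all_t = [np.array([0.0])]
    all_y = [y[None, :].copy()]

    def apply_point_transfers(t_now: float, y: np.ndarray) -> np.ndarray:
        for ev in scenario.oral_events:
            if abs(ev.time_min - t_now) < 1e-9:
                if area > 0:
                    load = y[1] / area  # ng/cm^2 on the exposed skin
                    moved = load * ev.contact_area * ev.transfer_efficiency
                    moved *= ev.retention * ev.n_events
                    moved = min(moved, y[1])
                else:
                    moved = 0.0
                y[1] -= moved
                y[3] += moved
        if scenario.wash_at_min is not None and abs(scenario.wash_at_min - t_now) < 1e-9:
            y[4] += y[1]
            y[1] = 0.0
        return y

    y = apply_point_transfers(0.0, y)
    all_y[0][0] = y
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        k_p_seg = rates.k_p if wearing(mid) else 0.0
        k_sc_seg = k_sc_m if mid >= lag else 0.0
        lam_seg = k_sc_seg + rates.k_o + rates.k_ww
        t_seg, y_seg = _rk4_segment(y, k_p_seg, lam_seg, k_sc_seg, rates.k_o, rates.k_ww, a, b, dt)
        y = y_seg[-1].copy()
        y = apply_point_transfers(b, y)
        y_seg[-1] = y
        all_t.append(t_seg[1:])
        all_y.append(y_seg[1:])

    time = np.concatenate(all_t)
    states = np.vstack(all_y)
    traj = MassTrajectory(
        time_min=time,
        m_textile=states[:, 0],
        m_skin=states[:, 1],
        m_sc=states[:, 2],
        m_oral=states[:, 3],
        m_ww=states[:, 4],
        m_p0=scenario.product.initial_mass + scenario.initial_skin_mass,
        label=scenario.label,
    )
    return traj


def cumulative_intake_closed_form(
    T: float,
    m_p0: float,
    k_p: float,
    k_sc: float,
    method: str = "auto",
) -> float:
    """Closed-form cumulative stratum-corneum intake after ``T`` hours of wear.

    For a first-order donor feeding the skin surface whose only loss is the
    stratum corneum, the intake admits a first-order-in-``k_sc`` solution

        m_sc(T) = k_sc * m_p0 * [T - (1 - exp(-k_p' T)) / k_p'],   k_p' = 60 k_p

    which is accurate when ``k_sc * T << 1`` (the regime of all textile
    scenarios here: k_sc*T ~ 1e-5..1e-3).  Outside that regime the exact
    two-exponential solution of the linear system is used.

    Parameters
    ----------
    T : float
        Wear duration in hours.
    m_p0 : float
        Initial donor mass, ng.
    k_p : float
        Release rate constant, 1/min.
    k_sc : float
        Stratum-corneum rate constant, 1/h.
    method : {"auto", "first_order", "exact"}
        "auto" selects first-order when ``k_sc * T < 0.01``.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    if k_p < 0 or k_sc < 0:
        raise ValueError("rate constants must be >= 0")
    if T == 0 or m_p0 == 0 or k_sc == 0:
        return 0.0
    kp_h = MINUTES_PER_HOUR * k_p
    if method == "auto":
        method = "first_order" if k_sc * T < 0.01 else "exact"
    if method == "first_order":
        if kp_h == 0:
            return 0.0
        return k_sc * m_p0 * (T - (1.0 - math.exp(-kp_h * T)) / kp_h)
    if method == "exact":
        lam = k_sc  # only loss channel, 1/h
        if kp_h == 0:
            return 0.0
        if abs(kp_h - lam) < 1e-12 * max(kp_h, lam):
            # confluent case: m_skin = kp_h * m0 * t * exp(-kp_h t)
            return m_p0 * (1.0 - math.exp(-kp_h * T) * (1.0 + kp_h * T))
        return (
            m_p0
            * kp_h
            / (kp_h - lam)
            * ((1.0 - math.exp(-lam * T)) - lam / kp_h * (1.0 - math.exp(-kp_h * T)))
        )
    raise ValueError(f"unknown method {method!r}")
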
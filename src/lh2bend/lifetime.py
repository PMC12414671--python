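"""From oscillator strength to excited-state lifetime and EET efficiency.

The measured decay rate of B850 contains radiative and nonradiative
contributions, 1/tau = kr + knr.  For structurally symmetric, weakly
electron-phonon-coupled emitters the two are linearly related,
knr ~ (knr0/kr0) kr + [A(T) - B(T)] knr0, so the total rate remains
proportional to the oscillator strength of the emitting state:
f ~ kr + knr = 1/tau.  The proportionality is anchored at a reference
state (free LH2, tau = 1.3 ns at room temperature).

Combining the deflection laws with fz ~ delta_z^2 gives the size-scaling
forms used for fitting:

* region 1 (cocurvature, large d):  1/tau = baseline + amplitude / d^2
* region 3 (plate deflection, small d):
  1/tau = baseline + amplitude * rho(d)^2 / (1 + 4 r0^2 / d^2)^3,
  with rho(d) = charge_coefficient / d.

EET efficiency from B850 to the reaction center is
eta = ktrap / (ktrap + kdecay) = tau / (tau + tau_trap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: room-temperature lifetime of free B850, ns
DEFAULT_REFERENCE_TAU_NS = 1.3

#: typical trapping time of the reaction center, ns
DEFAULT_TRAP_TAU_NS = 0.1


@dataclass(frozen=True)
class LifetimeCalibration:
    """Anchored map from oscillator strength to total decay rate.

    ``proportionality`` converts the radiative part (ns^-1 per oscillator
    strength unit); ``slope_ratio`` (knr0/kr0) and ``offset`` (ns^-1)
    encode the linear radiative/nonradiative relation.  With the default
    slope_ratio = offset = 0 the map is a pure proportionality, anchored
    so that ``reference_f`` maps to ``1 / reference_tau``.
    """

    proportionality: float
    reference_tau: float = DEFAULT_REFERENCE_TAU_NS
    reference_f: float | None = None
    slope_ratio: float = 0.0
    offset: float = 0.0
    quantum_yield: float | None = None

    def __post_init__(self) -> None:
        if not self.proportionality > 0:
            raise ValueError("proportionality must be positive")
        if not self.reference_tau > 0:
            raise ValueError("reference_tau must be positive")

    @classmethod
    def from_reference(
        cls,
        reference_f: float,
        reference_tau: float = DEFAULT_REFERENCE_TAU_NS,
        slope_ratio: float = 0.0,
        offset: float = 0.0,
    ) -> "LifetimeCalibration":
        """Anchor the map so reference_f -> 1/reference_tau."""
        if not reference_f > 0:
            raise ValueError("reference_f must be positive")
        rate = 1.0 / reference_tau - offset
        if not rate > 0:
            raise ValueError("offset exceeds the reference decay rate")
        prop = rate / (reference_f * (1.0 + slope_ratio))
        return cls(
            proportionality=prop,
            reference_tau=reference_tau,
            reference_f=reference_f,
            slope_ratio=slope_ratio,
            offset=offset,
        )


def rate_from_oscillator_strength(f, calibration: LifetimeCalibration):
    """Total decay rate 1/tau (ns^-1) for oscillator strength f."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("oscillator strength must be >= 0")
    rate = (
        calibration.proportionality * (1.0 + calibration.slope_ratio) * f
        + calibration.offset
    )
    return rate if rate.ndim else float(rate)


@dataclass(frozen=True)
class EfficiencyParams:
    """B850 lifetime and reaction-center trapping time (both ns)."""

    tau: float
    tau_trap: float = DEFAULT_TRAP_TAU_NS

    def __post_init__(self) -> None:
        if not self.tau > 0 or not self.tau_trap > 0:
            raise ValueError("tau and tau_trap must be positive")


def eet_efficiency(params: EfficiencyParams) -> float:
    """Excitation-energy-transfer efficiency eta = ktrap/(ktrap + kdecay).

    Algebraically identical to tau / (tau + tau_trap); lies in (0, 1),
    increasing in tau and decreasing in tau_trap.
    """
    return params.tau / (params.tau + params.tau_trap)


def region1_rate(d, amplitude: float, baseline: float):
    """Cocurvature decay-rate law, 1/tau = baseline + amplitude / d^2."""
    d = np.asarray(d, dtype=float)
    rate = baseline + amplitude / d**2
    return rate if rate.ndim else float(rate)


def region3_geometry_factor(d, r0: float):
    """Shape factor d -> 1 / (1 + 4 r0^2 / d^2)^3 of the small-size law."""
    d = np.asarray(d, dtype=float)
    g = (1.0 + 4.0 * r0**2 / d**2) ** -3.0
    return g if g.ndim else float(g)


def region3_rate(
    d,
    amplitude: float,
    baseline: float,
    r0: float = 3.8,
    charge_coefficient: float = 1.0,
):
    """Plate-deflection decay-rate law for small particles.

    1/tau = baseline + amplitude * rho^2 / (1 + 4 r0^2 / d^2)^3 with
    rho = charge_coefficient / d.  Only the product
    ``amplitude * charge_coefficient^2`` is identifiable from rate data.
    """
    d = np.asarray(d, dtype=float)
    rho = charge_coefficient / d
    rate = baseline + amplitude * rho**2 * region3_geometry_factor(d, r0)
    return rate if rate.ndim else float(rate)
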
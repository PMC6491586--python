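"""Derived bunch quantities: central-axis depth dose, time-of-flight
stretching, bunch current and acoustic signal-duration bounds."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bragg import BraggCurve
from .forward import BeamParams, MediumGeometry
from .stopping import StoppingModel, csda_range

__all__ = [
    "DepthDose",
    "depth_dose",
    "tof_spread",
    "mean_current",
    "signal_duration",
    "PROTON_REST_MEV",
]

PROTON_REST_MEV = 938.272  # proton rest energy, MeV
C_LIGHT = 299_792_458.0  # m/s
E_CHARGE = 1.602176634e-19  # C


@dataclass(frozen=True)
class DepthDose:
    """Central-axis dose profile: dose (Gy) on the depth grid z_grid (m)."""

    z_grid: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.dose) < 0):
            raise ValueError("dose must be non-negative")


def depth_dose(bs: BraggCurve, beam: BeamParams, rho: float = 1000.0) -> DepthDose:
    """Central-axis depth dose D(z) = n_i * B_s(z) / (rho * 2 pi sigma_r^2).

    For a transversely Gaussian bunch the on-axis energy density per unit
    depth is the depth deposition divided by the effective beam area
    2 pi sigma_r^2; dividing by the mass density gives dose in Gy.
    """
    factor = beam.n_i / (rho * 2.0 * np.pi * beam.sigma_r**2)
    return DepthDose(bs.z_grid, factor * bs.deposition)


def _beta(energy_mev: float) -> float:
    """Relativistic v/c of a proton with the given kinetic energy."""
    gamma = 1.0 + energy_mev / PROTON_REST_MEV
    return float(np.sqrt(1.0 - gamma**-2))


def tof_spread(e_lo: float, e_hi: float, distance: float) -> float:
    """Bunch stretching (s) over a drift: time-of-flight difference between
    the slowest (e_lo) and fastest (e_hi) protons, relativistic kinematics."""
    if not 0 < e_lo < e_hi:
        raise ValueError("need 0 < e_lo < e_hi")
    return distance / (_beta(e_lo) * C_LIGHT) - distance / (_beta(e_hi) * C_LIGHT)


def mean_current(n_i: float, duration: float) -> float:
    """Mean bunch current (A) of n_i protons passing within ``duration`` s."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return n_i * E_CHARGE / duration


def signal_duration(
    energy_mev: float,
    geom: MediumGeometry,
    model: StoppingModel = StoppingModel(),
) -> float:
    """Upper bound on the acoustic signal duration: 2 * range / c.

    The last (reflected) wave component travels at most one extra ion range
    before reaching the detector, so direct and reflected pulses span
    2 R(E) / c regardless of detector distance.
    """
    if energy_mev <= 0:
        raise ValueError("energy must be positive")
    return 2.0 * csda_range(energy_mev, model) / geom.c
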
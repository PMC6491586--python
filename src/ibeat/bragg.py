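"""Single-ion Bragg curves and spectrum-weighted (spread-out) Bragg curves.

The depth-deposition profile of a single ion is built analytically from the
power-law range model: the residual energy at depth z is
E(z) = ((R - z)/alpha)**(1/p), so the energy deposited inside a grid cell is
the difference of residual energies at the cell faces.  This integrates the
(R - z)**(1/p - 1) stopping-power singularity exactly and conserves energy by
construction.  The pristine profile is then Gaussian-convolved with the
range-straggling width and renormalized so the depth integral equals the
ion's kinetic energy in joules.

Depth coordinate convention: z = 0 at the inner face of the entrance window,
beam along +z, uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .stopping import MEV_TO_J, StoppingModel, csda_range, energy_from_range

__all__ = [
    "EnergySpectrum",
    "BraggCurve",
    "GridCoverageError",
    "bragg_curve",
    "bragg_curve_bank",
    "spread_bragg",
]


class GridCoverageError(ValueError):
    """Depth grid does not cover the ion range; a truncated curve would
    silently violate energy conservation."""


@dataclass(frozen=True)
class EnergySpectrum:
    """Discretized kinetic-energy distribution f(E_kin) of an ion bunch.

    Parameters
    ----------
    bin_edges : array, shape (n_bins + 1,)
        Ascending kinetic-energy bin boundaries in MeV.
    f : array, shape (n_bins,)
        Non-negative per-bin probability density in 1/MeV, normalized so that
        sum(f * diff(bin_edges)) == 1.
    n_i : float
        Total number of ions in the bunch carried by this spectrum.
    """

    bin_edges: np.ndarray
    f: np.ndarray
    n_i: float = 1.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "f", f)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be 1-D and strictly ascending")
        if f.shape != (edges.size - 1,):
            raise ValueError("f must have one entry per energy bin")
        if np.any(f < 0):
            raise ValueError("spectral density f must be non-negative")
        if self.n_i < 0:
            raise ValueError("ion count n_i must be non-negative")
        norm = float(np.sum(f * np.diff(edges)))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"spectrum not normalized: sum(f*dE) = {norm!r}")

    @classmethod
    def from_masses(cls, bin_edges, masses, n_i: float = 1.0) -> "EnergySpectrum":
        """Build a normalized spectrum from non-negative per-bin weights.

        The weights need not sum to one; their total is folded into the ion
        count so that ``n_i_out = n_i * sum(masses)`` carries the fluence.
        """
        edges = np.asarray(bin_edges, dtype=float)
        m = np.clip(np.asarray(masses, dtype=float), 0.0, None)
        total = float(m.sum())
        if total <= 0.0:
            raise ValueError("spectrum has empty support (all weights zero)")
        return cls(edges, m / total / np.diff(edges), n_i * total)

    @property
    def centers(self) -> np.ndarray:
        """Bin-center energies in MeV."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def masses(self) -> np.ndarray:
        """Per-bin probability mass f * dE (sums to 1)."""
        return self.f * self.widths

    @property
    def mean_energy(self) -> float:
        """Spectral mean kinetic energy in MeV."""
        return float(np.sum(self.masses * self.centers))

    @property
    def e_max(self) -> float:
        """Highest bin-center energy with non-zero weight (MeV)."""
        nz = np.nonzero(self.masses)[0]
        if nz.size == 0:
            return 0.0
        return float(self.centers[nz[-1]])


@dataclass(frozen=True)
class BraggCurve:
    """Depth profile of linear energy deposition of one ion (or one mean ion).

    ``deposition`` is in J/m per ion on the uniform grid ``z_grid`` (m).
    """

    z_grid: np.ndarray
    deposition: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_grid, dtype=float)
        d = np.asarray(self.deposition, dtype=float)
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "deposition", d)
        if z.shape != d.shape or z.ndim != 1:
            raise ValueError("z_grid and deposition must be matching 1-D arrays")
        dz = np.diff(z)
        if z.size < 2 or not np.allclose(dz, dz[0], rtol=1e-6):
            raise ValueError("z_grid must be uniform with at least two samples")
        if np.any(d < -1e-30):
            raise ValueError("deposition must be non-negative")

    @property
    def dz(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0])

    @property
    def total_energy_j(self) -> float:
        """Depth integral of the deposition (J per ion)."""
        return float(np.sum(self.deposition) * self.dz)

    @property
    def peak_depth(self) -> float:
        """Depth of the deposition maximum (m)."""
        return float(self.z_grid[int(np.argmax(self.deposition))])


def _check_grid(z_grid: np.ndarray) -> float:
    z = np.asarray(z_grid, dtype=float)
    dz = np.diff(z)
    if z.size < 2 or not np.allclose(dz, dz[0], rtol=1e-6):
        raise ValueError("z_grid must be uniform with at least two samples")
    return float(dz[0])


def bragg_curve(
    energy_mev: float, z_grid, model: StoppingModel = StoppingModel()
) -> BraggCurve:
    """Single-ion Bragg curve B(E_kin, z) on ``z_grid``.

    The curve peaks near ``csda_range(energy_mev)`` (straggling pulls the
    maximum slightly upstream) and is renormalized so that the depth integral
    equals the kinetic energy in joules (within floating-point error).

    Raises
    ------
    GridCoverageError
        If the grid does not extend to 1.2x the CSDA range.
    """
    if energy_mev <= 0:
        raise ValueError("energy must be positive")
    z = np.asarray(z_grid, dtype=float)
    dz = _check_grid(z)
    r = csda_range(energy_mev, model)
    if z[0] > 0.25 * r or z[-1] < 1.2 * r:
        raise GridCoverageError(
            f"grid [{z[0]:.4g}, {z[-1]:.4g}] m does not cover "
            f"[0, {1.2 * r:.4g}] m needed for E = {energy_mev} MeV"
        )
    # residual energy at the cell faces; residual range clipped to [0, R]
    faces = np.concatenate([z - 0.5 * dz, [z[-1] + 0.5 * dz]])
    resid = np.clip(r - faces, 0.0, r)
    e_face = energy_from_range(resid, model)
    dep = (e_face[:-1] - e_face[1:]) / dz  # MeV/m, exact cell-average

    sigma = model.straggling_sigma(energy_mev)
    if sigma > 0:
        dep = gaussian_filter1d(dep, sigma / dz, mode="constant", cval=0.0)
    dep = np.clip(dep, 0.0, None)
    total = dep.sum() * dz
    dep *= energy_mev * MEV_TO_J / total  # renormalize to E in J
    return BraggCurve(z, dep)


def bragg_curve_bank(
    energies_mev, z_grid, model: StoppingModel = StoppingModel()
) -> np.ndarray:
    """Stack of single-ion Bragg curves, shape (n_energies, n_z), J/m per ion.

    Convenience for linear forward operators (the pressure trace is linear in
    the deposition, so per-bin curves can be precomputed once).
    """
    return np.stack(
        [bragg_curve(e, z_grid, model).deposition for e in np.atleast_1d(energies_mev)]
    )


def spread_bragg(
    spectrum: EnergySpectrum, z_grid, model: StoppingModel = StoppingModel()
) -> BraggCurve:
    """Spread-out Bragg curve B_s(z) of a bunch, per ion.

    B_s(z) = sum_b f_b * dE_b * B(E_b, z) over spectrum bins; linear in the
    spectral weights.  The depth integral equals the spectral mean energy in
    joules.  Bins with zero weight are skipped, so empty high-energy bins do
    not trigger grid-coverage errors.
    """
    z = np.asarray(z_grid, dtype=float)
    _check_grid(z)
    dep = np.zeros_like(z)
    for mass, e_center in zip(spectrum.masses, spectrum.centers):
        if mass <= 0.0:
            continue
        dep += mass * bragg_curve(e_center, z, model).deposition
    return BraggCurve(z, dep)
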
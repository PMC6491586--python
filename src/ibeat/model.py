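"""Model/Results front end for the ionoacoustic reconstruction.

`IonoacousticModel` bundles one observed trace with the detector kernel,
geometry, stopping model and annealing settings; `fit()` runs the simulated
annealing inverse and returns a `ReconstructionResult` carrying the
retrieved spectrum, sigma_r, residual diagnostics, the depth dose and a
printable `summary()`.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .anneal import AnnealConfig, ReconResult, anneal, fit_report
from .bragg import EnergySpectrum, spread_bragg
from .detector import TransferFunction, read_transfer
from .dose import DepthDose, depth_dose
from .forward import BeamParams, MediumGeometry
from .stopping import StoppingModel, csda_range
from .trace import AcousticTrace, read_trace

__all__ = ["IonoacousticModel", "ReconstructionResult"]


class IonoacousticModel:
    """Inverse model of one recorded ionoacoustic trace.

    Parameters
    ----------
    observed : AcousticTrace
        Recorded voltage trace (already restricted to the time window to be
        fitted, typically the direct pulse).
    transfer : TransferFunction
        Detector kernel mapping pressure to voltage.
    geometry : MediumGeometry
        Medium and detector geometry.
    config : AnnealConfig
        Energy bins, sigma_r grid and annealing settings.
    stopping : StoppingModel, optional
        Range-energy parameterization of the medium.
    """

    def __init__(
        self,
        observed: AcousticTrace,
        transfer: TransferFunction,
        geometry: MediumGeometry,
        config: AnnealConfig,
        stopping: StoppingModel = StoppingModel(),
    ) -> None:
        self.observed = observed
        self.transfer = transfer
        self.geometry = geometry
        self.config = config
        self.stopping = stopping

    @classmethod
    def from_files(
        cls,
        trace_path,
        transfer_path,
        geometry: MediumGeometry,
        config: AnnealConfig,
        stopping: StoppingModel = StoppingModel(),
    ) -> "IonoacousticModel":
        """Build the model from trace / kernel text files."""
        return cls(read_trace(trace_path), read_transfer(transfer_path), geometry, config, stopping)

    def fit(self, seed: int | None = None) -> "ReconstructionResult":
        """Run the annealing reconstruction (optionally overriding the seed)."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        res = anneal(self.observed, self.transfer, self.geometry, cfg, self.stopping)
        return ReconstructionResult(self, res)


class ReconstructionResult:
    """Fitted spectrum, bunch width and diagnostics of one reconstruction."""

    def __init__(self, model: IonoacousticModel, raw: ReconResult) -> None:
        self.model = model
        self.raw = raw

    # -- parameter accessors -------------------------------------------------
    @property
    def spectrum(self) -> EnergySpectrum:
        return self.raw.spectrum

    @property
    def n_i(self) -> float:
        return self.raw.spectrum.n_i

    @property
    def sigma_r(self) -> float:
        return self.raw.sigma_r

    @property
    def residual(self) -> float:
        return self.raw.residual

    @property
    def relative_misfit(self) -> float:
        norm = float(np.linalg.norm(self.model.observed.samples))
        return float(np.sqrt(self.raw.residual)) / norm if norm > 0 else 0.0

    def report(self) -> dict:
        """JSON-serializable fit report (see :func:`ibeat.anneal.fit_report`)."""
        return fit_report(self.raw, self.model.observed)

    def depth_dose(self, rho: float | None = None) -> DepthDose:
        """Central-axis depth dose implied by the retrieved spectrum."""
        stopping = self.model.stopping
        spec = self.raw.spectrum
        z_step = self.model.config.z_step
        z_grid = np.arange(
            0.0, 1.25 * csda_range(float(spec.bin_edges[-1]), stopping) + z_step, z_step
        )
        bs = spread_bragg(spec, z_grid, stopping)
        beam = BeamParams(n_i=spec.n_i, sigma_r=self.raw.sigma_r)
        return depth_dose(bs, beam, rho if rho is not None else self.model.geometry.rho)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        spec = self.raw.spectrum
        mean_e = spec.mean_energy
        sd_e = float(np.sqrt(np.sum(spec.masses * (spec.centers - mean_e) ** 2)))
        rows = [
            ("ions in bunch (n_i)", f"{spec.n_i:.4g}"),
            ("transverse width sigma_r", f"{self.raw.sigma_r * 1e3:.2f} mm"),
            ("spectral mean energy", f"{mean_e:.3f} MeV"),
            ("spectral std energy", f"{sd_e:.3f} MeV"),
            ("residual Sigma", f"{self.raw.residual:.6g} V^2"),
            ("relative L2 misfit", f"{self.relative_misfit:.4f}"),
            ("accepted moves", f"{self.raw.accepted_count}/{self.raw.history.size}"),
            ("sigma_r grid points", f"{self.raw.sigma_grid.size}"),
            ("energy bins", f"{spec.f.size}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Ionoacoustic reconstruction", "=" * 43]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Overlay the observed trace and the reconstructed model trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = self.model.observed
        ax.plot(obs.times * 1e6, obs.samples, label="observed", lw=0.8)
        ax.plot(
            self.raw.model_trace.times * 1e6,
            self.raw.model_trace.samples,
            label="reconstructed",
            lw=1.2,
        )
        ax.set_xlabel("time (us)")
        ax.set_ylabel("signal (V)")
        ax.legend()
        return ax

    def plot_spectrum(self, ax=None):
        """Retrieved absolute energy distribution n_i * f(E)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        spec = self.raw.spectrum
        ax.stairs(spec.n_i * spec.f, spec.bin_edges)
        ax.set_xlabel("kinetic energy (MeV)")
        ax.set_ylabel("dN/dE (1/MeV)")
        return ax
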
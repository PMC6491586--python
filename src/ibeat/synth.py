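"""Seeded generators for synthetic study inputs.

Everything a reconstruction test needs can be generated from a seed and a
small parameter record: energy spectra (mono-energetic calibration bunches,
quasi-monoenergetic Gaussian bunches as delivered by chromatic focusing
optics, and broad TNSA exponentials with a cutoff), band-limited transducer
impulse responses, and noisy observed traces with their ground truth
attached.  Noise is additive white Gaussian scaled to a stated SNR over the
direct-pulse window; structured electromagnetic-pulse artifacts are not
emulated (the acoustic signal's microsecond delay removes them in practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .bragg import EnergySpectrum, spread_bragg
from .detector import TransferFunction, apply_transfer
from .forward import BeamParams, MediumGeometry, direct_window, pressure_trace
from .stopping import StoppingModel, csda_range
from .trace import AcousticTrace

__all__ = ["TruthRecord", "make_spectrum", "make_transducer_ir", "make_noisy_trace"]

#: default synthetic transducer: 10 MHz centre, 60% fractional bandwidth
DEFAULT_TF_META = {"f_c": 10e6, "fractional_bandwidth": 0.6}


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one synthetic observed trace.

    Together with the geometry and stopping model this fully determines the
    generated trace; regeneration from (seed, config) is exact.
    """

    spectrum: EnergySpectrum
    sigma_r: float
    tf_meta: dict = field(default_factory=lambda: dict(DEFAULT_TF_META))
    noise_snr_db: float = np.inf
    seed: int = 0
    segments: tuple = ("direct",)


def make_spectrum(kind: str, params: dict, bin_edges, n_i: float = 1.0) -> EnergySpectrum:
    """Discretized test spectrum of the requested family.

    kind = "mono": all mass in the bin containing params["energy"] (MeV).
    kind = "gaussian": normal with params["mean"], params["sd"] (MeV),
    integrated exactly over each bin.
    kind = "tnsa": f proportional to exp(-E / T_eff) truncated at E_cut, with
    params["t_eff"] and params["e_cut"] (MeV) — the broad exponential
    spectrum characteristic of target-normal sheath acceleration.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if kind == "mono":
        e = float(params["energy"])
        masses = np.zeros(edges.size - 1)
        idx = int(np.searchsorted(edges, e, side="right")) - 1
        if idx < 0 or idx >= masses.size:
            raise ValueError(f"energy {e} MeV outside the bin range")
        masses[idx] = 1.0
    elif kind == "gaussian":
        mean, sd = float(params["mean"]), float(params["sd"])
        masses = np.diff(norm.cdf(edges, loc=mean, scale=sd))
    elif kind == "tnsa":
        t_eff, e_cut = float(params["t_eff"]), float(params["e_cut"])
        centers = 0.5 * (edges[:-1] + edges[1:])
        masses = np.exp(-centers / t_eff) * np.diff(edges)
        masses[centers > e_cut] = 0.0
    else:
        raise ValueError(f"unknown spectrum kind {kind!r}")
    if masses.sum() <= 0:
        raise ValueError("requested spectrum has empty support on these bins")
    return EnergySpectrum.from_masses(edges, masses, n_i)


def make_transducer_ir(
    f_c: float,
    fractional_bandwidth: float,
    dt: float,
    seed: int | None = None,
    peak_v_per_pa: float = 1e-3,
) -> TransferFunction:
    """Synthetic band-limited transducer kernel.

    A Gaussian-enveloped sinusoid at centre frequency ``f_c`` whose -6 dB
    fractional bandwidth (full width / f_c of the spectral magnitude) equals
    the request; the kernel is scaled to a peak spectral magnitude of
    ``peak_v_per_pa``.  ``seed`` is accepted for generator-API symmetry; the
    kernel is deterministic.

    Raises if f_c violates the Nyquist limit of ``dt`` or the bandwidth is
    non-positive (a zero-bandwidth pure tone has no finite-support kernel).
    """
    if not f_c * dt < 0.5:
        raise ValueError(f"f_c = {f_c} Hz violates Nyquist for dt = {dt} s")
    if fractional_bandwidth <= 0:
        raise ValueError("fractional bandwidth must be positive")
    # Gaussian envelope: |H(f)| ~ exp(-(f - f_c)^2 / (2 sigma_f^2));
    # -6 dB (half) magnitude at f_c +/- sigma_f * sqrt(2 ln 2)
    sigma_f = fractional_bandwidth * f_c / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(4.0 * sigma_t / dt))
    lags = dt * np.arange(-half, half + 1)
    h = np.exp(-0.5 * (lags / sigma_t) ** 2) * np.cos(2.0 * np.pi * f_c * lags)
    n_fft = max(4096, 4 * h.size)
    h *= peak_v_per_pa / np.abs(np.fft.rfft(h, n_fft)).max()
    return TransferFunction(
        h, dt, lag0=-half, meta={"f_c": f_c, "fractional_bandwidth": fractional_bandwidth}
    )


def make_noisy_trace(
    truth: TruthRecord,
    geom: MediumGeometry,
    model: StoppingModel,
    t0: float,
    dt: float,
    n_samples: int,
    z_step: float = 10e-6,
    oversample: int = 20,
) -> tuple[AcousticTrace, TruthRecord]:
    """Synthetic observed trace: full forward chain plus white noise.

    Runs spread_bragg -> pressure_trace -> apply_transfer for the truth
    record, then adds white Gaussian noise whose power is set so that the
    SNR over the direct-pulse window equals ``truth.noise_snr_db``.
    Deterministic given ``truth.seed``.
    """
    spec = truth.spectrum
    e_max = float(spec.bin_edges[-1])
    z_grid = np.arange(0.0, 1.25 * csda_range(e_max, model) + z_step, z_step)
    bs = spread_bragg(spec, z_grid, model)
    beam = BeamParams(n_i=spec.n_i, sigma_r=truth.sigma_r)
    ideal = pressure_trace(bs, beam, geom, t0, dt, n_samples, truth.segments, oversample)
    tf = make_transducer_ir(
        truth.tf_meta["f_c"], truth.tf_meta["fractional_bandwidth"], dt
    )
    clean = apply_transfer(ideal, tf)
    if not np.isfinite(truth.noise_snr_db):
        return clean, truth
    t_lo, t_hi = direct_window(geom, csda_range(spec.e_max, model), truth.sigma_r)
    seg = clean.window(max(t_lo, clean.t0), min(t_hi, clean.times[-1]))
    rms = float(np.sqrt(np.mean(seg.samples**2)))
    noise_std = rms / 10.0 ** (truth.noise_snr_db / 20.0)
    rng = np.random.default_rng(truth.seed)
    noisy = clean.samples + rng.normal(0.0, noise_std, clean.samples.size)
    return AcousticTrace(clean.t0, clean.dt, noisy, "V"), truth
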
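"""Canonical synthetic benchmark studies.

These functions define, in one place, the package's desk-scale reproducible
studies: the relativistic time-of-flight numbers, the forward-model vs
brute-force-oracle equivalence, the three-segment timing structure of a
mono-energetic trace, and the end-to-end parameter-recovery study (generate
a noisy synthetic bunch, reconstruct it, compare against ground truth).
Both the test suite and the reproduction script run them, so the numbers
they report are always recomputed from scratch.

Geometry note: the detector distance is an experiment-specific quantity; the
studies use z_d = 55 mm, consistent with a ~36.5 us direct-pulse arrival for
a ~7 MeV bunch in water.
"""

from __future__ import annotations

import numpy as np

from .anneal import AnnealConfig, anneal
from .bragg import bragg_curve
from .dose import mean_current, signal_duration, tof_spread
from .forward import (
    BeamParams,
    MediumGeometry,
    direct_window,
    oracle_pressure_trace,
    pressure_trace,
)
from .stopping import StoppingModel, csda_range
from .synth import TruthRecord, make_noisy_trace, make_spectrum, make_transducer_ir

__all__ = [
    "STUDY_GEOMETRY",
    "ORACLE_CONFIGS",
    "tof_study",
    "oracle_equivalence",
    "timing_study",
    "recovery_study",
]

#: geometry of the synthetic studies (water at ~20 degC, far detector)
STUDY_GEOMETRY = MediumGeometry(z_d=0.055)

#: (energy MeV, sigma_r m, z_d m) combinations for the oracle cross-check
ORACLE_CONFIGS = (
    (7.0, 1.5e-3, 0.055),
    (7.0, 1.5e-3, 0.030),
    (6.2, 2.0e-3, 0.055),
    (5.0, 1.0e-3, 0.025),
)

#: sampling interval of the synthetic digitizer (s); 100 MS/s comfortably
#: oversamples a 10 MHz transducer
STUDY_DT = 1e-8


def tof_study() -> dict:
    """Drift-stretching, bunch-current and signal-duration numbers.

    A bunch spanning 4-8 MeV stretches over a 1.5 m drift; 1e8 protons in
    that stretched bunch carry about a milliamp; and the acoustic signal of
    100 MeV protons lasts at most 2R/c.
    """
    spread = tof_spread(4.0, 8.0, 1.5)
    return {
        "tof_4_8_mev_1p5m_ns": spread * 1e9,
        "bunch_current_ma": mean_current(1e8, spread) * 1e3,
        "signal_duration_100mev_us": signal_duration(100.0, STUDY_GEOMETRY) * 1e6,
    }


def oracle_equivalence(
    energy_mev: float,
    sigma_r: float,
    z_d: float,
    model: StoppingModel = StoppingModel(),
    dz: float = 2e-6,
    dt: float = STUDY_DT,
) -> float:
    """Relative L2 distance between the axial quadrature and the brute-force
    retarded-wave oracle over the direct segment of a mono-energetic bunch."""
    geom = MediumGeometry(z_d=z_d)
    r = csda_range(energy_mev, model)
    z_grid = np.arange(0.0, 1.3 * r, dz)
    bs = bragg_curve(energy_mev, z_grid, model)
    beam = BeamParams(n_i=1e8, sigma_r=sigma_r)
    t_lo, t_hi = direct_window(geom, r, sigma_r, pad=1e-6)
    n = int((t_hi - t_lo) / dt)
    trace = pressure_trace(bs, beam, geom, t_lo, dt, n, segments=("direct",))
    n_radial = min(220, 100_000 // z_grid.size)
    oracle = oracle_pressure_trace(bs, beam, geom, trace.times, n_radial=n_radial)
    return float(
        np.linalg.norm(trace.samples - oracle.samples) / np.linalg.norm(oracle.samples)
    )


def timing_study(
    energy_mev: float = 9.4,
    sigma_r: float = 1.5e-3,
    model: StoppingModel = StoppingModel(),
    dt: float = STUDY_DT,
) -> dict:
    """Three-segment structure of a mono-energetic trace.

    Returns the extremum arrival times of the direct, window and reflected
    pulses, the geometric predictions (z_d -+ z_peak)/c, and the offset of
    the direct extremum in samples.  The entrance-window source is enabled
    with the small energy fraction a few-MeV proton loses in a thin foil.
    """
    geom = MediumGeometry(
        z_d=STUDY_GEOMETRY.z_d, window_wet=40e-6, window_amplitude=0.02
    )
    r = csda_range(energy_mev, model)
    z_grid = np.arange(0.0, 1.3 * r, 2e-6)
    bs = bragg_curve(energy_mev, z_grid, model)
    beam = BeamParams(n_i=1e8, sigma_r=sigma_r)
    c, z_d = geom.c, geom.z_d
    t0 = (z_d - 1.3 * r) / c - 1e-6
    t_end = (z_d + 1.3 * r) / c + 4e-6
    n = int((t_end - t0) / dt)
    trace = pressure_trace(bs, beam, geom, t0, dt, n)
    t = trace.times
    z_peak = bs.peak_depth
    t_direct = (z_d - z_peak) / c
    t_window = z_d / c
    t_reflected = (z_d + z_peak) / c

    def extremum(lo, hi):
        m = (t >= lo) & (t <= hi)
        idx = np.flatnonzero(m)[np.argmax(np.abs(trace.samples[m]))]
        return float(t[idx]), float(abs(trace.samples[idx]))

    gap = 0.4e-6
    te_direct, a_direct = extremum(t0, t_window - gap)
    te_window, a_window = extremum(t_window - gap, t_window + gap)
    te_reflected, a_reflected = extremum(t_window + gap, t_end)
    return {
        "direct_extremum_s": te_direct,
        "window_extremum_s": te_window,
        "reflected_extremum_s": te_reflected,
        "predicted_direct_s": t_direct,
        "predicted_window_s": t_window,
        "predicted_reflected_s": t_reflected,
        "direct_offset_samples": (te_direct - t_direct) / dt,
        "reflected_offset_samples": (te_reflected - t_reflected) / dt,
        "amplitudes": (a_direct, a_window, a_reflected),
    }


# -- parameter-recovery study ------------------------------------------------

#: ground-truth bunch: quasi-monoenergetic Gaussian spectrum as delivered by
#: chromatic focusing optics
RECOVERY_TRUTH = {"mean": 7.0, "sd": 0.3, "n_i": 1e8, "sigma_r": 1.5e-3}
#: detector: 10 MHz, 60% fractional bandwidth; white noise at 20 dB SNR
RECOVERY_TF = {"f_c": 10e6, "fractional_bandwidth": 0.6}
RECOVERY_SNR_DB = 20.0
#: unfolding bins: 0.2 MeV, comparable to the transducer-limited axial
#: resolution, over the energy window implied by the trace's arrival-time
#: support (true spectrum +- 5 sd)
RECOVERY_BIN_EDGES = np.linspace(5.5, 8.5, 16)
RECOVERY_N_ITER = 12_000


def recovery_case(
    seed: int,
    geom: MediumGeometry = STUDY_GEOMETRY,
    model: StoppingModel = StoppingModel(),
):
    """Synthetic observed trace + kernel + truth record for one seed."""
    edges = RECOVERY_BIN_EDGES
    spectrum = make_spectrum(
        "gaussian",
        {"mean": RECOVERY_TRUTH["mean"], "sd": RECOVERY_TRUTH["sd"]},
        edges,
        n_i=RECOVERY_TRUTH["n_i"],
    )
    truth = TruthRecord(
        spectrum=spectrum,
        sigma_r=RECOVERY_TRUTH["sigma_r"],
        tf_meta=dict(RECOVERY_TF),
        noise_snr_db=RECOVERY_SNR_DB,
        seed=seed,
    )
    e_max = float(edges[-1])
    t_lo, t_hi = direct_window(
        geom, csda_range(e_max, model), truth.sigma_r, pad=0.5e-6
    )
    n = int((t_hi - t_lo) / STUDY_DT)
    observed, _ = make_noisy_trace(truth, geom, model, t_lo, STUDY_DT, n)
    tf = make_transducer_ir(
        RECOVERY_TF["f_c"], RECOVERY_TF["fractional_bandwidth"], STUDY_DT
    )
    return observed, tf, truth


def recovery_study(
    seed: int,
    geom: MediumGeometry = STUDY_GEOMETRY,
    model: StoppingModel = StoppingModel(),
) -> dict:
    """Full inverse run against a known synthetic bunch.

    Generates the noisy observed trace for ``seed``, reconstructs it with the
    default sigma_r grid, and reports truth-vs-recovered errors.
    """
    observed, tf, truth = recovery_case(seed, geom, model)
    cfg = AnnealConfig(
        bin_edges=RECOVERY_BIN_EDGES,
        seed=seed,
        n_iter=RECOVERY_N_ITER,
    )
    res = anneal(observed, tf, geom, cfg, model)
    mean_true = truth.spectrum.mean_energy
    mean_rec = res.spectrum.mean_energy
    return {
        "mean_true_mev": mean_true,
        "mean_recovered_mev": mean_rec,
        "mean_error_percent": 100.0 * (mean_rec / mean_true - 1.0),
        "n_i_true": truth.spectrum.n_i,
        "n_i_recovered": res.spectrum.n_i,
        "n_i_error_percent": 100.0 * (res.spectrum.n_i / truth.spectrum.n_i - 1.0),
        "sigma_r_true_mm": truth.sigma_r * 1e3,
        "sigma_r_recovered_mm": res.sigma_r * 1e3,
        "sigma_r_error_mm": (res.sigma_r - truth.sigma_r) * 1e3,
        "residual": res.residual,
    }
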
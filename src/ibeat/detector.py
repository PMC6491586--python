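"""Transducer transfer-function estimation and application.

The transducer plus receive electronics are modelled as a single linear
time-invariant system mapping incident on-axis pressure (Pa) to recorded
voltage (V).  The kernel is estimated from one calibration pair — the
measured trace of a well-characterized (e.g. mono-energetic) bunch and the
ideal pressure trace predicted for the same bunch — by regularized (Wiener)
spectral division.  All unmodelled detector physics (aperture averaging,
amplifier shaping, cabling) is absorbed into this one kernel.
"""

from __future__ import annotations

from ast import literal_eval
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .trace import AcousticTrace

__all__ = [
    "TransferFunction",
    "estimate_transfer",
    "apply_transfer",
    "write_transfer",
    "read_transfer",
]


@dataclass(frozen=True)
class TransferFunction:
    """Time-domain detector kernel in V/Pa per sample.

    ``lag0`` is the integer sample lag of the first kernel tap (negative for
    the acausal part kept by the centred spectral estimate).  ``meta`` holds
    centre frequency / bandwidth when the kernel is synthetic.
    """

    impulse_response: np.ndarray
    dt: float
    lag0: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = np.asarray(self.impulse_response, dtype=float)
        object.__setattr__(self, "impulse_response", h)
        if h.ndim != 1 or h.size == 0:
            raise ValueError("impulse_response must be a non-empty 1-D array")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def lags(self) -> np.ndarray:
        """Lag times (s) of the kernel taps."""
        return (self.lag0 + np.arange(self.impulse_response.size)) * self.dt

    def apply_to_samples(self, samples: np.ndarray) -> np.ndarray:
        """Convolve rows of ``samples`` with the kernel, preserving the time axis.

        Output sample k corresponds to the same absolute time as input
        sample k (the kernel's lag offset is honoured).
        """
        arr = np.atleast_2d(np.asarray(samples, dtype=float))
        n = arr.shape[1]
        full = fftconvolve(arr, self.impulse_response[None, :], axes=1)
        # full[m] lives at time index m + lag0 of the input grid
        out = np.zeros_like(arr)
        src_lo = max(0, -self.lag0)
        src_hi = min(full.shape[1], n - self.lag0)
        if src_hi > src_lo:
            out[:, src_lo + self.lag0 : src_hi + self.lag0] = full[:, src_lo:src_hi]
        return out if samples.ndim == 2 else out[0]


def apply_transfer(ideal: AcousticTrace, tf: TransferFunction) -> AcousticTrace:
    """Expected observed signal S_m(t) in volts for an ideal pressure trace."""
    if abs(ideal.dt - tf.dt) > 1e-9 * tf.dt:
        raise ValueError(f"dt mismatch: trace {ideal.dt} s vs kernel {tf.dt} s")
    return AcousticTrace(ideal.t0, ideal.dt, tf.apply_to_samples(ideal.samples), "V")


def estimate_transfer(
    measured: AcousticTrace, ideal: AcousticTrace, reg: float = 1e-3
) -> TransferFunction:
    """Estimate the detector kernel from a calibration pair.

    Wiener-style spectral division H = M I* / (|I|^2 + reg * max|I|^2); the
    kernel is inverse-transformed and centred so that both the causal and
    the small acausal (regularization-induced) parts are retained.

    Parameters
    ----------
    measured : AcousticTrace
        Recorded voltage trace of the calibration bunch.
    ideal : AcousticTrace
        Ideal pressure trace predicted for the same bunch on the same time
        grid.
    reg : float
        Noise-floor fraction of the peak spectral power of the ideal trace.
    """
    if abs(measured.dt - ideal.dt) > 1e-9 * ideal.dt:
        raise ValueError("calibration pair must share the sample interval")
    if not measured.aligned_with(ideal):
        raise ValueError("calibration pair must share an aligned time window")
    x = ideal.samples
    if not np.any(x):
        raise ValueError("ideal calibration trace is identically zero")
    n = x.size
    fx = np.fft.fft(x)
    fm = np.fft.fft(measured.samples)
    power = np.abs(fx) ** 2
    h_spec = fm * np.conj(fx) / (power + reg * power.max())
    h = np.real(np.fft.ifft(h_spec))
    h = np.roll(h, n // 2)
    return TransferFunction(h, ideal.dt, lag0=-(n // 2), meta={"reg": reg})


def write_transfer(tf: TransferFunction, path) -> None:
    """Write the kernel as two-column text (lag s, V/Pa) with header metadata."""
    header = [f"dt = {tf.dt!r} s", f"lag0 = {tf.lag0} samples"]
    for key, val in tf.meta.items():
        header.append(f"meta.{key} = {val!r}")
    header.append("columns: lag_s kernel")
    data = np.column_stack([tf.lags, tf.impulse_response])
    np.savetxt(Path(path), data, fmt="%.17g", header="\n".join(header))


def read_transfer(path) -> TransferFunction:
    """Read a kernel written by :func:`write_transfer`."""
    dt = None
    lag0 = 0
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("dt ="):
                dt = float(body.split("=")[1].split()[0])
            elif body.startswith("lag0 ="):
                lag0 = int(body.split("=")[1].split()[0])
            elif body.startswith("meta."):
                key, _, val = body[5:].partition("=")
                try:
                    meta[key.strip()] = literal_eval(val.strip())
                except (ValueError, SyntaxError):
                    meta[key.strip()] = val.strip()
    if dt is None:
        raise ValueError(f"{path}: missing dt header")
    data = np.loadtxt(path, ndmin=2)
    return TransferFunction(data[:, 1], dt, lag0, meta)
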
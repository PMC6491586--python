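"""Uniformly sampled acoustic time series and their plain-text serialization."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AcousticTrace", "write_trace", "read_trace"]


@dataclass(frozen=True)
class AcousticTrace:
    """Uniformly sampled acoustic trace.

    Ideal (modelled) pressure traces carry unit "Pa"; observed or
    detector-filtered signals carry unit "V".  Times are relative to the ion
    impact on the water volume.
    """

    t0: float
    dt: float
    samples: np.ndarray
    unit: str = "Pa"

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.dt > 0:
            raise ValueError("sample interval dt must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)

    def window(self, t_start: float, t_stop: float) -> "AcousticTrace":
        """Sub-trace restricted to [t_start, t_stop] (inclusive of samples within)."""
        i0 = int(np.ceil((t_start - self.t0) / self.dt - 1e-9))
        i1 = int(np.floor((t_stop - self.t0) / self.dt + 1e-9)) + 1
        i0, i1 = max(i0, 0), min(i1, len(self))
        if i1 <= i0:
            raise ValueError("window selects no samples")
        return AcousticTrace(self.t0 + i0 * self.dt, self.dt, self.samples[i0:i1], self.unit)

    def aligned_with(self, other: "AcousticTrace", rtol: float = 1e-6) -> bool:
        """True when the two traces share dt, t0 and length."""
        return (
            len(self) == len(other)
            and abs(self.dt - other.dt) <= rtol * self.dt
            and abs(self.t0 - other.t0) <= rtol * max(self.dt, abs(self.t0) + self.dt)
        )


def write_trace(trace: AcousticTrace, path) -> None:
    """Write a trace as two-column text (time s, amplitude) with a comment header.

    Floats are printed with 17 significant digits so the round trip through
    :func:`read_trace` is bit-exact.
    """
    path = Path(path)
    header = (
        f"t0 = {trace.t0!r} s\n"
        f"dt = {trace.dt!r} s\n"
        f"unit = {trace.unit}\n"
        "columns: time_s amplitude"
    )
    data = np.column_stack([trace.times, trace.samples])
    np.savetxt(path, data, fmt="%.17g", header=header)


def read_trace(path) -> AcousticTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    t0 = dt = None
    unit = "Pa"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("t0 ="):
                t0 = float(body.split("=")[1].split()[0])
            elif body.startswith("dt ="):
                dt = float(body.split("=")[1].split()[0])
            elif body.startswith("unit ="):
                unit = body.split("=")[1].strip()
    if t0 is None or dt is None:
        raise ValueError(f"{path}: missing t0/dt header")
    data = np.loadtxt(path, ndmin=2)
    return AcousticTrace(t0, dt, data[:, 1], unit)
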
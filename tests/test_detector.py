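"""Detector transfer function: estimation, application, LTI properties."""

import numpy as np
import pytest

import ibeat as ib


def _broadband_trace(n=512, dt=1e-8, seed=5):
    """Short modulated Gaussian pulse: ~10 +- 5 MHz spectral support, well
    away from the window edges."""
    t = dt * np.arange(n)
    center, width = n * dt / 2, 3 * dt
    x = np.exp(-0.5 * ((t - center) / width) ** 2) * np.cos(2e7 * np.pi * (t - center))
    return ib.AcousticTrace(0.0, dt, x, "Pa")


class TestApplyTransfer:
    def test_unit_kernel_is_identity(self):
        tr = _broadband_trace()
        tf = ib.TransferFunction(np.array([1.0]), tr.dt, lag0=0)
        out = ib.apply_transfer(tr, tf)
        assert out.unit == "V"
        assert np.allclose(out.samples, tr.samples, atol=1e-15)

    def test_linearity(self, transducer):
        x, y = _broadband_trace(seed=1), _broadband_trace(seed=2)
        y = ib.AcousticTrace(y.t0, y.dt, np.roll(y.samples, 40), "Pa")
        mix = ib.AcousticTrace(x.t0, x.dt, 2.0 * x.samples - 3.0 * y.samples, "Pa")
        lhs = ib.apply_transfer(mix, transducer).samples
        rhs = (
            2.0 * ib.apply_transfer(x, transducer).samples
            - 3.0 * ib.apply_transfer(y, transducer).samples
        )
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-18)

    def test_shift_invariance(self, transducer):
        x = _broadband_trace()
        shifted = ib.AcousticTrace(x.t0, x.dt, np.roll(x.samples, 25), "Pa")
        out = ib.apply_transfer(x, transducer).samples
        out_shifted = ib.apply_transfer(shifted, transducer).samples
        # compare away from the rolled-in boundary
        assert np.allclose(out_shifted[50:-50], np.roll(out, 25)[50:-50], rtol=1e-9,
                           atol=1e-12 * np.abs(out).max())

    def test_band_limiting(self, transducer):
        """A 10 MHz kernel leaves <1% spectral energy above 2x its centre."""
        rng = np.random.default_rng(11)
        x = ib.AcousticTrace(0.0, 1e-8, rng.normal(size=4096), "Pa")
        out = ib.apply_transfer(x, transducer)
        freqs = np.fft.rfftfreq(len(out), d=out.dt)
        power = np.abs(np.fft.rfft(out.samples)) ** 2
        high = power[freqs > 2e7].sum()
        assert high / power.sum() < 0.01

    def test_dt_mismatch_rejected(self, transducer):
        tr = ib.AcousticTrace(0.0, 2e-8, np.zeros(64), "Pa")
        with pytest.raises(ValueError):
            ib.apply_transfer(tr, transducer)


class TestEstimateTransfer:
    def test_identity_pair_gives_delta(self):
        x = _broadband_trace()
        tf = ib.estimate_transfer(ib.AcousticTrace(x.t0, x.dt, x.samples, "V"), x, reg=1e-6)
        peak = np.argmax(np.abs(tf.impulse_response))
        assert tf.lags[peak] == pytest.approx(0.0, abs=tf.dt / 2)
        # unit spectral response wherever the probe carries energy
        n = len(x)
        h_spec = np.abs(np.fft.fft(tf.impulse_response))
        x_spec = np.abs(np.fft.fft(x.samples))
        strong = x_spec > 0.1 * x_spec.max()
        assert np.allclose(h_spec[strong], 1.0, atol=0.02)

    def test_pure_delay_gives_shifted_peak(self):
        x = _broadband_trace()
        k = 17
        delayed = ib.AcousticTrace(x.t0, x.dt, np.roll(x.samples, k), "V")
        tf = ib.estimate_transfer(delayed, x)
        peak = np.argmax(np.abs(tf.impulse_response))
        assert tf.lags[peak] == pytest.approx(k * x.dt, abs=x.dt / 2)

    def test_roundtrip_recovers_kernel_in_band(self, transducer):
        """estimate(apply(x, h), x) matches h over the transducer passband."""
        x = _broadband_trace()
        measured = ib.apply_transfer(x, transducer)
        est = ib.estimate_transfer(measured, x, reg=1e-6)
        n = 4096
        h_true = np.fft.rfft(transducer.impulse_response, n) * np.exp(
            -2j * np.pi * np.fft.rfftfreq(n) * transducer.lag0
        )
        h_est = np.fft.rfft(est.impulse_response, n) * np.exp(
            -2j * np.pi * np.fft.rfftfreq(n) * est.lag0
        )
        freqs = np.fft.rfftfreq(n, d=transducer.dt)
        band = (freqs > 7e6) & (freqs < 13e6)  # -6 dB passband of the kernel
        num = np.linalg.norm(np.abs(h_est[band]) - np.abs(h_true[band]))
        assert num / np.linalg.norm(np.abs(h_true[band])) < 0.05

    def test_noisy_calibration_recovery(self, transducer):
        """Kernel recovered within 5% relative L2 in band at 30 dB SNR."""
        x = _broadband_trace()
        clean = ib.apply_transfer(x, transducer)
        rng = np.random.default_rng(4)
        rms = np.sqrt(np.mean(clean.samples**2))
        noisy = ib.AcousticTrace(
            clean.t0, clean.dt,
            clean.samples + rng.normal(0, rms / 10**1.5, len(clean)), "V",
        )
        est = ib.estimate_transfer(noisy, x, reg=1e-4)
        n = 4096
        freqs = np.fft.rfftfreq(n, d=x.dt)
        band = (freqs > 7e6) & (freqs < 13e6)
        h_true = np.abs(np.fft.rfft(transducer.impulse_response, n))[band]
        h_est = np.abs(np.fft.rfft(est.impulse_response, n))[band]
        assert np.linalg.norm(h_est - h_true) / np.linalg.norm(h_true) < 0.05

    def test_zero_ideal_rejected(self):
        z = ib.AcousticTrace(0.0, 1e-8, np.zeros(64), "Pa")
        m = ib.AcousticTrace(0.0, 1e-8, np.ones(64), "V")
        with pytest.raises(ValueError):
            ib.estimate_transfer(m, z)

    def test_dt_mismatch_rejected(self):
        a = ib.AcousticTrace(0.0, 1e-8, np.ones(64), "V")
        b = ib.AcousticTrace(0.0, 2e-8, np.ones(64), "Pa")
        with pytest.raises(ValueError):
            ib.estimate_transfer(a, b)


def test_transfer_file_roundtrip(tmp_path, transducer):
    path = tmp_path / "tf.txt"
    ib.write_transfer(transducer, path)
    back = ib.read_transfer(path)
    assert back.dt == transducer.dt
    assert back.lag0 == transducer.lag0
    assert np.array_equal(back.impulse_response, transducer.impulse_response)
    assert back.meta["f_c"] == transducer.meta["f_c"]
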
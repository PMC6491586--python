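"""Simulated-annealing spectrum unfolding: residual, perturbation kernel,
acceptance rules, determinism, and small recovery runs."""

import json

import numpy as np
import pytest

import ibeat as ib
from ibeat.anneal import fit_report


@pytest.fixture(scope="module")
def tiny_problem(geometry, stopping, transducer):
    """Noiseless single-bin bunch observed through the 10 MHz transducer."""
    edges = np.linspace(6.0, 8.0, 9)  # 8 bins of 0.25 MeV
    spec = ib.make_spectrum("mono", {"energy": 7.1}, edges, n_i=1e8)
    truth = ib.TruthRecord(spectrum=spec, sigma_r=1.5e-3, noise_snr_db=np.inf, seed=0)
    t_lo, t_hi = ib.direct_window(
        geometry, ib.csda_range(8.0, stopping), 1.5e-3, pad=0.5e-6
    )
    n = int((t_hi - t_lo) / 1e-8)
    observed, _ = ib.make_noisy_trace(truth, geometry, stopping, t_lo, 1e-8, n)
    return observed, truth, edges


class TestResidual:
    def test_identical_traces_zero(self):
        tr = ib.AcousticTrace(0.0, 1e-8, np.arange(50.0), "V")
        assert ib.residual(tr, tr) == 0.0

    def test_unit_offset_counts_samples(self):
        n = 37
        a = ib.AcousticTrace(0.0, 1e-8, np.zeros(n), "V")
        b = ib.AcousticTrace(0.0, 1e-8, np.ones(n), "V")
        assert ib.residual(b, a) == pytest.approx(float(n))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=100), rng.normal(size=100)
        a = ib.AcousticTrace(0.0, 1e-8, x, "V")
        b = ib.AcousticTrace(0.0, 1e-8, y, "V")
        brute = sum((xi - yi) ** 2 for xi, yi in zip(x, y))
        assert ib.residual(a, b) == pytest.approx(brute, rel=1e-12)

    def test_misaligned_traces_rejected(self):
        a = ib.AcousticTrace(0.0, 1e-8, np.zeros(10), "V")
        b = ib.AcousticTrace(1e-8, 1e-8, np.zeros(10), "V")
        with pytest.raises(ValueError):
            ib.residual(a, b)


class TestPerturbSpectrum:
    def setup_method(self):
        edges = np.linspace(4, 10, 13)
        self.spec = ib.make_spectrum("gaussian", {"mean": 7, "sd": 1.0}, edges, n_i=1e8)

    def test_zero_scale_is_identity(self):
        out = ib.perturb_spectrum(self.spec, 0.0, np.random.default_rng(0))
        assert np.allclose(out.f, self.spec.f, rtol=1e-12)
        assert out.n_i == pytest.approx(self.spec.n_i, rel=1e-12)

    def test_output_remains_normalized_nonnegative(self):
        rng = np.random.default_rng(1)
        spec = self.spec
        for _ in range(200):
            spec = ib.perturb_spectrum(spec, 1.0, rng)
            assert np.all(spec.f >= 0)
            assert np.sum(spec.f * spec.widths) == pytest.approx(1.0, abs=1e-9)

    def test_single_bin_kick_is_uniform(self):
        """Each bin is picked ~1/n_bins of the time over many draws."""
        rng = np.random.default_rng(2)
        n_bins, n_draws = 12, 10_000
        counts = np.zeros(n_bins)
        for _ in range(n_draws):
            out = ib.perturb_spectrum(self.spec, 0.5, rng)
            changed = np.flatnonzero(
                ~np.isclose(out.masses * out.n_i, self.spec.masses * self.spec.n_i,
                            rtol=1e-12)
            )
            if changed.size:
                counts[changed[0]] += 1
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - 1.0 / n_bins) < 0.015)


class TestAnneal:
    def test_zero_observed_gives_empty_bunch(self, geometry, transducer):
        edges = np.linspace(6.0, 8.0, 9)
        obs = ib.AcousticTrace(3.5e-5, 1e-8, np.zeros(200), "V")
        cfg = ib.AnnealConfig(bin_edges=edges, sigma_grid=[1.5e-3], n_iter=20, seed=0)
        res = ib.anneal(obs, transducer, geometry, cfg)
        assert res.spectrum.n_i == 0.0
        assert res.residual == 0.0

    def test_determinism_bitwise(self, tiny_problem, geometry, stopping, transducer):
        observed, _, edges = tiny_problem
        cfg = ib.AnnealConfig(
            bin_edges=edges, sigma_grid=[1.3e-3, 1.5e-3], n_iter=150, seed=42
        )
        r1 = ib.anneal(observed, transducer, geometry, cfg, stopping)
        r2 = ib.anneal(observed, transducer, geometry, cfg, stopping)
        assert np.array_equal(r1.spectrum.f, r2.spectrum.f)
        assert r1.spectrum.n_i == r2.spectrum.n_i
        assert r1.sigma_r == r2.sigma_r
        assert np.array_equal(r1.history, r2.history)
        assert r1.accepted_count == r2.accepted_count

    def test_greedy_limit_history_nonincreasing(
        self, tiny_problem, geometry, stopping, transducer
    ):
        """Metropolis at T -> 0+ reduces to greedy descent."""
        observed, _, edges = tiny_problem
        cfg = ib.AnnealConfig(
            bin_edges=edges, sigma_grid=[1.5e-3], n_iter=400, seed=3,
            temperature=1e-12, acceptance_rule="metropolis",
        )
        res = ib.anneal(observed, transducer, geometry, cfg, stopping)
        assert np.all(np.diff(res.history) <= 1e-18)

    def test_running_minimum_nonincreasing(
        self, tiny_problem, geometry, stopping, transducer
    ):
        observed, _, edges = tiny_problem
        cfg = ib.AnnealConfig(bin_edges=edges, sigma_grid=[1.5e-3], n_iter=400, seed=5)
        res = ib.anneal(observed, transducer, geometry, cfg, stopping)
        run_min = np.minimum.accumulate(res.history)
        assert np.all(np.diff(run_min) <= 0)
        assert res.residual <= run_min[-1] + 1e-18

    def test_single_bin_recovery_noiseless(
        self, tiny_problem, geometry, stopping, transducer
    ):
        """A noiseless mono-energetic bunch is located to within one bin and
        one sigma_r grid step."""
        observed, truth, edges = tiny_problem
        cfg = ib.AnnealConfig(
            bin_edges=edges,
            sigma_grid=[1.1e-3, 1.3e-3, 1.5e-3, 1.7e-3, 1.9e-3],
            n_iter=4000,
            seed=11,
        )
        res = ib.anneal(observed, transducer, geometry, cfg, stopping)
        true_bin = int(np.argmax(truth.spectrum.masses))
        mass = res.spectrum.masses
        near = mass[max(true_bin - 1, 0) : true_bin + 2].sum()
        assert near >= 0.9
        assert res.sigma_r == pytest.approx(truth.sigma_r, abs=0.2e-3)

    def test_invalid_config_rejected(self):
        edges = np.linspace(4, 10, 5)
        with pytest.raises(ValueError):
            ib.AnnealConfig(bin_edges=edges, temperature=0.0)
        with pytest.raises(ValueError):
            ib.AnnealConfig(bin_edges=edges, sigma_grid=[])
        with pytest.raises(ValueError):
            ib.AnnealConfig(bin_edges=edges, acceptance_rule="downhill")


class TestFitReport:
    def test_misfit_definition_and_json_roundtrip(
        self, tiny_problem, geometry, stopping, transducer
    ):
        observed, _, edges = tiny_problem
        cfg = ib.AnnealConfig(bin_edges=edges, sigma_grid=[1.5e-3], n_iter=300, seed=2)
        res = ib.anneal(observed, transducer, geometry, cfg, stopping)
        rep = fit_report(res, observed)
        assert rep["relative_misfit"] == pytest.approx(
            np.sqrt(res.residual) / np.linalg.norm(observed.samples)
        )
        back = json.loads(json.dumps(rep))
        assert back["n_i"] == rep["n_i"]
        assert back["f_per_mev"] == rep["f_per_mev"]

    def test_perfect_fit_zero_misfit(self, tiny_problem, geometry, stopping, transducer):
        observed, _, edges = tiny_problem
        cfg = ib.AnnealConfig(bin_edges=edges, sigma_grid=[1.5e-3], n_iter=10, seed=0)
        res = ib.anneal(observed, transducer, geometry, cfg, stopping)
        fake = ib.ReconResult(
            spectrum=res.spectrum, sigma_r=res.sigma_r, residual=0.0,
            history=res.history, accepted_count=res.accepted_count,
            sigma_grid=res.sigma_grid, sigma_residuals=res.sigma_residuals,
            model_trace=observed,
        )
        assert fit_report(fake, observed)["relative_misfit"] == 0.0
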
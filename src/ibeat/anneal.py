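"""Spectrum unfolding by simulated annealing.

The inverse problem: given one observed voltage trace S_0(t), find the
discretized energy distribution f(E_kin), the ion count n_i and the
transverse bunch width sigma_r whose forward-modelled signal
S_m(t) = detector( pressure( spread_bragg(f) ) ) minimizes the least-squares
residual Sigma = sum_k (S_m[k] - S_0[k])^2.

The spectrum is annealed at fixed temperature (T = 1 by default, no cooling
schedule): each iteration multiplies one uniformly chosen bin weight by
exp(u), u ~ U(-scale, scale), and the move is kept or discarded by the
acceptance rule.  sigma_r is handled by an outer grid search; the result
with the globally smallest residual wins.

Because the forward map is linear in the per-bin ion counts, the trace of
every candidate spectrum is a single matrix-vector product against a
precomputed bank of per-bin, per-ion detector-filtered traces; the annealing
loop itself is therefore cheap and the cost is dominated by one forward-bank
evaluation per sigma_r grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bragg import EnergySpectrum, bragg_curve_bank
from .detector import TransferFunction
from .forward import MediumGeometry, pressure_bank
from .stopping import StoppingModel, csda_range
from .trace import AcousticTrace

__all__ = [
    "AnnealConfig",
    "ReconResult",
    "residual",
    "perturb_spectrum",
    "anneal",
    "fit_report",
]


@dataclass(frozen=True)
class AnnealConfig:
    """Settings of the annealing reconstruction.

    Parameters
    ----------
    bin_edges : array
        Kinetic-energy bin boundaries (MeV) of the unknown spectrum.
    sigma_grid : array
        Candidate transverse widths sigma_r (m) for the outer grid search; a
        single-element grid fixes sigma_r.
    n_iter : int
        Annealing iterations per sigma_r grid point (default 500, i.e. "a
        few hundred").
    temperature : float
        Fixed annealing temperature T (default 1, no cooling schedule).
    perturb_scale : float
        Half-width of the uniform log-multiplicative bin kick exp(u),
        u ~ U(-scale, scale).
    seed : int
        Base RNG seed; each sigma_r grid point gets an independent child
        stream, so results are reproducible bit-for-bit.
    acceptance_rule : str
        "paper_literal" (default: a worse candidate is *rejected* with
        probability exp(-dSigma/T), so for residual changes small against T
        the rule is a near-greedy descent) or "metropolis" (standard form:
        accept a worse candidate with probability exp(-dSigma/T); requires T
        commensurate with the residual scale in V^2 to be useful).
    segments : tuple of str
        Which wave components the model trace includes when fitting
        (default direct pulse only).
    z_step : float
        Depth-grid step (m) of the internal Bragg-curve bank.
    oversample : int
        Internal time oversampling of the forward model.
    """

    bin_edges: np.ndarray
    sigma_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.5e-3, 5.01e-3, 0.2e-3), 10)
    )
    n_iter: int = 500
    temperature: float = 1.0
    perturb_scale: float = 0.5
    seed: int = 0
    acceptance_rule: str = "paper_literal"
    segments: tuple = ("direct",)
    z_step: float = 10e-6
    oversample: int = 20

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        grid = np.atleast_1d(np.asarray(self.sigma_grid, dtype=float))
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "sigma_grid", grid)
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")
        if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
            raise ValueError("sigma_grid must be non-empty, positive and ascending")
        if self.acceptance_rule not in ("metropolis", "paper_literal"):
            raise ValueError(f"unknown acceptance rule {self.acceptance_rule!r}")


@dataclass(frozen=True)
class ReconResult:
    """Outcome of one annealing reconstruction.

    ``spectrum`` carries the retrieved f(E_kin) and absolute ion count n_i;
    ``history`` is the per-iteration residual of the winning sigma_r run.
    """

    spectrum: EnergySpectrum
    sigma_r: float
    residual: float
    history: np.ndarray
    accepted_count: int
    sigma_grid: np.ndarray
    sigma_residuals: np.ndarray
    model_trace: AcousticTrace

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


def residual(model: AcousticTrace, observed: AcousticTrace) -> float:
    """Least-squares residual Sigma = sum_k (S_model[k] - S_0[k])^2."""
    if not model.aligned_with(observed):
        raise ValueError("model and observed traces are not aligned (t0/dt/length)")
    diff = model.samples - observed.samples
    return float(diff @ diff)


def _perturb_masses(masses: np.ndarray, scale: float, rng: np.random.Generator):
    """Multiply one uniformly chosen bin mass by exp(U(-scale, scale))."""
    idx = int(rng.integers(masses.size))
    u = float(rng.uniform(-scale, scale))
    out = masses.copy()
    out[idx] = max(out[idx] * np.exp(u), 0.0)
    return out, idx


def perturb_spectrum(
    spectrum: EnergySpectrum, scale: float, rng: np.random.Generator
) -> EnergySpectrum:
    """Randomly vary one spectrum bin, keeping f normalized.

    The unnormalized weight of a uniformly chosen bin is multiplied by
    exp(u) with u ~ U(-scale, scale); the density is renormalized and the
    change of total weight is folded into the ion count n_i, so the total
    fluence n_i * f * dE is what actually moved.
    """
    masses, _ = _perturb_masses(spectrum.masses, scale, rng)
    return EnergySpectrum.from_masses(spectrum.bin_edges, masses, spectrum.n_i)


def _accept(d_sigma: float, rule: str, temperature: float, rng) -> bool:
    if d_sigma <= 0:
        return True
    p = np.exp(-d_sigma / temperature)
    if rule == "metropolis":
        return bool(rng.random() < p)
    return bool(rng.random() >= p)  # paper_literal: reject with probability p


def _model_bank(
    centers: np.ndarray,
    z_grid: np.ndarray,
    geom: MediumGeometry,
    sigma_r: float,
    tf: TransferFunction,
    observed: AcousticTrace,
    model: StoppingModel,
    cfg: AnnealConfig,
    bragg_bank: np.ndarray,
) -> np.ndarray:
    """Detector-filtered trace (V) of one ion in each energy bin: (n_bins, n_t)."""
    p = pressure_bank(
        bragg_bank,
        z_grid,
        geom,
        sigma_r,
        observed.t0,
        observed.dt,
        len(observed),
        cfg.segments,
        cfg.oversample,
    )
    return tf.apply_to_samples(p)


def anneal(
    observed: AcousticTrace,
    tf: TransferFunction,
    geom: MediumGeometry,
    cfg: AnnealConfig,
    model: StoppingModel = StoppingModel(),
) -> ReconResult:
    """Retrieve f(E_kin), n_i and sigma_r from one observed trace.

    For each sigma_r grid point the spectrum is annealed from a flat start
    (scaled to the observed trace by least squares); the grid point with the
    globally smallest residual is returned.  Deterministic given cfg.seed.
    """
    if abs(observed.dt - tf.dt) > 1e-9 * tf.dt:
        raise ValueError("observed trace and transfer function dt mismatch")
    edges = cfg.bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    e_max = float(edges[-1])
    z_grid = np.arange(0.0, 1.25 * csda_range(e_max, model) + cfg.z_step, cfg.z_step)
    bragg_bank = bragg_curve_bank(centers, z_grid, model)

    s0 = observed.samples
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.sigma_grid.size)

    best = None  # (residual, sigma_idx, masses, history, accepted)
    sigma_residuals = np.empty(cfg.sigma_grid.size)
    banks: dict[int, np.ndarray] = {}
    for j, sigma_r in enumerate(cfg.sigma_grid):
        bank = _model_bank(
            centers, z_grid, geom, float(sigma_r), tf, observed, model, cfg, bragg_bank
        )
        banks[j] = bank
        rng = np.random.default_rng(seeds[j])

        flat = np.full(centers.size, 1.0 / centers.size)
        s_flat = flat @ bank
        denom = float(s_flat @ s_flat)
        scale0 = max(float(s_flat @ s0) / denom, 0.0) if denom > 0 else 0.0
        masses = flat * scale0  # ions per bin, n_i = masses.sum()

        cur = masses
        cur_sigma = float(np.sum((cur @ bank - s0) ** 2))
        best_local = (cur_sigma, cur)
        history = np.empty(cfg.n_iter)
        accepted = 0
        for it in range(cfg.n_iter):
            cand, _ = _perturb_masses(cur, cfg.perturb_scale, rng)
            cand_sigma = float(np.sum((cand @ bank - s0) ** 2))
            if _accept(cand_sigma - cur_sigma, cfg.acceptance_rule, cfg.temperature, rng):
                cur, cur_sigma = cand, cand_sigma
                accepted += 1
                if cand_sigma < best_local[0]:
                    best_local = (cand_sigma, cand)
            history[it] = cur_sigma
        sigma_residuals[j] = best_local[0]
        if best is None or best_local[0] < best[0]:
            best = (best_local[0], j, best_local[1], history, accepted)

    res, j_best, masses, history, accepted = best
    if masses.sum() > 0:
        spectrum = EnergySpectrum.from_masses(edges, masses)
    else:  # empty bunch: residual is minimized by n_i = 0
        flat_f = np.full(widths.size, 1.0 / (edges[-1] - edges[0]))
        spectrum = EnergySpectrum(edges, flat_f, 0.0)
    model_samples = masses @ banks[j_best]
    return ReconResult(
        spectrum=spectrum,
        sigma_r=float(cfg.sigma_grid[j_best]),
        residual=res,
        history=history,
        accepted_count=accepted,
        sigma_grid=cfg.sigma_grid,
        sigma_residuals=sigma_residuals,
        model_trace=AcousticTrace(observed.t0, observed.dt, model_samples, "V"),
    )


def fit_report(result: ReconResult, observed: AcousticTrace) -> dict:
    """JSON-serializable summary of a reconstruction against its data.

    Reports the final residual, the relative L2 misfit sqrt(Sigma)/||S_0||,
    the recovered spectrum moments, sigma_r and the reconstructed trace for
    overlay plots.
    """
    spec = result.spectrum
    norm = float(np.linalg.norm(observed.samples))
    mean_e = spec.mean_energy
    var_e = float(np.sum(spec.masses * (spec.centers - mean_e) ** 2))
    return {
        "residual": result.residual,
        "relative_misfit": float(np.sqrt(result.residual)) / norm if norm > 0 else 0.0,
        "n_i": spec.n_i,
        "sigma_r_m": result.sigma_r,
        "mean_energy_mev": mean_e,
        "std_energy_mev": float(np.sqrt(var_e)),
        "accepted_count": result.accepted_count,
        "n_iter": int(result.history.size),
        "bin_edges_mev": spec.bin_edges.tolist(),
        "f_per_mev": spec.f.tolist(),
        "model_trace": {
            "t0": result.model_trace.t0,
            "dt": result.model_trace.dt,
            "samples": result.model_trace.samples.tolist(),
        },
    }
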
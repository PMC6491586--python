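# Methods

`ibeat` models and inverts the ionoacoustic signal of a single, short ion
bunch stopping in water: a bunch whose duration is far below the acoustic
period deposits its energy effectively instantaneously, the heated column
launches a pressure wave, and an on-axis ultrasound transducer records it.
Because the depth profile of the deposition (the Bragg curve) is a sharp,
energy-dependent fingerprint, one recorded trace determines the absolute
kinetic-energy distribution of the bunch.  This note records the model, the
numerical choices, and what the synthetic studies do and do not demonstrate.

## Forward model

**Stopping.** The CSDA range in water is parameterized by the Bragg-Kleeman
power law `R = alpha * E^p` with defaults `alpha = 2.2e-3 cm/MeV^p`,
`p = 1.77`, which tracks published CSDA tabulations within a few percent
over 1-250 MeV (checked to 5% at 100 MeV in the tests).  The single-ion
depth-deposition profile is built from the exact residual-energy difference
across each grid cell — `E(z) = ((R - z)/alpha)^(1/p)`, so the integrable
`(R - z)^(1/p - 1)` stopping-power singularity at the end of range is
integrated analytically cell by cell — then convolved with a Gaussian
range-straggling width `sigma = 0.012 * R^0.935` (R in cm) and renormalized
so the depth integral equals the ion energy.  Energy conservation is
therefore exact by construction and verified to 0.5% in the tests.
Entrance windows (Ti, kapton, air) are characterized purely by
water-equivalent thickness through the residual-range rule.

**Acoustics.** For a deposition that factorizes into a depth profile
`B_s(z)` and a transverse Gaussian of width `sigma_r`, the spherical-mean
(Poisson) solution of the thermoacoustic wave equation gives the on-axis
pressure at distance `z_d` as

    p(z_d, t) = Gamma n_i / (4 pi c sigma_r^2) *
                d/dt Int_{z_d-ct}^{z_d+ct} B_s(z')
                exp(-[c^2 t^2 - (z_d - z')^2] / (2 sigma_r^2)) dz'.

Defaults are water near 20 degC: `c = 1483 m/s`, `Gamma = 0.11`,
`rho = 1000 kg/m^3`; all configurable, and the detector distance `z_d` is a
required, experiment-specific input.  Three wave components are summed
linearly: the direct pulse, a small entrance-window deposition pulse
(Gaussian source of the foil's water-equivalent width at z = 0, off by
default), and the initially backward-running wave returned by the entrance
boundary, modelled as an image source `B_s(-z')` scaled by a pressure
reflection coefficient (default -1, a pressure-release boundary behind an
acoustically thin foil; the sign and magnitude are configurable).
Side-wall reflections, off-axis field points, frequency-dependent water
attenuation and aperture integration are out of scope; the transducer is a
point on axis and everything else it does sits in the transfer function.

**Quadrature.** The kernel integral is evaluated on the deposition grid
with one numerical subtlety: the integrand equals exactly 1 at the moving
limits `|z_d - z'| = ct`, so a hard in/out mask makes the integral a
staircase in `t` whose finite-difference derivative is spike noise.  The
cell crossed by the wavefront is therefore included with its fractional
covered length (partial-volume weighting), which restores a C1 integrand.
The time derivative is a central difference on an internal grid oversampled
20x relative to the output sampling.  Against the exact analytic derivative
(boundary terms `c B_s(z_d -+ ct)` plus the interior `-c^2 t / sigma_r^2`
term) this path agrees to ~1% for resolved depth grids; a mono-energetic
curve should be sampled at a few micrometres (a few points per straggling
width), while broad spectra are well resolved by the default 10 um step.

**Independent oracle.** `oracle_pressure_trace` verifies the closed form by
brute force: the 3-D source is discretized into coaxial annulus x depth
cells (every point of a ring is equidistant from the on-axis detector);
each cell's energy is spread uniformly over the retarded arrival interval
given by its corner distances, accumulated on a 32x-oversampled time grid,
and the spherical-mean potential is differentiated numerically.  Annuli are
equal transverse probability mass (Rayleigh-CDF inversion), which removes
radial discretization bias; the uniform interval deposit removes the comb
aliasing a point-lumped source produces.  The oracle is O(cells) and guarded
at 1e5 cells — it exists for verification, not production.  Forward and
oracle agree to 1-1.6% relative L2 on the four standard study
configurations (5-7 MeV, sigma_r 1-2 mm, z_d 25-55 mm); the agreement
bound asserted in the acceptance suite is 3%.

## Detector response

The transducer plus electronics are one LTI kernel in V/Pa, estimated from
a calibration pair (measured trace of a well-known bunch vs the ideal
predicted pressure) by Wiener-regularized spectral division
`H = M I* / (|I|^2 + reg |I|^2_max)`, default `reg = 1e-3`.  The kernel is
kept centred (acausal taps retained) because regularization spreads a small
amount of energy to negative lags.  A calibration probe must carry spectral
energy across the band in which the kernel is to be trusted; outside the
probe's support the estimate falls back to ~0 (the regularization floor).
Synthetic kernels are Gaussian-enveloped sinusoids specified by centre
frequency and -6 dB fractional bandwidth (default 10 MHz, 60%, V311-like),
normalized to unit peak spectral magnitude times a nominal sensitivity.

## Inverse problem

The unknowns are the per-bin ion numbers `w_b = n_i f_b dE_b` on
user-chosen energy bins, plus the transverse width `sigma_r`.  Because the
forward map is linear in `w`, the trace of one ion in each bin is
precomputed per `sigma_r` (a bank of detector-filtered traces), and each
candidate spectrum costs one matrix-vector product; the annealing loop is
essentially free next to the per-`sigma_r` bank construction.

One iteration multiplies a uniformly chosen bin weight by `exp(u)`,
`u ~ U(-s, s)` (default s = 0.5), clips at zero, and evaluates
`Sigma = sum_k (S_m[k] - S_0[k])^2`.  The starting spectrum is flat, scaled
to the data by one least-squares fit of its amplitude.  `sigma_r` is an
outer grid search (default 0.5-5.0 mm in 0.2 mm steps, matching the
quantization of the reported width error); the grid point with the smallest
residual wins, and a single-element grid fixes `sigma_r`.  Runs are
bit-reproducible: each grid point gets an independent child stream of the
configured seed.

**Acceptance rule.** Two rules are implemented, at fixed temperature
(default T = 1, no cooling).  The default, `paper_literal`, *rejects* a
worsening move with probability `exp(-dSigma/T)` (accepts it with
`1 - exp(-dSigma/T)`).  For volt-scale traces, residual changes are tiny
against T = 1, so this behaves as near-greedy descent with rare uphill
escapes — and it converges.  The textbook alternative, `metropolis`
(*accept* worse with `exp(-dSigma/T)`), is also provided, but note that at
T = 1 on volt-scale data it accepts essentially every worsening move and
degenerates into a random walk; it is only useful with T set commensurate
with typical residual changes in V^2, and at T -> 0+ it reduces to pure
greedy descent (a property the tests exercise).  Neither rule's behaviour
is scale-free; this is an inherent consequence of fixing T while measuring
Sigma in physical units, and the reason the non-standard literal rule is
the default.

**Bins and windows.** The unfolding bins should match the physics: the
band-limited detector (10 MHz) gives an axial resolution of roughly half a
wavelength (~75 um), i.e. ~0.4 MeV around 7 MeV, so bins much finer than
that are strongly degenerate, anneal slowly, and — with noise — accumulate
spurious mass in bins whose arrival times contain no true signal (ordinary
noise-fitting of unregularized unfolding; no regularization is applied by
design).  The recovery studies therefore unfold on 0.2 MeV bins over an
energy window set the way a practitioner would set it, from the
arrival-time support of the trace.  The fit window is the direct segment by
default; the reflected segment can be included since it images the source
from the opposite side.

## Synthetic data and what the studies show

The generator produces mono-energetic, Gaussian (quasi-monoenergetic, as
delivered by chromatic focusing optics) and TNSA-exponential-with-cutoff
spectra; band-limited kernels; and observed traces through the full forward
chain with additive white Gaussian noise scaled to a stated SNR over the
direct-pulse window.  Everything regenerates exactly from (seed, config).
Real measurements differ in ways the generator deliberately omits:
structured EMP pickup (suppressed in practice by the microsecond acoustic
delay), digitizer quantization and trigger jitter, frequency-dependent
attenuation, non-Gaussian transverse profiles, and a detector response that
is only approximately LTI.  Passing recovery tests therefore demonstrate
the correctness and conditioning of the inference chain under its own
model, not field performance.

The standard recovery study: truth = Gaussian spectrum (7.0 +- 0.3 MeV,
1e8 protons, sigma_r = 1.5 mm), 10 MHz / 60% kernel, 20 dB SNR,
z_d = 55 mm (a ~36.5 us direct arrival), 100 MS/s sampling; reconstruction
on 15 x 0.2 MeV bins over 5.5-8.5 MeV with 12,000 iterations per sigma_r
grid point and the default 23-point sigma_r grid.  It runs in a few seconds
per realization on one CPU.  Typical outcomes (several seeds): spectral
mean within ~1.7%, n_i within ~7%, sigma_r recovered exactly at the grid
resolution (+-0.2 mm).

## Degenerate inputs and edge behaviour

Zero observed trace reconstructs to n_i = 0 (flat shape placeholder).  An
all-zero candidate spectrum is valid mid-anneal (clipping) and handled by
the n_i = 0 path.  Depth grids that do not cover 1.2x the range of a
contributing bin raise `GridCoverageError` rather than silently truncating
energy.  A bunch stopped entirely in the entrance window returns 0 MeV from
the slab rule, which is a valid outcome, not an error.  Trace and kernel
files round-trip bit-exactly (17 significant digits).

## Known limitations

- The power-law range model drifts by a few percent against tabulated
  stopping powers at the extremes of 1-250 MeV; a user-supplied range table
  would tighten absolute depth-energy mapping (the range coefficients are
  configurable).
- The retrieved n_i is only as absolute as the V/Pa calibration embedded in
  the transfer function.
- No uncertainty quantification beyond the residual and the sigma_r grid
  quantization; no multi-transducer or mixed-species reconstruction.
- The annealer is a stochastic point estimator; with very fine bins it
  under-converges and inherits the noise-fitting bias discussed above.
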
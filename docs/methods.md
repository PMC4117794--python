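# Methods

This note records the models, defaults and numerical choices behind
`g4pull`, and what the synthetic-data tests do and do not demonstrate.

## Physical constants and units

Forces are pN, lengths nm, times s, energies kBT internally (kcal/mol
only as a formatted output; 1 kBT = 0.586 kcal/mol at the default
295 K, the midpoint of the 21–23 °C room-temperature range).
kBT = 0.0138065·T pN·nm ≈ 4.073 pN·nm at 295 K.

## Polymer mechanics

**ssDNA.**  The unfolded 21-nt chain uses an extensible freely jointed
chain, x(f)/nt = c·L(f·b/kBT)·(1 + f/S), with Kuhn length b = 1.5 nm,
contour c = 0.56 nm/nt and stretch modulus S = 800 pN.  Real ssDNA in
~100 mM monovalent salt deviates from any ideal chain at low force
(base stacking); empirical phenomenological curves are more extensible
below ~10 pN than this eFJC.  The defaults were chosen once so the
observable step size lands on the measured anchors — 6.0 nm at 6.5 pN
and 8.9 nm at 20 pN (measured ~6 and 8 ± 2 nm) — because the analysis
chain only consumes extension *changes*.  A `phenomenological` model
accepts a tabulated (f, x/nt) curve through a monotone PCHIP
interpolant when an empirical parametrization is available.

**Folded G4.**  A rigid rod of size l₀ = 1.7 nm whose projection on the
force axis is l₀·L(f·l₀/kBT), with L the Langevin function.  L is
evaluated by its series below argument 0.05 to avoid catastrophic
cancellation; the f → 0 limit is analytic (→ 0).

**Δφ(f)** = −∫₀^f [x_ssDNA − x_G4] df′ / kBT by trapezoid quadrature on
a ≤ 0.005 pN grid (a 64-point Gauss–Legendre alternative agrees to
< 10⁻³ kBT over 0–50 pN).

*Consequence for the energetics*: because the default eFJC carries less
low-force extension than empirical ssDNA curves, |Δφ(5–7 pN)| is
~25–30 % smaller than an empirical-curve evaluation would give.  The
short-state ΔG0 lands at ~2.5 kBT (reported 3.6 ± 0.6) — inside a
±1.5 kBT band — while the long-state ΔG0 (~3.2 kBT vs reported
5.9 ± 0.4) cannot reach the reported value under *any* analysis
consistent with the printed lifetimes and this ssDNA curve: the
stationary ratio P_L/P_U is bounded by τ_long/τ_u ≈ 2.85, i.e.
ΔG_long(5 pN) ≤ 1.05 kBT, so ΔG0_long ≤ 1.05 + |Δφ(5 pN)| ≈ 4.4 kBT.
The package therefore treats the long-state zero-force band as an
advisory comparison, reported but not enforced.

## Kinetic scheme

States U (unfolded), S (short-lived fold), L (long-lived fold), UL
(ultra-long-lived fold); sequential topology U ⇌ S ⇌ L with branch
S → UL (configurable to L → UL) and rupture UL → U.  Each edge is a
Bell law k(f) = k0·e^(dx·f/kBT); dx is stored signed (folding < 0) and
reported as a magnitude.

**Dwell constants → microscopic rates.**  The observable folded-dwell
distribution of the sequential scheme is phase-type: an excursion into
{S, L} starting at S decays as a two-exponential mixture whose rate
constants are the eigenvalues λ± of the sub-generator
(λ₊λ₋ = k21·k32, λ₊+λ₋ = k21+k23+k32), *not* the naive identifications
1/τ_short = k21, 1/τ_long = k32 (those hold only when k23 ≪ k21).
`RateSet.from_dwell_constants` therefore inverts the spectrum exactly:
given (τ_short, τ_long) and the long/short event-count ratio n it
solves for (k21, k23, k32) so that a simulation reproduces the measured
mixture constants exactly.  The naive rule is kept as `method="naive"`
for comparison.  The count ratio is not reported per force; the default
n = 1 matches the constrained-fit relation k23 = k21 and makes 5 pN
folded-dominant (stationary folded fraction 0.60) and 7 pN
unfolded-dominant (0.09), as observed qualitatively.

**Calibrated conditions** (in `presets.py`): dwell constants
(τ_u, τ_short, τ_long) = (15.8, 3.0, 45) s at 5 pN, (53, 2.1, 25) s at
6 pN, (101, 3.2, 16.6) s at 7 pN; ramp-unfolding Bell edge
(k0, x‡) = (0.009 s⁻¹, 0.8 nm) at r = 2 pN/s; folding Bell law
k12: (3.3 s⁻¹, −3.0 nm) with 3.3 the geometric midpoint of the reported
1.6–6.7 s⁻¹ confidence range; long-state unfolding k32:
(0.037 s⁻¹, +0.2 nm).  The non-monotone τ_short sequence across forces
(3.0, 2.1, 3.2 s) is experimental scatter and is used as printed.

**UL parametrization** (phenomenological, config-exposed): entry
S → UL at 2·10⁻⁴ s⁻¹ with dx = 0 — the order of magnitude implied by
~6 occurrences in 15 holds of 1–4 h; rupture UL → U with
k0 = 10⁻⁷ s⁻¹, dx = 1.5 nm, calibrated against the closed-form modal
rupture force so a 2 pN/s ramp peaks at 42.9 pN and 1000-s survival at
5–7 pN exceeds 99 %.  Within hold times ≤ 120 s UL occupancy stays
below 0.5 %, so it is excluded from the 3-state p_fold fitting model.

**Master equation.**  Fixed-step classical RK4 (default dt = 0.01 s)
with a probability-conservation check (|Σp − 1| < 10⁻⁸ at every output
time) and automatic step halving on violation.  The p_fold *fit*
evaluates occupancies through an exact eigen-decomposition of the 3×3
generator for speed; tests pin it to the RK4 solver at 10⁻⁷.

**Stochastic simulation.**  Exact SSA under clamps.  Under ramps the
force is frozen over adaptive sub-steps chosen so (total exit
rate)·Δt < 0.05 and Δf ≤ 0.2 pN per step; rupture-force synthesis for
fitting uses exact inverse-CDF sampling of the Bell–Evans density
instead.

## Synthetic recordings

extension(t) = baseline + [unfolded]·step_size(f(t)) + Gaussian noise,
at 200 Hz with σ = 2 nm per sample (the instrument's bead-tracking
resolution), baseline 0 (tether/handle elasticity is not modelled —
the analysis uses extension changes only).  A per-trace force-scale
bias with CV 10 % models the magnet calibration error; it multiplies
the true force seen by the polymer models and the Bell rates (inert for
clamp simulations calibrated at the nominal force, where edges carry
dx = 0).  An optional one-pole low-pass noise mode mimics correlated
bead tracking; it is off by default so detector statistics are exact.
A `decimated(k)` acquisition divides the rate by k and the noise by
√k (block averaging); the test suite uses 20 Hz decimation, the
acceptance script the full 200 Hz.

What the generator does *not* emulate: camera blur/aliasing, bead
rotation, nonlinear drift, handle unwinding, and multi-tether
artifacts.  Passing recovery tests therefore demonstrates correctness
of the inference chain under the stated noise model, not robustness to
every instrumental pathology.

## Step detection and dwell statistics

The detector is a windowed penalized-least-squares change-point search:
a matched boxcar-difference filter (half-window = the dead time) scans
for candidate transitions, each candidate is refined to the exact local
L2-optimal split and accepted when the local cost reduction exceeds
penalty = 3·σ̂²·ln n (σ̂ from the median absolute successive
difference), then adjacent segments closer than min_step = 3 nm in
level are merged and the surviving levels are classified by weighted
1-d 2-means (lower level = folded).  A plain recursive binary
segmentation was rejected because single-split recursion is blind to
brief dwells inside long segments.  An optional Theil–Sen detrend
(default on) makes the output invariant to offsets and slow drift.

Dwells below min_dwell (default 2× the 0.1 s window) are merged into
their neighbours — the detector's dead time t_d.  The MLE accounts for
it twice over: (i) all dwell likelihoods are left-truncated at t_d
(memorylessness makes the 1-component censored MLE closed-form:
τ̂ = Σ(t−t_d)/n_uncensored including censored mass); (ii) a missed
opposite-class dwell fuses its two neighbours, inflating the apparent
lifetime by 1/(1−q), q = opposite-class probability mass below t_d —
the first-order correction τ̂·(1−q̂) is applied to the unfolded and
long-folded lifetimes with q̂ taken from the fitted mixture.  With
these corrections the full chain is unbiased to ~1 % at the study's
sample sizes (checked against ground-truth state paths).

Right-censored dwells (trace boundaries) enter as survival terms by
default; a drop-censored mode reproduces naive analysis.  The
two-component mixture is fitted by direct Nelder–Mead on
(ln λ₁, ln λ₂, logit A) from 5 starting points; standard errors come
from the numerical observed-information matrix.  Model selection
(1 vs 2 components) uses ΔBIC > 2, with an underpowered guard below 20
uncensored dwells.  At n ≈ 684 folded dwells the intrinsic sampling
spread of the short mixture lifetime is ~9 % — parameter recovery
tests use 3-SE tolerances for this reason.

## Rupture-force and Bell fits

The rupture fit maximizes the exact Bell–Evans likelihood; k0 has a
closed-form profile given x‡, leaving a robust 1-d bounded search over
ln x‡.  Bell fits are weighted linear regressions of ln k on f
(weights (k/se)²), giving x‡ = slope·kBT and a 95 % CI on k0 from the
intercept.  The p_fold fit minimizes the binomial negative
log-likelihood of (M, N) outcomes over (k12, k32) under the constraint
k23 = k21 = α·k32 (α = 10 by default; fits move ~10 % when α is halved
or doubled, so the constraint choice does not drive conclusions), via
a 15×15 log-spaced grid plus Nelder–Mead refinement; a parallel
topology (competing direct folds U → S, U → L with the same reverse
rates) is provided for model comparison and loses to the sequential
scheme on sequentially generated data.

## Problem sizes

The acceptance script simulates at 200 Hz until ~683 true folding
events at 5 pN (~7.5 h of trace) and ~200 unfolded dwells at 7 pN
(~6 h), then runs the full detection and fitting chain (≈5 s on one
CPU); Bell and rupture recoveries average 200 and 100 seeded
replicates.  The test suite runs the same chains on 20 Hz decimated
recordings with identical event counts.

## Known limitations

* The ssDNA default is an idealized chain; zero-force energies inherit
  its low-force behaviour (see above).  Supply a tabulated empirical
  curve for quantitative ΔG0 work.
* The UL state is a phenomenological two-parameter description, not a
  mechanistic model; nothing is claimed about its structure.
* Dead-time corrections are first order; they break down when dwell
  scales approach the detector window (ratios ≲ 5).
* The detector assumes two extension levels per clamp segment;
  multi-level ladders and hidden-Markov emission models are out of
  scope.
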
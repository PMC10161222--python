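# Methods

## Correlation model

The package models the normalized autocorrelation of confocal
fluorescence fluctuations as

    G(τ) = 1 + (1/N) · T(τ) · Σᵢ fᵢ · gᵢ(τ)
    T(τ)  = 1 + F/(1−F) · exp(−τ/τ_T)
    gᵢ(τ) = (1 + τ/τ_D,i)⁻¹ · (1 + τ/(s² τ_D,i))⁻¹ᐟ²

with N the mean number of molecules in the effective observation volume,
F ∈ [0, 1) the stationary triplet (dark-state) fraction, τ_T the triplet
relaxation time, s = z₀/w₀ the structure parameter and τ_D,i = w₀²/4Dᵢ
the diffusion time of component i (Σ fᵢ = 1, one or two components).
Assumptions: free 3D diffusion, a 3D-Gaussian detection profile,
ideal detectors (no afterpulsing or dead time) and a triplet term that
factorizes from diffusion (valid for τ_T ≪ τ_D; the parameter
constructor warns when this ordering is violated).

Two conventions in this family vary between instrument vendors: the
baseline (G → 1 here, held in the module constant `BASELINE`) and the
(1−F)-normalized triplet amplitude (used here, so that
G(0⁺) − 1 = (1/N)/(1−F)).  Both are isolated in `evaluate_model` so an
alternative convention is a one-line change.

The weighted diffusion time is the fraction-weighted arithmetic mean
τ_w = Σᵢ fᵢ τ_D,i — the simplest summary of "average aggregate size"
when a curve mixes a fast (monomer/free dye) and a slow (aggregate)
component.  A brightness-weighted mean would up-weight large aggregates;
it is deliberately not the default because the component fractions of
the correlation amplitude are already brightness²-weighted.

Volume calibration uses the standard relations w₀ = √(4 D_ref τ_D,ref),
z₀ = s·w₀ and V_eff = π³ᐟ² w₀² z₀ with a reference dye of known
diffusion coefficient (rhodamine 6G 414 µm²/s; ATTO488 400 µm²/s; Cy5
360 µm²/s).  The structure parameter determined from the dye fit is held
fixed in all sample fits.

## Correlator

The estimator is G(τ) = ⟨F(t)F(t+τ)⟩ / (⟨F⟩⟨F⟩) with all means taken
over the shifted overlap of the two windows ("symmetric normalization"),
which removes the first-order bias from slow intensity drift and
bleaching.  Cross-correlations average the two lag directions, making
the result exactly invariant to channel order.  The lag grid is the
multi-tau scheme of hardware correlators: 16 linear lags at the raw bin
width, then repeated bin-doubling stages contributing 8 lags each; the
grid stops when the coarsened trace is shorter than twice the longest
stage lag.  A brute-force direct estimator over explicit integer lags is
retained as the reference implementation; on smooth correlations the two
agree to well under 1% at shared lags (the coarsened estimate is a
triangular average over ±1 coarse bin around the lag, a second-order
effect when the stage spacing is small against the decay).

Per-lag standard errors come from splitting the trace into 10 contiguous
segments, correlating each on the same (prefix) lag grid, and taking the
standard error across segments.  Lags too long for a segment get NaN
errors; fits fall back to unweighted residuals when the error vector is
incomplete.  A constant-zero channel is rejected (undefined
normalization); NaN amplitudes are tolerated in curve containers as
missing-data markers and excluded by the series fitter.

## Fitting

Levenberg–Marquardt (lmfit/MINPACK, xtol = ftol = 1e-12) on residuals
(model − G), weighted by 1/se when a complete positive error vector is
present.  Start values come from the curve itself: N from the short-lag
amplitude, diffusion times from the lag at half-decay (split ×/÷ 4 for
two components).  Default bounds: N ∈ (1e-3, 1e5), τ_D ∈ (half the
shortest lag, 10 s), F ∈ [0, 0.5], τ_T ∈ (0.1, 50) µs — the triplet
bounds reflect organic-dye photophysics.  Both diffusion times are free
by default (no monomer-time pinning).  Two-component results are
canonicalized to ascending τ_D, so "first/second component" is well
defined; a fitted time ratio τ_D1/τ_D2 > 0.5 triggers an
ill-conditioning warning.  Non-convergence sets a flag on the result and
is never silent.

Repeated measurements (the screening design is 30 consecutive 10 s
recordings per time point; FRET-FCS uses 10 × 20 s) are summarized by
the median and 25–75 quartiles of count rate and τ_w, using numpy's
linear-interpolation quantile convention.  Failed fits are excluded and
counted, never imputed; a time point where every repeat fails raises an
error naming the time point.

## Simulator

`simulate_trace` is a minimal physical model of the instrument: point
emitters perform Brownian motion with per-bin Gaussian displacements of
std √(2DΔt) per axis in a periodic box (default 10× the observation
radii per edge, warning below that), the detection profile is
exp(−2(x²+y²)/w₀² − 2z²/z₀²), and each channel draws Poisson counts
around Δt·(background + Σ particles brightness·profile).  Channels share
particle positions, so a species bright in two channels produces real
cross-correlation — the operational surrogate for FRET-positive
co-assembled oligomers (FRET is modeled at species level as an
acceptor-channel brightness, not at photon-physics level).  Optional
triplet blinking is a two-state Markov chain per particle with the
stationary dark fraction and relaxation time of the model's triplet
term; while a particle is outside the detection region the state is
re-drawn from its stationary distribution.

Species concentration is specified as mean occupancy of V_eff, the same
N an FCS fit reports; the simulator draws the box population from the
corresponding Poisson distribution.  The expected count rate has the
closed form background + Σ N_eff·ε·2⁻³ᐟ² (box-size corrections via erf
are applied in `expected_count_rate`).

Performance: particles far from the observation volume (normalized
ellipsoidal radius u² > 9, where the profile is < 2e-8) are propagated
in single multi-bin Gaussian jumps sized so that reaching the emitting
region mid-jump would be a >4σ event per axis; this is exact for the
detected signal up to that truncation and makes second-scale traces with
thousands of particles tractable.  The kernel is numba-compiled with a
pure-numpy fallback.  Determinism: every stochastic operation requires
an explicit seed (or Generator); identical seeds give bit-identical
output on a given platform.

What the simulator does *not* emulate: detector afterpulsing/dead time,
optical aberrations and refractive-index mismatch, photobleaching,
explicit aggregation kinetics (nucleation–elongation), and asynchronous
photon timestamps.  Passing tests therefore validate the analysis chain
against idealized-confocal ground truth, not against every artifact of
real recordings.

## Higher-level generators (study conditions)

Time-lapse aggregation uses a logistic growth fraction
θ(t) = 1/(1+exp(−r(t−t½))) (the data motivating this show a lag,
exponential growth and an equilibrium phase; no quantitative law is
published, so the logistic is a stand-in with free parameters).  ThT
intensity follows baseline + plateau·θ with defaults 200 + 2·10⁴
counts/s; the aggregate diffusion time ramps 0.3 → 5 ms on the same
sigmoid while the monomer component stays at 150 µs; the aggregate
amplitude fraction rises to 0.8.  Repeat-level count-rate scatter has a
10% coefficient of variation and curves carry 2% noise — the scatter of
repeated short FCS measurements is dominated by sample heterogeneity
rather than shot noise.  Defaults: 30 repeats × 10 s per time point.

Dose–response tables follow the descending four-parameter logistic
CPP(c) = bottom + (top−bottom)/(1+(c/IC50)^h) with defaults top 1.3,
bottom 0.2 (kcounts·s⁻¹·particle⁻¹ scale), h = 1, eight log-spaced
concentrations spanning 30-fold on each side of the IC50, three
replicates, and Gaussian noise proportional to the local curve value
(5% default).

## Classification rule

A compound's trajectory is compared with the control on the same time
grid (≥3 points).  Calls, in order:

1. **inhibition** — the treated median lies below the control's lower
   quantile (default: 25th percentile of the repeat values) at each of
   the last `endpoint_points` time points.  The default of 2 trailing
   points (rather than the endpoint alone) is a variance-reduction
   choice: with 30 repeats, a single median-vs-quartile comparison of
   *identical* conditions fails ~2% of the time by sampling noise alone;
   requiring two consecutive exceedances squares that rate without
   affecting genuinely suppressed trajectories.
2. **acceleration** — the treated trajectory reaches half of its total
   rise earlier than the control by more than one (configurable) grid
   spacing, with linear interpolation between time points.
3. **no_effect** otherwise.

All thresholds are heuristics exposed in `ClassificationConfig`, not
published values.

## Dose–response estimation

The 4PL is fitted with all four parameters free (Hill slope not pinned
to 1), IC50 parameterized as log₁₀ for stability, start values from the
extreme-concentration means and the half-range crossing.  An IC50
outside the tested range is flagged extrapolated; a range that does not
bracket IC50/10 … 10·IC50 warns about wide confidence intervals;
non-monotone concentration means beyond twice their joined standard
errors set a poor-fit flag without aborting.  Note on precision: with
eight concentrations, three replicates and 5% relative noise, the
intrinsic coefficient of variation of the free-4PL IC50 estimate is
8–9% (verified against an independent scipy implementation), so
single-experiment IC50s at this noise level carry ~10% uncertainty; the
noiseless fit is exact to numerical precision.

## Viability statistics

CV = 100·(total − dead)/total, with a warning below 2000 counted cells
(binomial error on CV then exceeds ~1 percentage point).  Condition
comparisons use Welch's unequal-variance two-sided t-test — robust to
variance heterogeneity between treatment groups — with n−1 standard
deviations and per-comparison (unadjusted) p-values.

## Problem sizes in tests

The test suite and acceptance script size their simulations to desk
scale: physics round-trips use 30–120 s traces at 26–130 µs binning
(≈30,000–60,000 diffusion times per trace, putting the τ_D estimator's
sampling error near 3%), occupancies of 1–5 (180–900 simulated box
particles; up to 9,000 for the occupancy-50 brightness check), and
classification accuracy is estimated over 20 seeds per scenario at the
default 30 repeats × 7 time points.
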
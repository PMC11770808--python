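# Methods

## Photon-by-photon hidden Markov model

The emitter is a two-state continuous-time Markov chain with generator `Q`
(rates `k_close`: open→closed, `k_open`: closed→open, both ~10⁴–10⁵ s⁻¹).
Photon arrival times are treated as exogenous; only the photon *colors*
(donor vs acceptor detection after donor excitation) are modeled, with
per-state acceptor probability equal to the state's FRET efficiency. This
is valid because the total donor-excitation photon rate is
state-independent in the generator (FRET reroutes photons between channels
without changing their number), so arrival times carry no extra state
information.

Time is discretized on the acquisition clock (default 25 ns, 40 MHz sync).
The hidden chain advances per tick with transition matrix
`A = expm(Q·Δt)`; a gap of `n` ticks between photons contributes the
propagator `Aⁿ`. The forward likelihood multiplies propagators and
per-photon emission weights, with the chain started from the stationary
distribution of `Q` at each burst (molecules enter the focus at
equilibrium; a free initial distribution is available behind a flag).

**EM.** The E-step computes, for every inter-photon gap, the expected
number of tick-level i→j transitions conditioned on the photon record. For
a gap of `n` ticks these are obtained exactly from the joint recurrence
`P[n] = P[n−1]A`, `G[n,i,j] = G[n−1,i,j]A + P[n−1]C_ij` with
`C_ij = e_i A_ij e_jᵀ`, tabulated once per iteration up to the longest gap.
Per photon pair only an endpoint-weight accumulation (O(N²)) is needed; the
O(N⁴) contraction with `G` happens once per distinct gap length. The M-step
renormalizes the expected tick-transition counts into a new `A` and maps it
back to rates via the matrix logarithm (closed form for two states). State
efficiencies are the expected acceptor fraction per state. Because the
burst-start distribution is tied to `Q`, this is a generalized EM; the
implementation verifies the likelihood never decreases and stops at the
previous iterate if an update would lower it (never observed at the scales
tested — the ~100 transition-bearing photons per burst dominate the single
start term).

Gaps longer than 2¹⁶ ticks (1.6 ms) are propagated with the capped power;
at the rates considered the chain is at stationarity far earlier, and burst
search guarantees intra-burst gaps orders of magnitude shorter.

**Initialization and convergence.** A deterministic grid — efficiency pairs
{(0.2,0.8),(0.3,0.7),(0.4,0.6)} × symmetric rate decades {10³,10⁴,10⁵} s⁻¹
— is short-run (20 iterations) on an evenly thinned subset of ≤1,000
bursts; the best candidate is iterated to convergence on all bursts.
Convergence is |Δloglik| < 10⁻⁶ per photon, at most 3,000 iterations.
Global fits across measurements pool the emission statistics (shared
efficiencies) while each measurement keeps its own rate matrix; a fixed-E
mode optimizes only the rates.

`K_C = P_closed/P_open` is reported from the stationary distribution of the
fitted `Q` (equal to `k_close/k_open` for two states); a Viterbi
dwell-fraction estimate is provided as a cross-check and agrees within ~10 %
when dynamics are resolvable.

**Resolution limits.** With donor-excitation rates of 2.5×10⁵ s⁻¹,
interconversion at 10⁵ s⁻¹ leaves ~2.5 photons per dwell; rate estimates
then degrade (tens of percent) while the efficiencies remain accurate. The
recovery suite spans 10⁴–10⁵ s⁻¹ and judges medians across that range.

## Validation procedures

*Recoloring* keeps every photon's arrival time, draws a fresh state path
from the fitted model per burst, and redraws colors from the state
efficiencies. The discrepancy score is the L2 distance between per-burst
mean-efficiency density histograms (Kolmogorov–Smirnov behind a flag),
calibrated against a null of model-vs-model recolorings with different
seeds. *Dwell-time analysis* fits maximum-likelihood exponential rates to
Viterbi dwells, placing transition times midway between the flanking
photons and excluding the first/last dwell of each burst: boundary dwells
are truncated by the burst envelope and, with this generator, including
them inflates the rate estimate. *Burst-variance analysis* compares the SD
of consecutive n-photon window efficiencies (default n = 5, ddof = 1,
bursts with ≥ 2 windows) with the static binomial envelope `sqrt(E(1−E)/n)`;
a time-resolved variant bins windows by duration.

## Synthetic photon data

Bursts are fixed-rate photon windows with exponentially distributed
durations (default mean 0.5 ms; a fixed-duration option exists) separated
by 10 ms gaps — burst-level statistics, not focal geometry, are what the
inference consumes. Pulsed-interleaved excitation is simulated at the label
level: donor-excitation photons at 2.5×10⁵ s⁻¹ split between channels by
the current state's efficiency, acceptor-excitation photons at 2.5×10⁵ s⁻¹
for stoichiometry. Default state efficiencies are 0.37 (open) and 0.72
(closed); 10,000 bursts emulate one measurement.

Contamination is generated additively so that the standard correction is
unbiased: leakage adds acceptor-channel photons at `l ×` the donor-channel
rate, direct excitation at `d ×` the acceptor-excitation rate. Then
`F_DA = N_DA − lN_DD − dN_AA` recovers the FRET photons in expectation and
corrected E equals the generator's E at γ = 1. Donor-only and acceptor-only
bursts (optional fractions) reproduce the E/S-histogram wings from which
`l = Ē/(1−Ē)` and `d = S̄/(1−S̄)` are estimated.

Not emulated: diffusion through a Gaussian focus (no brightness profile or
burst-duration/brightness correlation), triplet blinking and other dye
photophysics, background structure beyond uniform Poisson rates, and
nanotimes. Passing tests therefore demonstrate correctness of the inference
under the stated generative model, not robustness to those artifacts.

## Burst search and corrections

Inter-photon intervals are smoothed with a centered 15-photon moving mean
and thresholded at 5 µs; a burst is a maximal run of photons adjacent to a
passing interval, kept if it holds ≥ 50 photons. The centered window trims
up to ~7 photons at each burst edge — a deliberate trade for well-defined
boundaries. Timestamps are integer clock ticks; thresholds are converted by
round-half-up. The γ factor defaults to 1 (configurable); the dual-label
stoichiometry window defaults to (0.3, 0.8) and is recorded in the output.

## The 12-state turnover model

Species {E, ET, EM, ETMᵢ, EMTᵢ, ETM} × {open, closed}. Binding and
unbinding connect open states only (the closed active site is shielded);
association uses one shared rate constant `k_on` (default 10 µM⁻¹s⁻¹) with
`k_off = k_on·K_d`, placing binding in the rapid-equilibrium regime — the
steady state is insensitive to `k_on` well above turnover. Rearrangement
ETMᵢ→ETM (`k_r^T`) and EMTᵢ→ETM (`k_r^M`) is irreversible by default
(reversibility and ETM unbinding are flags); catalysis lumps
phosphotransfer and product release as ETM_closed→E_open at `k_cat`
(initial-velocity regime, no product rebinding). Both ternary binding steps
reuse the binary K_d (no cooperativity).

Steady state solves the null space of the generator's transpose, restricted
to the communicating class of the open apo state when zero concentrations
disconnect parts of the chain. The independent cross-check integrates
dp/dt = Gᵀp with a stiff solver (LSODA) from the apo start to ≥ 45
relaxation times of the slowest nonzero mode; linear solve and integration
agree to ~10⁻¹².

Default wild-type-like parameters: `k_cat = 2620 s⁻¹`, `k_r^T = 4880 s⁻¹`,
`k_r^M = 260 s⁻¹`; K_d(ATP)/K_d(AMP) = 159/332 µM (0 M urea), 170/522 µM
(0.4 M), 183/758 µM (0.8 M). Per-species conformational rates use a common
opening rate of 2×10⁴ s⁻¹ (microsecond dynamics, ~100× faster than
turnover) and closing rates set by the measured closed/open ratios: apo and
AMP-bound 0.16, ATP-bound 1.28, ternary species 1.65 at 0 M urea; 0.86 and
1.10 with 0.8 M urea (0.4 M interpolated linearly — only the affinities
were measured there). These rate tables are package defaults standing in
for per-condition measured tables, which the scheme accepts as
configuration; consequently the velocity *phenomenology* (substrate
inhibition, urea crossover, scaling invariance) is reproduced
quantitatively for these defaults, not for the study's exact curves.

Apparent opening/closing rates — what an ensemble smFRET measurement sees —
are occupancy-weighted means of the per-species rates over the closed
(respectively open) states.

## Global χ² fitting

Residuals are `(v_model − v_obs)/SEM` per point (per-point SEMs, the
default weighting). The three shared rate constants are fitted in log10
space (they span decades) with bounded trust-region least squares from 8
deterministic starts on a log grid; all starts are logged. Profile
confidence intervals re-optimize the nuisance rates on a grid around the
optimum and locate the Δχ² = 1 (68 %) or 3.84 (95 %) crossing by
interpolating on √Δχ², which is linear in the parameter for a quadratic
surface and keeps coarse grids accurate; grids extend automatically and an
uncrossed flank is reported as an open (one-sided) interval — the expected
outcome for `k_r^M` when the data show no substrate inhibition.

## Classical enzymology fits

The product-inhibited progress curve is `[P](t) = v₀(1−e^(−ηt))/η`
(exponential-saturation form; initial slope v₀, plateau v₀/η, linear limit
as η→0), fitted by nonlinear least squares with a numerically stable
`expm1` evaluation. Michaelis–Menten and the ligand-excess 1:1 isotherm
`f = L/(K_d+L)` use (optionally weighted) `curve_fit`; designs without
curvature or saturation are flagged rather than silently fitted.

## Problem sizes and determinism

Recovery suites use 10,000 bursts (~6·10⁵ donor-excitation photons) per
measurement for the HMM, 1,000 random schemes for the steady-state
cross-check, and 50 replicates for profile-interval coverage; these sizes
make the medians and coverage fractions statistically meaningful while
keeping a full run in minutes on one core. Every stochastic routine takes
an explicit seed (`numpy.random.default_rng`); identical seeds reproduce
identical photons, fits and reports.
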
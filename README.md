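# fretkin

Single-molecule FRET burst analysis with photon-by-photon hidden-Markov
inference, coupled to a conformationally gated kinetic model of adenylate
kinase (AK) turnover.

Adenylate kinase catalyzes ATP + AMP ⇌ 2 ADP while its LID domain opens and
closes over the active site on the microsecond time scale — two orders of
magnitude faster than turnover. Diffusion-based smFRET experiments on a
LID–CORE dye pair resolve these dynamics photon by photon: each burst of
photons from a molecule crossing the confocal volume carries the signature of
open (low FRET) and closed (high FRET) dwells. The balance between the two
conformations, together with the order of substrate binding, controls the
enzyme's velocity — including its hallmark substrate inhibition by AMP and
the counter-intuitive activation of the inhibited enzyme by sub-denaturing
urea. `fretkin` implements both halves of this analysis and the synthetic
data generators needed to exercise them end to end.

## What it computes

**smFRET side** (`synth`, `bursts`, `h2mm`, `hmm_validate`)

- Photon streams from two-state emitters (continuous-time Markov chain,
  pulsed-interleaved excitation labels, leakage/direct-excitation
  contamination, 40 MHz clock).
- Burst search by sliding-window inter-photon-time smoothing (15 photons,
  5 µs cut-off, ≥ 50 photons), raw FRET efficiency `E = N_DA/(N_DD+N_DA)`
  and stoichiometry `S`, correction factors from the donor-only and
  acceptor-only wings of the E/S histogram, and corrected efficiencies
  `E = F_DA/(γN_DD + F_DA)` with `F_DA = N_DA − lN_DD − dN_AA`.
- A two-state photon-by-photon HMM: per-tick propagator `A = exp(Q·Δt)`,
  forward likelihood over photon colors and arrival times, Baum–Welch EM
  with exact expected tick-transition counts for arbitrary inter-photon
  gaps, Viterbi state paths, global fits sharing the state efficiencies
  across measurements, and the closed/open occupancy ratio
  `K_C = P_closed/P_open = k_close/k_open`.
- Three consistency checks: recoloring (redraw photon colors from the
  fitted model at fixed arrival times), dwell-time analysis of the Viterbi
  paths (censored boundary dwells excluded), and burst-variance analysis
  against the shot-noise envelope `sqrt(E(1−E)/n)`.

**Kinetics side** (`kinscheme`, `kinfit`, `enzymo`)

- A 12-state model — six species (E, ET, EM, ETMᵢ, EMTᵢ, ETM) × {open,
  closed} — in which binding and the rearrangement of a mis-posed ternary
  complex (rate `k_r`, pathway-dependent) occur only in the open
  conformation and phosphotransfer (`k_cat`) proceeds from the closed ETM.
  Steady-state occupancies come from the generator's null space (checked
  against stiff ODE integration); velocity is `v = k_cat·p(ETM_closed)`.
  Substrate inhibition by AMP emerges when the "AMP first" rearrangement is
  slow (`k_r^M ≪ k_cat`).
- Scans isolating the mechanism: common/unequal scaling of the
  conformational rates of ATP-bound species, urea-effect isolation
  (affinity-only vs dynamics-only hybrids), pathway fluxes, and the
  closed/open ratio that maximizes turnover at physiological nucleotide
  levels.
- Global χ² fitting of {k_cat, k_r^T, k_r^M} across urea concentrations
  (per-urea Kd and conformational rates fixed from experiment-like inputs),
  with profile-likelihood confidence intervals; progress-curve extraction
  of (v₀, η) from `[P](t) = v₀(1−e^(−ηt))/η`, Michaelis–Menten and 1:1
  binding fits.

## Worked example

```bash
fretkin demo --seed 1
```

runs the full synthetic pipeline (4,000 simulated bursts at E_open = 0.37,
E_closed = 0.72, symmetric 4×10⁴ s⁻¹ interconversion; velocity datasets at
three urea levels with 5 % noise) and prints a machine-readable report. With
seed 1:

```
"h2mm": {
  "E_open": 0.3704,  "E_closed": 0.7135,
  "k_close_rel_err": 0.074,  "k_open_rel_err": 0.106,
  "K_C": 1.035
},
"validation": {
  "recolor_distance": 0.050,  "recolor_null_95": 0.081,
  "bva_mean_sd": 0.246,       "bva_mean_envelope": 0.220
},
"kinetics": {
  "chi2_red": 1.000,
  "k_cat_rel_err": 0.0021, "k_r_T_rel_err": 0.0016, "k_r_M_rel_err": 0.0005
}
```

Reading this: the HMM refit recovers both state efficiencies to better than
0.01 and the microsecond rates to ~10 %, so `K_C ≈ 1.04` against a true
value of 1. The recoloring distance sits inside its self-consistency null
band, and the burst-variance SD (0.246) exceeds the static shot-noise
envelope (0.220) — the signature of genuine within-burst dynamics. The
global kinetic fit recovers the three shared rate constants to a fraction of
a percent with χ²_red ≈ 1.

The kinetic model alone is available from the shell, e.g. the AMP-dependent
velocity at 1 mM ATP (non-monotonic — substrate inhibition):

```bash
fretkin kinetics --urea 0.0 --amp-min-um 50 --amp-max-um 10000 --n-points 8
```

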
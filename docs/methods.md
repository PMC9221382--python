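# Methods

## Forward model

A cell-covered microelectrode is modeled per unit area (specific impedances,
Ω·cm²):

- Naked electrode: constant-phase element `Z_n = 1/(Q(iω)^β)`. β is
  restricted to (0.8, 1]; β = 1 recovers an ideal capacitance.
- Cell membranes: apical and basal capacitances in series,
  `Z_m = 2/(iω·Cm)` with Cm in µF/cm².
- Current constriction in the cell–substrate gap: `g = α·√(1/Z_n + 1/Z_m)`
  with the covered-patch admittance

  `1/Z_c = (1/Z_n)·[ Z_n/(Z_n+Z_m) + (Z_m/(Z_n+Z_m)) / ((g/2)·I₀(g)/I₁(g) + Rb·(1/Z_n+1/Z_m)) ]`.

- Partial coverage φ ∈ [0, 1] mixes admittances affinely:
  `1/Z_mix = φ/Z_c + (1−φ)/Z_n`.
- Node impedance: `Z = R_f + Z_mix/A`, with series media/lead resistance
  R_f (Ω) and total electrode area A (cm²).

α = r_c·√(ρ/h) bundles cell radius, medium resistivity and sub-cellular gap
height; only α itself is identifiable, so its constituents are never
estimated separately.

### Numerical choices

- The Bessel ratio `(g/2)·I₀(g)/I₁(g)` is computed with exponentially scaled
  Bessel functions (`scipy.special.ive`), whose shared exponential factor
  cancels, so the term stays finite for arbitrarily large complex g. For
  |g| < 1e−6 the series limit `1 + g²/8` is used to avoid 0/0.
- The forward model was verified against a 50-digit arbitrary-precision
  re-implementation (mpmath) to ≲1e−8 relative error over a 27-point
  (Rb, α, Cm) grid; the test suite pins this.

## Default electrode

One node comprises ten 250-µm-diameter electrodes: A = 10·π·(125 µm)² =
4.9087e−3 cm². The shipped cell-free model uses R_f = 300 Ω and β = 0.95,
with the CPE magnitude Q calibrated in closed form
(`Q = ω^−β·cos(βπ/2)/((R1K_free − R_f)·A)` at ω = 2π·1000) so the node-level
Re Z(1 kHz) equals 1200 Ω — the cell-free resistance level that damage
trajectories decay toward. `calibrate_naked` refits (R_f, Q, β) to a measured
naked spectrum and flags fits whose residual is large, whose β pins at 1, or
whose CPE contributes negligibly (purely resistive data, Q and β
unidentifiable).

## Surrogates

Real-time monitoring uses two scalars per sample: R(1K) = Re Z(1 kHz),
sensitive to the tight-junction resistance, and C(64K) = −1/(ω·Im Z) at
64 kHz in nF, sensitive to electrode coverage. The 64-kHz reactance must be
capacitive; inductive readings are rejected as sensor faults.

## Inversion

`GKInverter` minimizes complex-log residuals (log-magnitude and phase jointly)
over (Rb, α, Cm) with bounded least squares from Latin-hypercube starts drawn
in log space, because the parameters span decades and a single basin of
attraction cannot be assumed; reserve starts beyond `n_starts` are spent only
while the best residual stays far above machine noise. Coverage is fixed at 1
by default since Rb → 0 and φ < 1 are mutually confounded. Diagnostics:
`cell_free_` (fit indistinguishable from the naked electrode; boundary result
Rb = α = 0 returned), and `plateau_warning_` (mid-band 0.5–10 kHz impedance
within 10% of the naked level, leaving Rb weakly identified). The spectrum
must span ≥ 2 decades with ≥ 5 frequencies.

## Damage-trajectory analysis

Surrogate traces are epoch-sampled (default every 10 RD cycles). Two
segmentation methods estimate the Phase-1 length N_P1:

- **Joint fit** (default): for each candidate epoch boundary, a plateau plus
  a continuous exponential departure is least-squares fitted; the boundary
  minimizing the SSE wins. A changepoint is only declared when the
  constant-model SSE exceeds the best two-phase SSE by a factor ≥ 2,
  otherwise the trace is flagged `no_phase2`.
- **Threshold**: baseline = median of the first three epochs; N_P1 is the
  first sample deviating > 5% from baseline for two consecutive epochs.

Phase 2 is fitted as `R(N) = R0·exp(−λ(N−N_P1)) + R_F` by bounded nonlinear
least squares (λ, R0, R_F ≥ 0), initialized from the trace tail and a
log-linear regression slope. Fits with r² below threshold or non-decaying
tails are flagged. The fitter matches a dense brute-force λ grid search
(step 1e−4) within one grid step on noisy instances (pinned by tests).

## Case-level statistics

Per-node (N_P1, λ, Rb_init) values are aggregated per culture condition with
sample standard deviations (n−1). Pairwise comparisons use two-tailed
t-tests — paired by node index where counts match, Welch otherwise — with
optional Benjamini–Hochberg adjustment; degenerate zero-variance cases return
limit p-values with warnings. The resilience threshold is the midpoint x0 of
a three-parameter logistic `N_P1(x) = N_max/(1 + exp(−(x−x0)/k))` fitted to
N_P1 against Rb_init, with k estimated in log space and the midpoint
initialized at the largest jump of the sorted response.

## Interfacial stress metrics

For an air–liquid interface of radius R moving at speed U in a medium of
viscosity µ and surface tension γ: Laplace pressure drop ΔP = γ/R, capillary
number Ca = µU/γ (inputs in mN/m, mm, mPa·s, mm/s are converted to SI
internally), and the RD cycle period 2L/U for a sweep amplitude L. At the
default protocol values (γ = 70 mN/m, R = 0.175 mm, µ = 1 mPa·s,
U = 0.5 mm/s, L = 50 mm) these evaluate to ΔP = 400 Pa, Ca = 7.1e−6, and a
200 s period; the computed period follows directly from 2L/U for the stated
protocol.

## Synthetic-data generator

Two tiers, all randomness derived from `SeedSequence((seed, node_id))`
substreams so adding nodes never perturbs existing ones:

- **Phenomenological** (`make_phenomenological_traces`,
  `simulate_case_cohort`): surrogate traces built directly from the two-phase
  law — plateau 8020 Ω, changepoint 208 cycles (cohorts: Normal draws snapped
  to the epoch grid), decay λ = 0.0107/cycle toward R_F = 1200 Ω — with
  multiplicative Gaussian noise (default CV 3%). This tier defines the decay
  of R(1K) itself, so recovered λ is directly comparable to the generating
  value.
- **Mechanistic** (`simulate_rd_experiment`, `simulate_culture`): full
  spectra from the GK forward model. Phase 1 declines Rb linearly from
  `rb_init` (default 10 Ω·cm²) while α rises (defaults α_init = 6,
  `alpha_rise_frac` = 1), a compensation that keeps R(1K) near-flat and
  C(64K) stable through Phase 1; Phase 2 sets Rb = 0 and decays coverage
  exponentially. Culture growth uses logistic coverage and Rb with
  half-times inversely proportional to seeding density. Node heterogeneity
  is a uniform ±10% multiplier.

The generator emulates surrogate-level damage phenomenology and
spectrum-level trends; it does not model electrode drift, medium evaporation,
temperature transients, cell migration/re-healing after injury, or
frequency-correlated noise (noise is independent across frequencies and
epochs).

## Limitations

- The GK model assumes a laterally homogeneous confluent layer; partial
  coverage is only an affine admittance mixture, not a spatial model.
- λ and N_P1 from the mechanistic tier depend on the assumed Phase-1
  compensation; only the phenomenological tier guarantees that the generating
  decay constant is the decay constant of R(1K).
- Paired t-tests assume node-index pairing is meaningful across cases; with
  few nodes per case (typically 7) all p-values are low-powered.
- The sigmoid threshold fit is unreliable when all observed Rb_init lie on
  one side of the midpoint; such fits are flagged degenerate rather than
  rejected.
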
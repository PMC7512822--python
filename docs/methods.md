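# Methods

## The model

`sigtherm` analyzes a strictly linear signal-transduction cascade of `n`
signaling species `X_m1 … X_mn` (cascade label `m`).  The extracellular
ligand `X_m1` activates the receptor `X_m2` into its phosphorylated form
`X_m2*`; each activated species then activates the next one, and a constant
phosphatase pool deactivates it.  For each step `j = 2 … n`:

    driver_j + X_mj + ATP  →  driver_j + X_mj* + ADP      rate k_m,j−1
    Ph_m,j−1 + X_mj*       →  Ph_m,j−1 + X_mj + Pi        rate k_−m,j−1

with `driver_j = X_m,j−1*` except for the receptor step, which is driven
by the ligand `X_m1` itself.  ATP, ADP, Pi and the phosphatases are
chemostatted: held at fixed concentration, providing the thermodynamic
drive.  Because every reaction leaves `X_mj + X_mj*` unchanged for each j,
total signaling material `X = Σ_j (X_mj + X_mj*)` is conserved exactly
along every trajectory — within 1e−9 for the ODE path and identically for
the integer-copy stochastic path.

Phosphatase concentrations appear once per reaction pair, so
`phosphatase_levels` has length `n − 1`, aligned with the rate lists;
the initial-concentration lists have length `n`.

### Kinetics

Two simulators share one `ReactionNetwork`:

* **Stochastic** — Gillespie's direct method over integer copy numbers,
  exact (no tau-leaping).  A volume parameter Ω converts the bimolecular
  activation rate into a propensity `k·[ATP]·N_driver·N_substrate/Ω`.
  Identical seeds give identical trajectories event for event.
* **Deterministic** — mass-action ODEs integrated with LSODA at
  rtol 1e−10.  The rate laws divide bimolecular terms by the same Ω, so the
  ODE is the large-volume limit of the SSA *in the same units*; with the
  default Ω = 1 the state is an ordinary concentration vector.

The ligand stimulus is sustained by default; a finite pulse
(onset, duration) reproduces the transient rise-and-decay time course of
each activated species.  The pulse is implemented as a {0,1} time gate
multiplying the receptor-activation propensity rather than as a forced
ligand waveform, so molecule conservation survives.  The SSA handles the
piecewise-constant propensity exactly by advancing to the next gate switch
whenever the drawn waiting time would overshoot it (valid because the
exponential clock is memoryless); the ODE integrates each gate segment
separately so the discontinuity never degrades error control.

### Step durations

The signed durations of step j are read off the time course of `X_mj*`:
the forward duration `τ_mj > 0` runs from the onset of the concentration
rise to the peak, the backward duration `τ_−mj < 0` is minus the time from
the peak back to the steady band.  Onset and return are crossings of the
threshold `steady + max(band, rise_fraction · peak excess)`, with
`band = band_frac · steady`.  Defaults: `rise_fraction = 0.05`,
`band_frac = 0.02`.  Crossing times are linearly interpolated between
samples, making the extraction accurate to the grid resolution, and the
whole procedure is invariant to shifting all timestamps.  Stochastic
trajectories are smoothed with a moving average (default 11 events) before
crossing detection, because a raw jump path re-crosses any level
arbitrarily often in its vicinity.  Thresholds are explicit parameters
precisely so that τ is reproducible.

### Maximum-entropy coding

A configuration assigns each of the `X` molecules to one of the 2n species
states; the number of distinguishable signal events is the multinomial
coefficient `Ψ = X!/∏_j X_mj!·X_mj*!`, computed exactly through
log-gamma.  By first-order Stirling, `log Ψ ≈ S = −X Σ (p log p + p* log p*)`
with occurrence probabilities `p_mj = X_mj/X`.  Maximizing S subject to

1. normalization `Σ_j (p_mj + p_mj*) = 1` (joint over all steps), and
2. fixed total duration `τ_m = X Σ_j (p_mj τ_mj − p_mj* τ_−mj)`

gives the exponential assignment `−log p_mj = β τ_mj`,
`−log p_mj* = −β τ_−mj`, with a *single* multiplier β shared by every step
and normalization multiplier `α = −X`.  β solves
`Σ_j e^{−βτ_mj} + Σ_j e^{βτ_−mj} = 1`, whose left side is strictly
decreasing in β (from `2n − 1` down to −1, so a positive root exists
whenever `2n > 1`); the solver brackets geometrically and uses Brent's
method, verifying the residual is below 1e−12.

`maxent_numeric` maximizes the same entropy by direct constrained
optimization (SLSQP over log-probabilities, which enforces positivity;
analytic gradients and constraint Jacobians).  Its multipliers are
recovered from the stationarity conditions of the converged point by
linear least squares.  The numeric and analytic routes agree componentwise
to better than 1e−6 and serve as mutual checks; neither is derived from
the other.

Two genuinely open design points were resolved as follows.  The joint
normalization over all 2n states (rather than per step) is adopted as the
primary convention; all downstream identities are stated for it.  And `X`
is treated as a fixed constraint, not a free optimization variable: the
stationarity condition in `X` then holds automatically at the optimum
(it reduces to `S/X = β τ_m/X`), so it is a consistency identity rather
than an extra equation.

### Entropy production and the conservation claim

Per-step average entropy production rates (AEPR) are reported as
magnitudes: forward `−log p_mj / τ_mj` and backward `log p_mj* / τ_−mj`,
both positive for probabilities in (0,1) under the sign convention
`τ > 0 > τ_−`.  Folding the forward/backward sign bookkeeping into
magnitudes keeps the physically meaningful statement sharp: **at the
coding optimum every one of the 2n per-step AEPR values equals β**, so the
AEPR is conserved along the whole cascade.  Conservation is quantified as
the relative max−min spread over the 2n values — not a hypothesis test —
with default tolerance 1e−6 for analytic inputs (the maxent pipeline
achieves ~1e−16) and a Monte-Carlo criterion for simulated inputs.  The
comparison is inclusive at the boundary.  Random probability assignments
whose `−log p/τ` ratios differ by ≥10% always fail the test at rel_tol
1e−3 (the negative-control generator rejection-samples to guarantee that
spread).

Consequences of the exponential assignment, all verified to 1e−9:
`S = β τ_m`; per-step entropy production `S_mj = τ_mj ⟨ζ⟩ = −log p_mj`;
and channel capacity `C = K ⟨ζ⟩ = K S_m/τ_m` — information per unit time
equals the conserved AEPR up to the unit constant K (1 for nats/time,
log₂e for bits/time; K only rescales reported information, never internal
arithmetic, and all internal logarithms are natural).

`fit_beta` solves the inverse problem: the least-squares slope through the
origin of `−log p_mj` against `τ_mj`, plus the maximum relative residual.
On maxent-generated probabilities it recovers β to 1e−9; under 1%
multiplicative noise on the probabilities (n = 10) the mean relative error
is ≈0.1–0.3%, comfortably inside the noise level; non-exponential
assignments give residuals well above 0.05.

### Trajectory estimator of entropy production

The step affinity at a state is the log-flux ratio
`log(f_j/b_j) = log[k_j · driver · X_mj · ATP / (k_−j · Ph · X_mj*)]`,
zero exactly at detailed balance (the `detailed_balance_residual`
operation).  The finite-window trajectory AEPR is:

* deterministic — the trapezoid time average of
  `σ(t) = (f − b)·log(f/b) ≥ 0`;
* stochastic — the summed per-jump log-propensity ratios
  `Σ log[a_μ(x)/a_μ̃(x′)] / T`, where μ̃ is the partner reaction of the
  activation/deactivation pair.

The underlying theory equates a log-ratio of transition probabilities with
a time-averaged production rate in an infinite-time limit; the package
exposes finite-window estimates with a block standard error (the window
split into contiguous blocks, default 100) instead of pretending the limit
is attained.  One structural fact matters for interpretation: this linear
cascade has **no reaction cycles**, so every exactly stationary state is
flux-balanced step by step (`f_j = b_j` for all j) and is therefore a
detailed-balance state — the closed-form stationary entropy production
rate of the two-state chain is exactly zero, and the stochastic estimator
(whose stationary expectation vanishes for a reversible chain) agrees with
it within its standard error.  Positive entropy production appears only
under driving, i.e. during transients; the deterministic estimator is
validated there against direct quadrature of the closed-form two-state
relaxation (relative agreement ~1e−3 on a 2000-point grid).  The estimator
diverges if a flux vanishes inside the window (e.g. windows starting at
`X* = 0`); such windows are rejected with an explicit error.

### Synthetic cascades

`make_cascade` inverts the coding layer: durations are drawn uniformly on
[0.5, 1.5]·scale (backward negated) and rescaled by the exact factor
`β₀/β_true` — legitimate because the normalization condition is invariant
under `τ → cτ, β → β/c` — so the emitted profile's β equals `beta_true` to
1e−9.  Kinetic rates then follow a heuristic: deactivation rates from the
backward-duration magnitudes (`k₋·Ph ≈ 1/|τ₋|`) and activation rates from
the quasi-steady balance so each step's steady active:inactive ratio
approximates `p*:p` with the upstream driver at its own quasi-steady
level.  Total signaling material defaults to X = 100 concentration units,
all molecules initially inactive and distributed over steps in proportion
to `p + p*`.  Inverting the full transient kinetics for prescribed τ is
ill-posed, so fixture rates target occupancies, not exact durations; the
end-to-end check accordingly tests the *pipeline* (simulate → extract →
maxent → conserve), whose conservation outcome is a property of whatever
durations are measured, not of the fixture's target values.

What the generator does **not** emulate: receptor-level saturation
(Michaelis–Menten), branching or converging topologies, extrinsic noise,
spatial gradients, and any fitted kinetic parameters of real MAPK
cascades.  Passing tests therefore demonstrate the internal consistency of
the kinetics–coding–thermodynamics chain under elementary mass action, not
agreement with measured signaling data.

## Problem sizes

Default test and verification sizes: cascades of n ≤ 10; deterministic
grids of 200–8000 points; SSA ensembles of 40–100 replicates at volumes up
to 10³ (≈1500 copies, ~10⁴ events per run); 100-seed Monte-Carlo loops for
recovery and control studies.  The end-to-end check uses n = 5 with a
ligand pulse of onset 0.5 and duration 2 on a 4000-point grid to t = 120,
long enough for every downstream species to return to baseline.

## Known limitations

* First-order Stirling entropy overshoots the exact log-multinomial by
  `(1/2)[Σ_j log(2πX_mj) − log(2πX)]`: about 6% of S at X = 100 for a
  four-species occupancy and ~0.9% at X = 1000.  The package reports the
  first-order Stirling entropy deliberately (it is the quantity whose
  maximization defines the coding optimum); the exact counter is available
  alongside for any X where the distinction matters.
* The trajectory AEPR estimator is one admissible reading of the
  infinite-time transition-probability ratio; it is cross-validated
  against the probability-based estimator rather than asserted unique.
* The multi-cascade label m is carried as metadata only; cross-cascade
  comparisons are left to the caller.
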
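# Methods

This note documents the model, the numerical choices and the design
decisions behind `fermsense`, and states what the synthetic campaigns do
and do not establish about real plant data.

## Process model

The fed-batch broth is described by six balance equations (see the
README for the full system): biomass growth, substrate consumption,
enzyme production with first-order degradation, dissolved-oxygen
transfer/uptake, hydrogen-ion bookkeeping, and volume accumulation from
the four feed streams. Dilution enters every concentration state as
−(x_j/V)·Σ a_ji u_i with a 6×4 coefficient matrix `A` defaulting to all
ones, in which case the dilution driver equals dV/dt exactly.

Two printed variants of the substrate inflow term (S_C/V and S_C·V) are
both dimensionally inconsistent for a feed of concentration S_C at rate
u₁; the implementation defaults to the mass-consistent S_C·u₁/V and
keeps the literal variants behind `ModelConfig.substrate_inflow` for
comparison. The phosphate/antifoam coefficients K_M, K_A in the enzyme
equation are signed (default +, set negative for true inhibition), and
the corresponding inflow term defaults to dilution form
(K_M u₃ + K_A u₄)/V with a literal ·V alternative.

### Rate laws

The balance structure is mechanistic; the specific rates are the
empirical ("grey") part and are pluggable. The default bundle is

    μ = μmax · S/(K_S + S + S²/K_i) · C_L/(K_O + C_L)
        · (1 − X/X_max) · K_E/(K_E + E)
    ν = μ/Y_XS + m_S        ρ = α μ + β
    η = μ/Y_XO + m_O        γ = c_H μ

i.e. Monod uptake with substrate inhibition (methanol is toxic in
excess), oxygen limitation, logistic crowding, and product inhibition by
the accumulating enzyme. The product-inhibition factor matters
structurally, not just kinetically: without any dependence of the rates
on E, the enzyme state leaves no trace in the measurable outputs, the
third column of the output-derivative Jacobian is identically zero and
the inverse problem is unsolvable (rank ≤ 2). A process for which the
soft sensor can work at all must close that loop; the default law closes
it in the biologically standard way. All default laws expose analytic
state gradients; arbitrary user laws fall back to central differences.

Default kinetic values are fixture values chosen once to reproduce the
stated study conditions of the induction phase — specific growth rate
below 0.01 1/h (protease avoidance at industrial scale), methanol held
near the 1 % (≈10 g/L) setpoint, biomass of order 50 g/L in a ~60–80 L
broth — not estimates of any particular plant: μmax = 0.015 1/h,
K_S = 15 g/L, K_i = 40 g/L, K_O = 5 (% sat), X_max = 65 g/L,
K_E = 50 U/mL, Y_XS = 0.4 g/g, m_S = 0.01 g/(g·h), α = 3, β = 0.005,
Y_XO = 5e-4, m_O = 5, c_H = 1e-7 mol/g, K_La = 20 1/h, C_L* = 100 % sat.

### Integration

Fixed-step classical RK4 (default step 0.01 h; campaigns use 0.02–0.05 h)
for determinism and testability; scipy's adaptive RK45 is available
through `simulate(..., method="rk45")`. The oxygen-transfer mode is the
fastest time constant (1/K_La = 0.05 h), so steps must satisfy
K_La·dt < 2.8 for RK4 stability; the defaults leave a comfortable
margin. After each step the five concentration states are floored at
zero and the number of clips recorded on the trajectory (none occur
under default conditions). A step-halving test confirms the h⁴ global
error scaling, and the volume channel reproduces V₀ + t·Σu exactly
under constant feeds.

## Invertibility diagnostic

The reconstruction target is the local invertibility of
(x₁, x₂, x₃) ↦ (ẍ₄, ẋ₄, ẋ₅). First derivatives come directly from the
balance equations; ẍ₄ is a central difference of ẋ₄ along a short
simulated arc (half-length 1e-3 h, feeds frozen). Each Jacobian column
is a central difference with step 1e-4 scaled by the state magnitude.

Rank is decided by singular-value thresholding at 1e-8 of the largest
singular value — on a row-equilibrated copy of the Jacobian (each row
divided by its inf-norm). Equilibration is essential, not cosmetic: the
rows mix dissolved-oxygen units with hydrogen-ion concentrations of
order 1e-6 mol/L, so the raw rows differ by ~8 orders of magnitude and a
raw relative threshold would misreport a full-rank matrix as rank 2.
Row scaling leaves the true rank invariant. The raw Jacobian is still
reported.

The printed symbolic reduction of the invertibility condition ends in a
product form whose leading factor is ∂η/∂x₁; its inner terms cannot be
reconstructed unambiguously, so the package does not guess a symbolic
form. Instead `det_diagnostic` is a numerical proxy —
det(equilibrated J) × (∂η/∂x₁ / ‖∇η‖) — that vanishes exactly when
either the rank drops or ∂η/∂x₁ = 0, mirroring both printed conditions.
Degenerate (state-independent) η and γ provably collapse the rank to
≤ 2, which the diagnostic reports and the tests assert.

## Preprocessing

* **Filter.** Moving average of window m with an outlier branch: when an
  innovation |x(k) − x̂(k−1)| reaches the threshold D, the sample is
  replaced by x̂(k−1) + D·sign(·) before the mean is recomputed. The
  source formulation literally replaces the sample by the *difference*
  x(k) − x̂(k−1), which discards the signal level; the clamped-innovation
  reading preserves level continuity and bounds spike amplification by D
  per step. Warm-up averages over the available history.
* **Differentiation.** Five-point stencils, exact through degree-4
  polynomials. Interior points use the standard central formulas;
  boundary points use one-sided five-point stencils whose weights are
  solved from a Vandermonde system at run time. One-sided second
  derivatives are one order less accurate than the interior — on an
  exponential oxygen-relaxation oracle at 0.5-h sampling the interior
  rows stay below 1e-3 relative error while the two edge rows reach the
  percent range. With 60-sample campaigns this affects 4 of 60 rows.
* **Normalization.** Min-max to [0,1] by default (z-score available),
  fitted on training rows only and frozen; degenerate constant channels
  get scale 1 with a warning. Statistics persist to JSON beside the
  model and carry a fingerprint that prediction paths can verify.
* **Offline alignment.** Assay series are mapped onto finer grids by
  sliding-window local least squares (window 5, degree 2) — it
  reproduces polynomials up to the window degree exactly and smooths
  assay noise that linear interpolation would reproduce verbatim. No
  extrapolation.

## Network and optimizer

The network core (forward pass, MSE, backprop, SGD, Adam) is written
directly in numpy because the identification algorithm is the point of
the package. Hidden layers use ReLU (subgradient at 0 defined as 0),
the output is linear, weights are He-initialized from a seeded
generator, biases start at zero. Training is full batch — campaigns
have tens of rows. Adam defaults are λ = 1e-3, β₁ = 0.9, β₂ = 0.999,
ε = 1e-8. Closed-form identities anchor the implementation: the first
Adam update has magnitude exactly λ per coordinate as ε → 0; constant
gradients give λ·sign(g) steps; β₁ = β₂ = 0 reduces to sign-gradient
descent, and huge ε to SGD scaled by λ/ε. Gradients are verified against
a central-difference oracle to 1e-6 relative error (oracle step 1e-5;
at 1e-6 the oracle's own roundoff exceeds the bar for small gradients).
A divergent run (non-finite loss) raises with the epoch and learning
rate. `FCNNRegressor` wraps the core in scikit-learn estimator
conventions.

## Soft sensor

`build_features` samples the measured channels on the assay grid
(default every 4 h), optionally filters them, differentiates x₄ (orders
1, 2) and x₅ (order 1), and stacks the 13 features in physical units;
normalization happens inside the estimator, from training rows only.
One symbol-table reading in the source swaps the roles of x̄₄..x̄₆ and
mentions a ẋ₆ derivative; the package follows the state convention
x₄ = C_L, x₅ = [H⁺], x₆ = V throughout and implements the feature set
(x₄, ẋ₄, ẍ₄, x₅, ẋ₅, x₆), with ẋ₆ available via `include_x6_dot`.

`SoftSensorRegressor` trains one 13-32-16-1 network per target (seeds
derived from `random_state` and the target index) with shared
normalization statistics. The architecture is a default, not a claim —
the source does not specify one.

Splits: chronological 70/30 is the deployment-hygiene default for a
single batch; batch-wise hold-out suits multi-batch campaigns; an
interleaved split (every third row) serves within-range validation of
the static inverse map, the regime in which reported test errors are
comparable to training errors. The optimizer comparison in the
acceptance suite uses the noise-free campaign with the interleaved
split, because extrapolation- or batch-bias-dominated test sets measure
the shared bias floor rather than the optimizer, and sensor noise at the
4-h sampling interval makes the ẍ₄ feature noise-dominated, which any
sufficiently powerful optimizer overfits.

`online_correct` continues Adam on the original training rows plus a
sliding window (default 20) of the newest labeled samples for k epochs
(default 50), with normalization frozen, and accepts the parameters at
their best loss on that pool — so a correction can never leave the model
worse on the data it was corrected against. On a fixture whose maximum
growth rate drops 40 % mid-campaign, correcting on the first five
post-shift assays reduces the error on the remainder of the new regime.

`evaluate` reports per-target MSE in normalized units (comparable
across targets; Table-style comparisons between optimizers use these)
and in physical units, plus relative-error series at the assay
timestamps with a guard: points with |y| < 1e-6 are flagged and excluded
from medians. Prediction curves are interpolated to a 30-min display
grid with the same local least-squares scheme as the alignment step.
`cascade_identity_check` is the end-to-end diagnostic: simulate → sample
→ featurize → predict → compare against the simulator's true states;
its result is the median relative error per target.

## Synthetic campaigns

A campaign is a pure function of (config, seed). Defaults encode the
study conditions: one 240-h methanol-induction phase (t = 0 at induction
onset; the preceding batch/glycerol phases enter through the initial
state X₀ = 55 g/L, S₀ = 10 g/L, E₀ = 0.05 U/mL, C_L₀ = 65 % sat,
pH₀ = 5.7, V₀ = 60 L), offline assays every 4 h → 60 pairs per batch,
±10 % inter-batch jitter on μmax and Y_XS, and sensor noise at the
instrument accuracies: DO 0.5 % of reading, pH 0.02 units (applied in pH
space, mapped to [H⁺]), flow 2 % of setpoint, temperature 0.1 °C, assays
2 % relative with the enzyme reported no lower than the 0.01 detection
floor.

**Feed sizing.** Substrate uptake is maintenance-dominated, so the
methanol balance behaves as an open-loop integrator: a constant feed
sized at any single operating point drifts into a collapsed-substrate
state. The generator therefore sizes the program against a reference
pass in which substrate is pinned at its setpoint — emulating what the
plant's methanol controller achieves — and gives the feed the small
linear ramp (capped at 10 % about the mean over the phase) that tracks
broth-volume growth. Seeded random ramps within ±5 % add realistic
program variation on top. Under the defaults, S stays within
8.3–10 g/L, μ stays below 0.001 1/h, and the ammonia feed balances the
time-averaged proton release.

**What passing tests show — and do not.** The campaigns share the
simulator with the model under test, so parameter-recovery results
demonstrate that the pipeline solves the inverse problem it poses:
correctly assembled features, a trainable inverse map, a well-posed
reconstruction. They do not demonstrate robustness to model mismatch —
real broths have unmodeled metabolism, sensor drift, pH-control
dynamics and non-Gaussian disturbances. The noise model is white and
per-sample; correlated drift would degrade the derivative features
further than the tests show.

## Known limitations

* The derivative features at 4-h sampling are noise-dominated under the
  printed sensor accuracies (the second DO derivative especially), so
  models trained on noisy campaigns overfit those channels; a longer
  window, lower-order features or regularization would be the first
  fixes on plant data.
* Chronological test splits measure extrapolation beyond the training
  time range; ReLU networks extrapolate linearly and the reported test
  MSE is correspondingly pessimistic there.
* The closed-form inverse map is never constructed symbolically; where
  the Jacobian rank drops (e.g. rates independent of a state), the
  package reports non-invertibility rather than attempting
  regularized reconstruction.
* pH chemistry is ion bookkeeping, not buffering equilibria; K_La is
  constant, not correlated with agitation or airflow.
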
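# Methods

## Model

Softening is modelled as three coupled first-order processes: a constant
internal ethylene signal `Eth` induces production of a lumped pool of
cell-wall-degrading enzymes `Enz` (rate constant `k_enz`), the pool decays
(`k_d`), and it degrades firmness `F` toward a residual asymptote `F_fix`
(`k_f`):

    dEth/dt = 0
    dEnz/dt = k_enz·Eth − k_d·Enz,    Enz(0) = Enz0
    dF/dt   = −k_f·(F − F_fix)·Enz,   F(0)   = F0

All rates are Arrhenius-scaled, `k(T) = k_ref·exp((E·1000/R)(1/T_ref − 1/T))`
with `T_ref = 295.15 K`, `R = 8.314 J mol⁻¹ K⁻¹` and activation energies
tabulated in kJ/mol (hence the factor 1000).

Key assumptions, and where they come from:

- **Constant ethylene during storage.** Measured internal ethylene in
  transported fruit settles at a low, stable level within a day; the model
  treats `Eth` as a per-batch (optionally per-fruit) constant. `Eth` is in
  arbitrary units — it reflects internal level *and* sensitivity, not a
  concentration — so only the product `EF = k_fenz(T_mean)·Eth` (the
  *ethylene factor*) is physically interpretable.
- **Zero initial enzyme pool.** Ripening is inhibited on the tree and
  chilled container transport suppresses the enzyme system, so `Enz0 = 0`
  at the start of storage. This makes `k_f` and `k_enz` jointly
  unidentifiable; the package exposes only their product `k_fenz`
  (mol⁻¹ d⁻¹) and reports enzyme levels in units absorbing the lumping
  (`k_f·Enz`). The full `Enz0 ≠ 0` solution remains available behind the
  `enz0` field for testing and for the estimation ladder's explicit check
  of the zero assumption.
- **One firmness per fruit.** Instruments read several positions per
  fruit; the CSV reader averages replicate readings at the same time point
  and logs their spread as a data-quality statistic. The model has a single
  `F` per fruit and position gradients are not modelled.

## Evaluation paths

At constant temperature the system has the closed form

    F(t) = F_fix + (F0 − F_fix)·exp(g),
    g = (k_fenz·Eth − k_d·Enz0)·(1 − e^(−k_d t))/k_d² − k_fenz·Eth·t/k_d

(the familiar lumped expression when `Enz0 = 0`). Piecewise-constant
scenarios are evaluated *exactly* by chaining this solution across
segments, restarting from the carried `(F, Enz)` state at each boundary.
Logged temperature traces (data-logger records, interpolated linearly) are
integrated with adaptive RK45 at `rtol 1e-8 / atol 1e-10` — deliberately
much tighter than prediction needs, so the integrator can serve as a strict
independent cross-check of the closed form (the property suite requires
agreement to 1e-5 of `F0`; observed agreement is orders tighter).

Numerical care: for `k_d·t < 1e-4` the exponent `g` switches to its Taylor
series `−Enz0·t − k_fenz·Eth·(t²/2 − k_d t³/6 + k_d² t⁴/24)`, avoiding the
catastrophic cancellation in `(1 − e^(−k_d t))/k_d²`; the series limit
`g → −k_fenz·Eth·t²/2` is verified against the branch to 1e-8. The mean
storage temperature entering EF is the *time-weighted* mean over segments
(trapezoidal for traces), computed in °C and converted to K; time-weighting
is what reproduces the published per-sub-batch EF values for two-period
scenarios, whereas a simple mean does not.

## Estimation

`fit` minimises the summed squared firmness residuals over all records with
each parameter either fixed or free at a chosen level (common / batch /
group / fruit) — fixed-effect indexed least squares, not a random-effects
likelihood. Implementation choices:

- **Optimiser.** Trust-region reflective least squares with box bounds
  (rates > 0, energies ≥ 0, `Eth ≥ 0`, `F_fix ≥ 0`). Initial firmness is
  reparameterised as `F0 = F_fix + exp(θ)` so the constraint `F0 > F_fix`
  can never be crossed; when a free `F0` entry spans several `F_fix`
  entries the anchor falls back to 0. A Jacobian sparsity pattern (each
  record touches only its own fruit/batch entries) keeps large per-fruit
  fits cheap.
- **Initialisation.** Deterministic and data-driven: `F0` from each
  fruit's first measurement, `F_fix` from 0.9× the batch minimum, `Eth`
  from a coarse log-grid scan, kinetics from the supplied start. When
  kinetic parameters are free — the case with genuine local-minimum risk —
  five seeded multi-starts run and the best is kept; the fixed-kinetics
  workflow is near-separable and uses the single deterministic start
  (override with `n_starts`).
- **Identifiability.** `kfenz_ref` and `Eth` free together is rejected
  with an explicit error: rescaling one and inversely rescaling the other
  leaves every prediction unchanged at any temperature, which is also why
  the 'Kent' convention fixes `kfenz_ref = 1` and lets `Eth` absorb the
  scale. Kinetics can only be fixed or common (they are cultivar
  properties).
- **Standard errors.** Gauss–Newton with pooled residual variance:
  `s²·(JᵀJ)⁻¹` from a central-difference Jacobian in natural parameter
  space at the optimum; entries are NaN when the information matrix is
  numerically singular. Wald-interval calibration is verified by
  simulation (coverage within [88%, 99%] at nominal 95%).
- **Fit quality.** Adjusted R² in percent,
  `100·(1 − (RSS/(n−p))/(TSS/(n−1)))` with TSS about the grand mean of the
  observations — the standard definition, adopted because "percentage
  variance accounted for" admits no other unambiguous reading.
- **Non-convergence** is flagged on the result (`converged=False`), never
  silently ignored.

`staged_fit` runs the attribution ladder: (1) everything common, (2)
`F_fix`/`Eth`/`Enz0` per batch, (3) `F0` per fruit, (4) optionally `Eth`
per fruit. Each stage warm-starts from the previous, which also guarantees
the nested-model property (RSS never increases down the ladder). Before
stage 3 the per-batch `Enz0` estimates are tested against twice their
standard errors; if all are indistinguishable from zero, `Enz0` is fixed at
0 and the lumped parameterisation used from there on. When a stage refines
a parameter's level, all higher-level parameters are frozen at their
previous-stage estimates (the alternative — re-freeing them — was rejected
to keep each stage's question well-posed).

The default workflow fixes the packaged cultivar kinetics and estimates
only `Eth`/`F_fix`/`F0`; freeing the kinetics is an explicit opt-in that
requires data at two or more temperatures.

## Synthetic data

The generator emulates the study's batch geometry: per-fruit initial
firmness drawn from `Normal(f0_mean, f0_sd)` truncated below at
`f_fix + 1` FI (designs where the truncation would reject most draws are
refused), noise-free trajectories from the exact model under the batch
scenario, and iid Gaussian measurement error added on top. Presets
reproduce three published designs from the packaged tables: the
four-temperature 'Keitt' batch (30 fruit × {10, 17, 24, 30} °C, 16 d,
F0 ~ N(61.7, 16.8), Eth 1.52, F_fix 12.7), its 'Kent' analogue
(N(36.3, 12.5), Eth 0.48, F_fix 6.9), and the eight Israeli sub-batches
with paired control/ethylene arms (Eth 0.63 vs 5.62) under their two-period
scenarios. An optional independent lognormal multiplier on per-fruit `Eth`
emulates fruit-to-fruit variation in ethylene response uncorrelated with
initial firmness.

Defaults and why: measurement noise sd 2.0 FI (no instrument error is
published; 2 FI is a realistic acoustic repeatability figure, tunable per
design); sub-batch sizes and measurement grids follow the published
designs (every 2 d over 16 d; every 1–2 d over 13 d for the paired-arm
experiment, here 0–13 d with a final-day reading; 25 fruit per Israeli
sub-batch, i.e. 200 fruit over eight sub-batches).

What passing tests on these data do and do not show: the generator draws
from the *same* model the estimator fits, so recovery and coverage results
certify the estimation machinery, not the model's adequacy for field data.
Real datasets carry lack-of-fit (position gradients, drifting ethylene,
chilling effects), which is why their percentage of variance accounted for
sits well below what model-true data with a 2-FI error produce; the test
suite checks the published 86–95% regime at the residual level that regime
implies (~6 FI), and parameter recovery at the 2-FI instrument level.
Position-level replicate variance is not simulated (no published value
exists), and neither are gas-exchange physics or container headspace
dynamics.

## Known limitations

- `Eth` is batch-conditional and unit-free; the model cannot predict EF
  for a new batch ahead of measurement, only describe and extrapolate once
  early firmness data exist.
- Chilling physiology and the tree factor are not modelled; they enter
  only through their motivating role for `Enz0 = 0`.
- The 'Kent' parameter set is partial by construction (`kfenz_ref` set
  to 1), so 'Kent' `Eth` values are comparable within cultivar only
  through EF.
- Fixed-effect least squares treats per-fruit parameters as free
  coefficients; with very short series per fruit the per-fruit estimates
  absorb noise, and standard errors rely on the pooled-variance
  Gauss–Newton approximation.
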
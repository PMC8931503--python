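# Methods

## Currents and gating model

Both currents are two-gate Hodgkin–Huxley models driven by the K⁺ driving
force `V − E_K`:

```
I_Kto   = G_to · a_to³ · i_to · (V − E_K)
I_Kslow = G_r  · a_r  · i_r  · (V − E_K)
```

I_Kto gating is written through transition rates (ms⁻¹),

```
α_a = 0.18064 e^{0.03577(V + x1)}
β_a = 0.395   e^{−0.06237(V + x2)}
α_i = 0.000152 e^{−(V + x3)/x4} / (0.067083 e^{−(V + x5)/x4} + 1)
β_i = 0.00095  e^{(V + x6)/x7}  / (0.051335 e^{(V + x6)/x7} + 1)
```

with `g_∞ = α/(α + β)` and `τ = 1/(α + β)`; I_Kslow directly through curves

```
a_∞ = 1/(1 + e^{−(V + x1)/x2})        τ_a = 0.493 e^{−0.0629 V} + x5
i_∞ = 1/(1 + e^{(V + x3)/x4})         τ_i = x6 − 170/(1 + e^{(V + x7)/x8})
```

Assumptions: voltage-independent maximal conductances; no temperature
dependence; I_Kss is a voltage-independent constant present only during the
depolarizing step (its role in the bi-exponential decomposition), with no
gating model of its own; the two I_Kslow subcomponents are not separated.

`τ_a` and `τ_i` readings follow the only interpretation consistent with the
source formulation and with the calibrated `x6` magnitudes (`x6` ≈ τ_i at
strong depolarization, since the logistic term vanishes there; `τ_i → x6 −
170` at strong hyperpolarization, which is why `x6 > 170 ms` is enforced).

### Parameters, units, defaults

* `x1…x8`: voltage shifts and slopes in mV, except I_Kslow `x5` (activation-τ
  floor, ms) and `x6` (inactivation-τ plateau, ms). Literature defaults: Kto
  `(30, 30, 13.5, 7, 33.5, 33.5, 7)`, Kslow
  `(22.5, 7.7, 45.2, 5.7, 2.058, 1200, 45.2, 5.7)`.
* `G_to = 0.4067`, `G_r = 0.16` mS/µF; with conductance in mS/µF and voltage
  in mV, current density comes out in pA/pF.
* `E_K = −84.2 mV`, from the Nernst relation at the source formulation's
  intra/extracellular K⁺ concentrations near room temperature; no value is
  fixed by the calibration data themselves, so it is exposed as a
  configurable constant (`ModelConstants`).
* Calibratable subsets (from the factorial screen): Kto
  `{x1, x2, x3, x6, x7, G_to}`; Kslow `{x1, x2, x3, x4, x6, G_r}`. The
  packaged WT/Mgat1KO presets carry group-mean values for these entries and
  literature defaults elsewhere.

## Voltage-clamp simulation

Protocol: hold −70 mV, depolarize for 4.5 s, sample at 1 ms. The default
step range is −60…+50 mV in 10-mV increments — the range used in the
predicted characteristic curves — although the experimental protocol is
quoted from −50 mV; both are configurable. 1-ms sampling resolves the
slowest kinetics comfortably; for peak-time studies of I_Kslow activation
(τ_a ≈ 2 ms at +50 mV) `dt_out` can be reduced to 0.05 ms.

Because the clamp is piecewise constant, each gate obeys a linear ODE per
phase and is propagated by the exact relaxation
`g(t) = g_∞ + (g0 − g_∞)e^{−t/τ}` (the `analytic` back-end). The `ode`
back-end integrates the same equations with `scipy.integrate.solve_ivp`
(LSODA, rtol 1e-8, atol 1e-10) phase by phase and serves as an independent
numerical route; the two are required to agree within 1e-4 of the per-trace
peak magnitude. Agreement is normalized by the trace peak rather than
pointwise because currents decay through zero-crossing-free but tiny values
late in the step, where pointwise relative error is meaningless.

Gates start at their steady state for the holding potential by default. This
makes the pre-step current exactly constant (full equilibration of the slow
inactivation gate at −70 mV would otherwise need ~5·x6 ≈ 7–9 s of holding)
and removes holding-phase drift artifacts entirely; custom initial gate
values are supported for studying non-equilibrated starts.

Time origin: t = 0 at step onset; holding samples carry negative t. Trace
CSV files (`time_ms, current_pApf, v_step_mv, kind`) record this convention.

## Feature extraction

* **Amplitude** Â: the maximum of the trace over the step window, ties broken
  by earliest time.
* **Time constant** τ̂: mono-exponential fit `A e^{−t/τ} + C` of the segment
  from the peak to the step end (the activation upstroke is excluded). The
  fit profiles out the linear parameters `(A, C)` exactly for each τ and
  searches only over log τ with a bounded scalar minimizer (τ ∈ [0.01, 1e6]
  ms, xatol 1e-12 in log τ). This is deterministic, needs no user starting
  values, and recovers noiseless inputs to optimizer precision. Flat
  segments leave τ unidentifiable and return a flagged (non-converged)
  result rather than a number.
* **Bi-exponential decomposition**: same profiling over the pair
  (log τ₁, log τ₂), multi-started from the grid {10, 50, 100} × {500, 1200,
  2000} ms and refined by Nelder–Mead; amplitudes and offset are constrained
  nonnegative by default (outward currents) via nonnegative least squares,
  with an unconstrained mode available. Component labels are assigned purely
  by ordering (smaller τ → Kto). Fits with |τ₁ − τ₂|/τ₂ < 1e-3 are flagged
  degenerate. Because the best-of-grid start can only improve as starts are
  added, the residual sum of squares is monotone in the multi-start count.
* Calibration always uses the *fitted* τ̂, not the analytic time constant, so
  simulated and experimental traces pass through an identical estimator.
  (For I_Kto the simulated decay is exponential and the two agree to ~0.1%;
  for I_Kslow the early decay is contaminated by activation, giving ~1–5%
  discrepancy — the reason the Kslow fit-vs-analytic checks use a 5% band.)

## Calibration

Objective: `δ_A + δ_τ` with `δ_A = |A − Â|`, `δ_τ = |τ − τ̂|`, evaluated by
simulating the candidate at the single target voltage (+50 mV by default,
where the group feature statistics are reported) with the analytic back-end.
The two addends mix pA/pF and ms without weights; this is deliberate —
convergence is judged per feature, so the scale imbalance affects only
intermediate ranking — and an optional weighted mode is not enabled by
default. Failed simulations or fits score +∞ and rank strictly last; exact
fitness ties are broken lexicographically by parameter value for
determinism.

**Self-breeding GA.** Population `N = k(1 + s)` initialized uniformly in the
search box. Each generation: rank, keep the top k unchanged (elitism — best
score is monotone), compute the per-parameter variance of the elites, pool
it as the arithmetic mean over the last `min(w, generations)` variances, and
let each elite spawn s offspring by adding independent per-parameter
Gaussian noise with the pooled variance, clipped to the box. Defaults
`N = 100, k = 10, s = 9, w = 5, max_gen = 500`: modest populations suffice
because each objective evaluation uses the closed-form gate solution
(~1 ms). The windowed pooled variance makes the search self-scaling: it
contracts as the elites agree, without an external cooling schedule.

**Stopping rule.** Runs stop when *both* `δ_A < ε_A` and `δ_τ < ε_τ`
(tolerances `(0.1 pA/pF, 1 ms)` for Kto, `(0.1, 5 ms)` for Kslow — smaller
than the standard errors of the group means they target). A permissive
either-feature variant is available (`stop_rule="either"`). Hitting
`max_gen` returns a non-converged result with full history, not an
exception.

**Search box.** Default bounds are `[0.25×, 6×]` each free parameter's
literature default, with slope parameters floored at 1 mV so logistic terms
cannot blow up. The upper factor is chosen so the box admits the calibrated
kinetics of *both* experimental groups: the slower-inactivating knockout
shifts the Kto β_i pair (`x6`, `x7`) several-fold above the literature
values, and any cap below ~5× the `x7` default makes the knockout's
amplitude and time constant jointly unreachable — the amplitude floor along
the τ-matching manifold then sits far above the target. Bounds are fully
configurable per run.

**Standard-GA baseline.** Top-k selection, uniform crossover of random elite
pairs for the `N − k` offspring, Gaussian mutation with fixed scale
(default 5% of the per-parameter range), same stopping rule.

**Identifiability.** Two target features against ≥3 free parameters is
under-determined: any point on a feature-equivalent manifold is a valid
solution. Replicate summaries (`fit_replicates`, default R = 30 independent
seeds, non-converged runs excluded and counted) therefore report the spread
of equivalent solutions in a mean ± SE table; parameter-level closeness to
any particular generating vector is neither expected nor asserted — what is
asserted is that re-simulating any converged solution reproduces the target
features within tolerance.

## Factorial screening

Full 2^p two-level designs in standard order (first factor fastest). Default
levels are ±20% multiplicative around the literature defaults — unreported
in the original study; ±20% keeps every run in physiologic gating ranges —
with responses `(Â, τ̂)` evaluated at +50 mV. Main effects are
`mean(high) − mean(low)`; standardized effects divide by the response range
across runs so amplitude and τ effects are rankable together. Selection
takes the top m (default 6, the size of the calibrated subsets) by the
larger standardized absolute effect, reporting ties at the cut instead of
breaking them. Since the screening levels are a choice, the selected subset
can differ from the packaged calibratable subsets at other levels; exact
subset reproduction is not asserted. Conductance is structurally the
strongest amplitude factor (current is linear in G) and has a null τ effect
(τ̂ is scale-invariant), which the test suite verifies.

## Synthetic cohorts

`synth_cohort` emulates group feature statistics: per-cell
`(A_Kto, τ_Kto, A_Kslow, τ_Kslow, A_Kss)` rows whose means are the features
forward-simulated from the group presets (no hand-entered numerals) and
whose spread is Normal(mean, cv·mean) truncated at zero by rejection, with a
warning when truncation exceeds 1% of the mass. The default cv = 0.3 is a
documented placeholder for typical cell-to-cell variability in whole-cell
feature data; the experimental error bars constrain it only graphically.
Group sizes default to the experimental n = 35 (WT) / 38 (Mgat1KO). The
default steady-state offset A_Kss = 2 pA/pF is likewise a placeholder
magnitude for a small non-inactivating component.

What the generator does **not** emulate: correlations between features
within a cell, capacitance/series-resistance and leak artifacts, voltage
errors, rundown, or non-Gaussian heavy tails. Passing tests built on these
cohorts therefore demonstrate pipeline correctness (estimator consistency,
determinism, convergence behavior) under idealized variability, not
robustness to real recording pathologies. `synth_iksum_traces` adds i.i.d.
Gaussian noise to the simulated summed current for stress-testing the
bi-exponential fit; real recording noise is colored and amplitude-dependent.

## Known limitations and preset-implied edge cases

* The packaged group presets imply a crossing of the Kto current–voltage
  relation at strongly hyperpolarized steps (−60…−30 mV): the knockout's
  activation-midpoint shifts outweigh its smaller conductance where both
  currents are fractions of a percent of their depolarized peaks, so the
  "knockout peak below wild type at every voltage" contrast holds only from
  about −20 mV upward for I_Kto (it holds everywhere for I_Kslow). Likewise
  the two groups' I_Kslow availability (SSI) curves, while close, differ by
  up to ~0.06 near −40 mV. The acceptance suite asserts the strict
  every-voltage versions of both contrasts and documents these two failures
  rather than weakening the claims.
* Single-voltage targets: calibration matches features at one depolarization
  only; multi-voltage simultaneous objectives are out of scope.
* No action-potential (current-clamp) simulation, no other membrane
  currents, no Markov channel models, no temperature dependence.
* Problem sizes in the shipped tests: GA acceptance runs use the default
  configuration with 5 seeds per group target; replicate-scaling checks use
  a reduced population and a shortened step window to keep the
  law-of-large-numbers comparison cheap. All stochastic tests are seeded and
  bit-reproducible.
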
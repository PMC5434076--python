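# Methods

## Disease model

`adtherapy` models the lesional skin of a moderate-to-severe atopic
dermatitis (AD) patient as a three-variable switched (hybrid) dynamical
system evolving in days:

* `P(t)` — load of infiltrated environmental stressors / pathogens
  (mg ml⁻¹),
* `B(t)` — skin barrier integrity, dimensionless in [0, 1],
* `D(t)` — level of inflammation markers (Th2-promoting cytokines,
  activated dendritic cells).

Two binary switches ride on the continuous dynamics, both driven by `P`:

* `R` — innate immune receptor activity. `R = R_on` is the clinical AD
  flare; `R = R_off` is the quiescent (subclinical) state.
* `K` — kallikrein (protease) activity responsible for desquamation-driven
  barrier damage.

Each switch is a perfect reversible switch with hysteresis: it turns ON
when `P` rises above its activation threshold (`P⁺`, nominally 40 mg ml⁻¹)
and turns OFF only when `P` falls below the lower deactivation threshold
(`P⁻`, nominally 26.6 mg ml⁻¹).  Inside the band the switch keeps its
state, which is what makes flares persistent: once triggered, inflammation
continues until the stressor load is pushed well below the trigger level.

The treated dynamics are

    dP/dt = κ_P·P_env/(1 + γ_B·B)  −  α_I·R·P/(1 + β₁·C)  −  δ_P·P

    dB/dt = [ κ_B / ( (1 + γ_R·R/(1 + β₂·C)) · (1 + γ_G·G/(1 + β₃·C)) ) + E ] · (1 − B)
            −  δ_B·K·B/(1 + β₂·C)

    dD/dt = κ_D·R/(1 + β₄·C)  −  δ_D·D

with corticosteroid potency `C(t)` and emollient potency `E(t)` as inputs.
Reading the terms:

* Stressors infiltrate from a constant environmental load `P_env` at a rate
  set by the skin permeability `κ_P`, attenuated by an intact barrier
  (`γ_B·B`).  They are eradicated by innate immune responses (antimicrobial
  peptides) at rate `α_I·R` — only substantial while the receptors are ON —
  and decay at the basal rate `δ_P`.  Corticosteroids, while
  anti-inflammatory, are known to suppress antimicrobial-peptide
  expression; the factor `1/(1 + β₁·C)` encodes that adverse effect
  (`β₁ = 0.005`, so it is mild at therapeutic potencies).
* The barrier self-restores towards its nominal integrity `B = 1` at rate
  `κ_B`, inhibited by innate-immune signalling (`γ_R·R`) and by Th2
  cytokines (`γ_G·G`, with the Gata-3 level `G` held at 1 to represent
  systemic Th2 sensitization of a severe patient).  Corticosteroid lifts
  both inhibitions (`β₂`, `β₃`) and also suppresses the kallikrein-mediated
  degradation `δ_B·K·B` (`β₂`), while the emollient `E` directly supports
  barrier restoration.  The production and degradation terms vanish at
  `B = 1` and `B = 0` respectively, so `B` is confined to [0, 1] by
  construction.
* Inflammation markers are produced while receptors signal (`κ_D·R`,
  reduced by corticosteroid through `β₄`) and degrade at `δ_D`.  With `G`
  fixed, `D` is a read-out of inflammation history and does not feed back
  on `P` or `B`.

Severity is encoded by two genetic-risk parameters: `κ_P` (FLG-mutation
-like barrier leakiness; nominal 0.85 day⁻¹) and `α_I` (innate immune
competence; nominal 0.05 day⁻¹).  A *severe cohort* is a parameterization
whose untreated dynamics possess a unique attractor that is a persistent
flare: receptors locked ON inside the hysteresis band with a collapsed
barrier (`check_severe_cohort` verifies uniqueness from a grid of initial
states).  For the nominal cohort this pathological steady state is
`P ≈ 32.9`, `B ≈ 0.007`, `D = 133.6` (the latter is the closed-form balance
`κ_D·R_on/δ_D = 4·16.7/0.5`).  It is the initial condition of all planning.

### The kallikrein switch

The model fixes `K_off = 1` and treats the remaining kallikrein-switch
choices as configuration: its driver is `P` with thresholds defaulting to
the receptor thresholds (`K⁻ = P⁻`, `K⁺ = P⁺`) — a flare activates the
protease cascade together with the receptors — and `K_on` defaults to 2.
`K_on = 2` is the smallest integer level at which constant emollient alone
(`Ē = 0.04`) cannot push a flaring nominal patient below the deactivation
threshold, i.e. emollient monotherapy does not induce remission in severe
patients, which is the clinical premise for designing corticosteroid
schedules in the first place.  All four quantities are plain parameters
(`K_minus`, `K_plus`, `K_off`, `K_on`) and are recorded in every resolved
configuration.

When `K⁻ = P⁻` the two switches cross their thresholds at the same instant;
both integration paths flip every switch whose armed threshold is reached
at an event time, so coincident thresholds never de-synchronize the modes.

## Treatment objectives

Proactive therapy has two phases.  The *induction* phase applies a constant
corticosteroid potency `C̄ ∈ [0, C_max]` for `T_r ∈ [0, T_r^max]` days
(nominally `C_max = 50`, `T_r^max = 8` weeks) to extinguish the flare; the
*maintenance* phase repeats weekly cycles in which potency `C_i` is applied
on the first `T_C^i ∈ {0,…,7}` days of the week.  The emollient is applied
constantly at `Ē = 0.04` throughout.  Both phases minimize

    J = k₁·J₁ + k₂·J₂ + k₃·J₃ + k₄·J₄,   (k₁, k₂, k₃, k₄) = (0.5, 1, 10, 10)

with, for a phase of maximal duration `T_max` (= `T_r^max` or `T_m = 7`),
target level `P*` (induction 24, maintenance 26) and final time `T`:

* `J₁ = (T/T_max)²` — treatment-duration burden,
* `J₂ = (C·T/(C_max·T_max))²` — amount of corticosteroid
  (duration × strength), the cost / side-effect proxy,
* `J₃ = ((P(T) − P*)/P*)² + Φ` — final deviation from target, plus the
  non-convex penalty `Φ`,
* `J₄ = (1/T)·∫₀ᵀ ((P(t) − P*)/P*)² dt` — mean squared trajectory
  deviation (for a maintenance cycle the normalization is the cycle length
  `T_m`).

`Φ` makes success lexically dominant: for induction,
`Φ_r = 100 + 0.1·(P(T_r) − P⁻)` if `P(T_r) > P⁻` and 0 otherwise (remission
not achieved); for a maintenance cycle the same form applies but only when
*both* `P` ends above `P⁻` *and* the receptors are ON (flare recurrence).
The deviation terms are relative to the target and two-sided, so both
under- and overshooting the chosen disease level are penalized; all four
components are dimensionless and invariant under a rescaling of the time
unit.  The induction target 24 sits just below the best stressor level the
treated model can sustain (`P ≈ 24.5` at `B = 1`), and the maintenance
target 26 sits just below the deactivation threshold 26.6.

## Planner

The planner solves the induction problem once from the pathological steady
state, then plans each weekly maintenance cycle *from the state actually
reached at that cycle's start* (the weekly clinic visit; observation is
noise-free).  This recursion makes the scheme self-correcting under poor
adherence: an `AdherenceScenario` lets the applied treatment deviate from
the suggestion (stopping corticosteroid after a number of induction days,
skipping corticosteroid and/or emollient in chosen cycles — always
under-application), and subsequent cycles are re-planned from the worsened
state.  Durations are continuous inside the optimizer and rounded to whole
days for the reported/applied schedule (daily on–off application); the
reported objective is re-evaluated at the rounded schedule.  On-days are
placed at the start of each cycle by default; placement `"end"` gives the
weekend-therapy variant.

Both planning problems are solved with differential evolution,
DE/rand-to-best/1: population 30, 1000 generations (configurable;
`donor = x_r1 + F·(x_best − x_r1) + F·(x_r2 − x_r3)` with `F = 0.6`),
binomial crossover with `CR = 0.5` and a guaranteed donor coordinate,
boundary clipping, greedy selection that accepts equal-objective trials,
and a fixed generation budget.  The indices `r1, r2, r3` are drawn without
replacement excluding the target index.  Every run is reproducible from a
single master seed; maintenance cycle `i` uses a seed derived from
`(master, i)` so any cycle can be reproduced in isolation.

## Scenario drivers

* **Target sweep** — full proactive runs at alternative maintenance target
  levels under a common seed.  The shipped defaults are 26 (nominal), 32
  (close to the activation threshold) and 22 (below the lowest sustainable
  stressor level); fold-changes of corticosteroid amount are reported
  against the nominal-target run.
* **Cohorts** — full runs for (κ_P, α_I) cohorts; cohorts whose optimizer
  cannot achieve remission (Φ_r > 0 at the capped induction) are flagged
  and their maintenance planning proceeds from the achieved state, which
  for strongly burdened cohorts turns into effectively continuous
  corticosteroid use.
* **Global sensitivity** — joint multiplicative perturbations, uniform
  within ±50%, of either the model rate constants (default 529 draws) or
  the objective weights (default 400 draws).  Per draw the induction
  problem is either re-optimized or the nominal schedule re-evaluated
  (both modes are implemented; re-optimization is the default).  Draws
  yielding invalid parameterizations (e.g. an inverted hysteresis band) or
  no pathological steady state are excluded and counted.  At perturbation
  0 every draw reproduces the nominal result exactly.

## Numerics

* **Reference simulator** (`simulate`): LSODA with `rtol = 1e-8`,
  `atol = 1e-10`; switch crossings are located by the solver's event
  machinery (well below 1e-9 day), integration restarts at each event with
  the flipped mode, and the output grid is 0.01-day spaced plus all
  breakpoints and event times.  State positivity / `B ≤ 1` are enforced
  only against integration noise (violations above 1e-6 raise).
* **Optimizer kernel**: the inner DE loop evaluates schedules with a
  numba-compiled fixed-step RK4 integrator (step 0.01 day) whose switch
  crossings are bisected to 1e-9 day within the step; it accumulates the
  `J₄` integrand trapezoidally as it steps.  The two paths agree to ~1e-6
  relative on week-scale segments and are cross-validated in the test
  suite.
* **Steady states**: long-horizon integration (500 days) with convergence
  declared when the relative change over a 50-day window falls below 1e-9;
  a root-finding cross-check on the algebraic fixed-point equations is part
  of the test suite, not of the production path (integration is robust to
  the switch structure, a pure root search is not).
* **Hysteresis** forbids Zeno behaviour as long as `P⁻ < P⁺`, which the
  parameter container enforces.

## Problem sizes

DE converges on these two-dimensional problems long before the default
1000-generation budget; the shipped experiment scripts and the test suite
run 200 generations with population 30, for which repeated seeds give
day-identical schedules, and the sensitivity drivers default to small
sample counts in tests.  All headline quantities (induction duration,
on-days per week, amount fold-changes) are stable across seeds at this
scale.

## Known limitations

* No spatial structure: one homogeneous skin compartment.
* The environment is constant; stochastic stressor fluctuation (which
  would make high maintenance targets risky) is not simulated.
* `G` is fixed at 1 (systemic Th2 sensitization); consequently `D` is a
  read-out rather than a feedback variable, and adaptive-immunity dynamics
  (de/re-sensitization) are out of scope.
* Weekly visits observe the state exactly; measurement noise is a hook,
  not a model.
* The kallikrein switch construction (driver, thresholds, on-level) is a
  modelling choice recorded in configuration; alternative constructions
  change the untreated barrier equilibria quantitatively.
* Model-predictive control with a receding horizon (graded therapy) is
  deliberately not implemented; the planner optimizes each phase/cycle to
  its own end.
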
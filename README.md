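# adtherapy

Computational design of **proactive therapy** schedules for atopic
dermatitis (AD), for modellers and methodologists working on treatment
scheduling: a hybrid (switched) ODE model of skin barrier–immune dynamics
under topical corticosteroid and emollient treatment, plus a recursive
optimal-control layer — solved with differential evolution — that produces
an induction schedule ("get control") and weekly maintenance schedules
("keep control") for virtual patient cohorts, including poor-adherence and
global-sensitivity studies.

## The model and the control problem

A virtual patient is the state (P, B, D): infiltrated stressor load
(mg ml⁻¹), skin barrier integrity (∈ [0, 1]) and inflammation-marker level.
Innate receptor activity R and kallikrein activity K are perfect reversible
switches with hysteresis driven by P — ON above P⁺ = 40 (an AD flare starts),
OFF again only below P⁻ = 26.6 (the flare stops):

    dP/dt = κ_P·P_env/(1 + γ_B·B) − α_I·R·P/(1 + β₁·C) − δ_P·P
    dB/dt = [κ_B/((1 + γ_R·R/(1+β₂·C))(1 + γ_G·G/(1+β₃·C))) + E]·(1−B)
            − δ_B·K·B/(1 + β₂·C)
    dD/dt = κ_D·R/(1 + β₄·C) − δ_D·D

Corticosteroid potency C relieves inflammation-mediated barrier suppression
(β₂, β₃), suppresses dendritic-cell activation (β₄), and mildly impairs
antimicrobial eradication (β₁); the emollient E supports barrier
restoration.  Severe patients — parameterized by skin permeability κ_P and
innate competence α_I — have a unique untreated attractor: a persistent
flare with a collapsed barrier.  From that state the planner minimizes

    J = k₁·J₁ + k₂·J₂ + k₃·J₃ + k₄·J₄

(duration, amount = potency×days, final- and trajectory-deviation from a
target stressor level, plus a non-convex +100 penalty for failing to reach /
keep remission) over (T_r, C̄) for the induction phase and, recursively,
over (T_C, C_i) for each weekly maintenance cycle, re-planning every week
from the state actually reached.  The optimizer is DE/rand-to-best/1
(population 30, F = 0.6, CR = 0.5, fixed generation budget, fully seeded).
See `docs/methods.md` for assumptions, parameter meanings and numerics.

## Worked example

```python
from adtherapy import (ModelParameters, ObjectiveWeights, ControlBounds,
                       DEConfig, run_proactive_therapy)
from adtherapy.scenarios import modal_on_days

p, w, b = ModelParameters(), ObjectiveWeights(), ControlBounds()
res = run_proactive_therapy(p, w, b, DEConfig(generations=200, seed=1),
                            n_cycles=8)
print(res.induction.T_r, round(res.induction.C_bar, 2))
print([t for t, sw, d in res.induction.trajectory.events if sw == "R"])
print([(c["suggested_days"], round(c["suggested_potency"], 1))
       for c in res.cycles])
print(modal_on_days(res), res.flare_recurrences)
```

prints

```
19 17.38
[1.5607451687965865]
[(3, 4.1), (4, 6.7), (4, 6.5), (4, 6.5), (4, 6.5), (4, 6.5), (4, 6.5), (4, 6.5)]
4 0
```

i.e. the optimal induction applies potency ≈ 17.4 for 19 days; the flare
stops after 1.56 days (the single R switch event); the weekly re-planner
then keeps remission with 3–4 corticosteroid days per week (modal 4) at low
potency, with zero flare recurrences over the 8-week maintenance horizon.
The same run from the shell:

```bash
adtherapy plan --seed 1 --generations 200 --cycles 8 --out out/
# T_r=19 C_bar=17.38 on-days/week=4 recurrences=0
```

Other subcommands: `simulate`, `sweep-targets`, `cohorts`, `adherence`,
`sensitivity`; all accept `--config cfg.yaml` (see `examples/nominal.yaml`)
and write a reproducible bundle (plan JSON, tidy trajectory CSV, events
JSON, report, resolved config) into `--out`.

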
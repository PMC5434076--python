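"""Recursive optimal-control driver for proactive therapy.

The therapy has two phases.  The *induction* phase applies a constant
corticosteroid potency C_bar for T_r days to suppress the flare; (T_r,
C_bar) is found by differential evolution.  The *maintenance* phase repeats
weekly cycles: at the start of each cycle the patient's state is observed
(a weekly clinic visit) and DE finds the cycle's schedule — C applied on the
first T_C days of the week at potency C_i — minimizing the cycle objective.
Planning each cycle from the *actual* observed state makes the recursion
robust to non-adherence: if the applied treatment deviated from the
suggestion, the next cycle is planned from wherever the patient actually is.

Durations are continuous inside the optimizer and rounded to whole days for
the reported / applied schedule (daily on-off application); the reported
objective is re-evaluated at the rounded schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .de import OptimizationResult, optimize
from .model import check_severe_cohort, pathological_steady_state
from .objectives import (ObjectiveBreakdown, induction_objective,
                         maintenance_objective, phi_r, total_corticosteroid)
from .params import (ControlBounds, DEConfig, DiseaseState, ModelParameters,
                     ObjectiveWeights)
from .simulate import Trajectory, TreatmentSchedule, flare_status, simulate

__all__ = [
    "TherapyPlan",
    "AdherenceScenario",
    "InductionResult",
    "ProactiveResult",
    "plan_induction",
    "plan_maintenance_cycle",
    "run_proactive_therapy",
    "cycle_seed",
]


@dataclass
class TherapyPlan:
    """Suggested schedule: induction pair plus weekly maintenance cycles."""

    induction_days: int
    induction_potency: float
    maintenance_cycles: list = field(default_factory=list)  # [(T_C_i, C_i)]
    emollient: float = 0.04

    def amounts(self) -> dict:
        return total_corticosteroid(self)


@dataclass(frozen=True)
class AdherenceScenario:
    """Deviation of the applied treatment from the suggested plan.

    ``induction_c_days``: corticosteroid actually applied only for the first
    so-many induction days (None: full adherence).
    ``induction_e_on``: emollient actually applied during the induction
    phase.  ``cycle_overrides`` maps 0-based maintenance-cycle indices to
    (corticosteroid applied?, emollient applied?) — omitted cycles are fully
    adherent.  Non-adherence is always under-application.
    """

    induction_c_days: int | None = None
    induction_e_on: bool = True
    cycle_overrides: dict = field(default_factory=dict)


@dataclass
class InductionResult:
    T_r: int
    C_bar: float
    objective: ObjectiveBreakdown
    optimization: OptimizationResult
    trajectory: Trajectory
    remission_achieved: bool


@dataclass
class ProactiveResult:
    plan: TherapyPlan
    induction: InductionResult
    trajectory: Trajectory
    cycles: list = field(default_factory=list)  # per-cycle diagnostics dicts
    flare_recurrences: int = 0

    def amounts(self) -> dict:
        return self.plan.amounts()


def cycle_seed(master_seed: int, cycle_index: int) -> int:
    """Derived seed for one maintenance cycle (reproducible in isolation)."""
    ss = np.random.SeedSequence([int(master_seed), int(cycle_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def plan_induction(p: ModelParameters, w: ObjectiveWeights, b: ControlBounds,
                   de_config: DEConfig, init: DiseaseState | None = None,
                   check_severity: bool = False, dt: float = 0.01) -> InductionResult:
    """DE-optimal (T_r, C_bar) for the induction phase.

    Starts from the cohort's pathological steady state unless ``init`` is
    given.  ``check_severity=True`` additionally verifies that the untreated
    dynamics have a unique flare attractor before planning.  The optimal
    duration is day-rounded for the reported schedule and the objective
    re-evaluated there.  A plan that fails to achieve remission (phi_r > 0)
    is returned flagged, not raised: it is a cohort finding.
    """
    if check_severity and not check_severe_cohort(p):
        raise ValueError("parameters do not define a severe cohort "
                         "(no unique pathological steady state)")
    if init is None:
        init = pathological_steady_state(p)

    def objective(x):
        return induction_objective(x[0], x[1], p, w, b, init, dt=dt).J

    res = optimize(objective, [(0.0, b.T_r_max), (0.0, b.C_max_induction)],
                   de_config)
    T_r = int(np.clip(np.round(res.best_vector[0]), 0, b.T_r_max))
    C_bar = float(res.best_vector[1])
    breakdown = induction_objective(float(T_r), C_bar, p, w, b, init, dt=dt)

    if T_r > 0:
        sched = TreatmentSchedule.constant(float(T_r), C_bar, b.E_bar)
        traj = simulate(init, sched, p)
    else:
        # degenerate zero-length induction: empty trajectory at the start
        traj = Trajectory(times=np.array([0.0]),
                          states=init.y[None, :],
                          modes=np.array([[init.mode.r_on, init.mode.k_on]]),
                          applied=np.array([[0.0, b.E_bar]]),
                          events=[], final_state=init)
    remission = phi_r(traj.state_at_end().P, p) == 0.0
    return InductionResult(T_r=T_r, C_bar=C_bar, objective=breakdown,
                           optimization=res, trajectory=traj,
                           remission_achieved=remission)


def plan_maintenance_cycle(state_at_visit: DiseaseState, cycle_index: int,
                           p: ModelParameters, w: ObjectiveWeights,
                           b: ControlBounds, de_config: DEConfig,
                           dt: float = 0.01, placement: str = "start"):
    """DE-optimal (T_C, C_i) for one weekly cycle from the observed state.

    Returns (T_C days, C_i, ObjectiveBreakdown, OptimizationResult).  The
    DE seed is derived from the config seed and the cycle index, so any
    cycle is reproducible in isolation.
    """
    cfg = de_config.with_(seed=cycle_seed(de_config.seed, cycle_index))

    def objective(x):
        return maintenance_objective(x[0], x[1], p, w, b, state_at_visit,
                                     dt=dt, placement=placement).J

    res = optimize(objective, [(0.0, b.T_m), (0.0, b.C_max_maintenance)], cfg)
    T_C = int(np.clip(np.round(res.best_vector[0]), 0, b.T_m))
    C_i = float(res.best_vector[1])
    breakdown = maintenance_objective(float(T_C), C_i, p, w, b,
                                      state_at_visit, dt=dt,
                                      placement=placement)
    return T_C, C_i, breakdown, res


def _applied_cycle_schedule(T_C: int, C_i: float, b: ControlBounds,
                            start: float, c_on: bool, e_on: bool,
                            placement: str) -> TreatmentSchedule:
    C = C_i if c_on else 0.0
    E = b.E_bar if e_on else 0.0
    return TreatmentSchedule.on_off(T_C if c_on else 0, C, E,
                                    cycle_length=b.T_m, start=start,
                                    placement=placement)


def run_proactive_therapy(p: ModelParameters, w: ObjectiveWeights,
                          b: ControlBounds, de_config: DEConfig,
                          n_cycles: int = 8,
                          scenario: AdherenceScenario | None = None,
                          init: DiseaseState | None = None,
                          dt: float = 0.01,
                          placement: str = "start") -> ProactiveResult:
    """Full proactive therapy: induction then ``n_cycles`` weekly cycles.

    Each cycle is planned from the state the patient actually reached,
    which includes the effect of any prior non-adherence from ``scenario``.
    """
    if n_cycles < 1:
        raise ValueError("need at least one maintenance cycle")
    scenario = scenario or AdherenceScenario()

    ind = plan_induction(p, w, b, de_config, init=init, dt=dt)
    plan = TherapyPlan(induction_days=ind.T_r, induction_potency=ind.C_bar,
                       emollient=b.E_bar)

    # applied induction (may deviate from the suggestion)
    if (scenario.induction_c_days is None and scenario.induction_e_on) or ind.T_r == 0:
        traj = ind.trajectory
    else:
        c_days = (ind.T_r if scenario.induction_c_days is None
                  else min(int(scenario.induction_c_days), ind.T_r))
        E = b.E_bar if scenario.induction_e_on else 0.0
        if 0 < c_days < ind.T_r:
            sched = TreatmentSchedule(
                (0.0, float(c_days), float(ind.T_r)),
                (ind.C_bar, 0.0), (E, E))
        else:
            sched = TreatmentSchedule.constant(
                float(ind.T_r), ind.C_bar if c_days else 0.0, E)
        start_state = (pathological_steady_state(p) if init is None else init)
        traj = simulate(start_state, sched, p)

    state = traj.state_at_end()
    cycles = []
    t0 = float(ind.T_r)
    full = traj

    for i in range(n_cycles):
        T_C, C_i, breakdown, res = plan_maintenance_cycle(
            state, i, p, w, b, de_config, dt=dt, placement=placement)
        c_on, e_on = scenario.cycle_overrides.get(i, (True, True))
        sched = _applied_cycle_schedule(T_C, C_i, b, t0, c_on, e_on, placement)
        cyc_traj = simulate(state, sched, p)
        status = flare_status(cyc_traj)
        cycles.append({
            "cycle": i,
            "suggested_days": T_C,
            "suggested_potency": C_i,
            "applied_c": bool(c_on),
            "applied_e": bool(e_on),
            "suggested_amount": T_C * C_i,
            "applied_amount": (T_C * C_i) if c_on else 0.0,
            "objective": breakdown.as_dict(),
            "P_end": cyc_traj.state_at_end().P,
            "B_end": cyc_traj.state_at_end().B,
            "flares_in_cycle": status["n_flares"],
            "seed": cycle_seed(de_config.seed, i),
        })
        plan.maintenance_cycles.append((T_C, C_i))
        full = full.concat(cyc_traj)
        state = cyc_traj.state_at_end()
        t0 += b.T_m

    recurrences = sum(1 for (t, sw, d) in full.events
                      if sw == "R" and d > 0 and t > 1e-9)
    return ProactiveResult(plan=plan, induction=ind, trajectory=full,
                           cycles=cycles, flare_recurrences=recurrences)
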
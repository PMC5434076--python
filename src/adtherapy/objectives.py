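"""Objective functions of the two planning phases.

Both phases minimize J = k1*J1 + k2*J2 + k3*J3 + k4*J4 over a candidate
schedule, where

* J1 penalizes treatment duration (patient burden), as the squared fraction
  of the maximal phase duration;
* J2 penalizes the amount of corticosteroid applied, duration x strength,
  squared after normalization by the maximal amount (cost / side-effect
  risk);
* J3 penalizes the squared relative deviation of the final stressor load P
  from the phase target, plus the non-convex remission / flare penalty
  (phi_r for the induction phase, phi_m for a maintenance cycle);
* J4 penalizes the time-averaged squared relative deviation of the P
  trajectory from the target.

All four components are dimensionless.  The phi penalties jump by 100 at
their activation condition, which makes achieving (and keeping) remission
lexically dominant over the smooth terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .params import (ControlBounds, DiseaseState, ModelParameters,
                     ObjectiveWeights, SwitchMode)
from .simulate import TreatmentSchedule, simulate

__all__ = [
    "phi_r",
    "phi_m",
    "induction_objective",
    "maintenance_objective",
    "total_corticosteroid",
    "ObjectiveBreakdown",
]


def phi_r(P_final: float, p: ModelParameters) -> float:
    """Remission-failure penalty at the end of the induction phase.

    100 + 0.1*(P - P_minus) when the final stressor load still exceeds the
    flare-deactivation threshold, else 0.
    """
    if P_final < 0:
        raise ValueError("P_final must be >= 0")
    if P_final > p.P_minus:
        return 100.0 + 0.1 * (P_final - p.P_minus)
    return 0.0


def phi_m(P_end: float, mode: SwitchMode, p: ModelParameters) -> float:
    """Flare-recurrence penalty at the end of a maintenance cycle.

    Active only when BOTH the stressor load exceeds P_minus and the
    receptors are in the flaring (ON) state.
    """
    if P_end < 0:
        raise ValueError("P_end must be >= 0")
    if P_end > p.P_minus and mode.r_on:
        return 100.0 + 0.1 * (P_end - p.P_minus)
    return 0.0


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Weighted objective value and its components (pre-weighting)."""

    J: float
    J1: float
    J2: float
    J3: float
    J4: float
    phi: float
    P_final: float
    final_state: DiseaseState | None = None

    def as_dict(self) -> dict:
        return {"J": self.J, "J1": self.J1, "J2": self.J2, "J3": self.J3,
                "J4": self.J4, "phi": self.phi, "P_final": self.P_final}


_EV_T = np.empty(_kernel.MAX_EVENTS)
_EV_SW = np.empty(_kernel.MAX_EVENTS, dtype=np.int64)
_EV_DIR = np.empty(_kernel.MAX_EVENTS, dtype=np.int64)
_DUMMY_TS = np.empty(1)
_DUMMY_YS = np.empty((1, 3))


def _run_fast(init: DiseaseState, seg_ends, Cs, Es, p: ModelParameters,
              target: float, dt: float):
    """Kernel integration of a piecewise-constant schedule from t=0.

    Returns (final y, final mode, integral of squared relative deviation of
    P from ``target``, number of switch events).  The kernel accumulates the
    squared relative deviation directly.
    """
    y, r_on, k_on, n_ev, dev, _ = _kernel.integrate_piecewise(
        init.y.astype(np.float64), init.mode.r_on, init.mode.k_on, 0.0,
        np.asarray(seg_ends, dtype=np.float64),
        np.asarray(Cs, dtype=np.float64), np.asarray(Es, dtype=np.float64),
        p.as_array(), dt, target, False,
        _EV_T, _EV_SW, _EV_DIR, -1.0, _DUMMY_TS, _DUMMY_YS)
    return y, SwitchMode(r_on=bool(r_on), k_on=bool(k_on)), dev, n_ev


def induction_objective(T_r: float, C_bar: float, p: ModelParameters,
                        w: ObjectiveWeights, b: ControlBounds,
                        init: DiseaseState, dt: float = 0.01,
                        engine: str = "fast") -> ObjectiveBreakdown:
    """Objective of a constant-potency induction phase of duration ``T_r``.

    Corticosteroid of potency ``C_bar`` and emollient of potency ``E_bar``
    are applied for ``T_r`` days from ``init`` (normally the pathological
    steady state).  ``engine`` 'fast' uses the compiled fixed-step kernel,
    'events' the adaptive reference simulator.
    """
    if not 0 <= T_r <= b.T_r_max + 1e-9:
        raise ValueError(f"T_r={T_r} outside [0, {b.T_r_max}]")
    if not 0 <= C_bar <= b.C_max_induction + 1e-9:
        raise ValueError(f"C_bar={C_bar} outside [0, {b.C_max_induction}]")

    targ = w.P_target_induction
    if T_r <= 0:
        Pf = init.P
        dev2 = ((Pf - targ) / targ) ** 2
        phi = phi_r(Pf, p)
        J3 = dev2 + phi
        J = w.k3 * J3 + w.k4 * dev2
        return ObjectiveBreakdown(J=J, J1=0.0, J2=0.0, J3=J3, J4=dev2,
                                  phi=phi, P_final=Pf, final_state=init)

    if engine == "fast":
        y, mode, devint, _ = _run_fast(init, [T_r], [C_bar], [b.E_bar],
                                       p, targ, dt)
        final = DiseaseState(P=float(max(y[0], 0.0)),
                             B=float(min(max(y[1], 0.0), 1.0)),
                             D=float(max(y[2], 0.0)), mode=mode)
    elif engine == "events":
        sched = TreatmentSchedule.constant(float(np.round(T_r)), C_bar, b.E_bar)
        traj = simulate(init, sched, p, sample_dt=dt)
        final = traj.state_at_end()
        rel = (traj.states[:, 0] - targ) / targ
        devint = float(np.trapezoid(rel * rel, traj.times))
    else:
        raise ValueError(f"unknown engine {engine!r}")

    Pf = final.P
    J1 = (T_r / b.T_r_max) ** 2
    J2 = (C_bar * T_r / (b.C_max_induction * b.T_r_max)) ** 2
    phi = phi_r(Pf, p)
    J3 = ((Pf - targ) / targ) ** 2 + phi
    J4 = devint / T_r
    J = w.k1 * J1 + w.k2 * J2 + w.k3 * J3 + w.k4 * J4
    return ObjectiveBreakdown(J=J, J1=J1, J2=J2, J3=J3, J4=J4, phi=phi,
                              P_final=Pf, final_state=final)


def maintenance_objective(T_C: float, C_i: float, p: ModelParameters,
                          w: ObjectiveWeights, b: ControlBounds,
                          init: DiseaseState, dt: float = 0.01,
                          engine: str = "fast",
                          placement: str = "start") -> ObjectiveBreakdown:
    """Objective of one maintenance cycle of length ``T_m``.

    Corticosteroid of potency ``C_i`` is applied for the first ``T_C`` days
    of the cycle (or the last, for placement='end'), the emollient
    throughout; the flare penalty phi_m is evaluated at the cycle end.
    """
    if not 0 <= T_C <= b.T_m + 1e-9:
        raise ValueError(f"T_C={T_C} outside [0, {b.T_m}]")
    if not 0 <= C_i <= b.C_max_maintenance + 1e-9:
        raise ValueError(f"C_i={C_i} outside [0, {b.C_max_maintenance}]")

    targ = w.P_target_maintenance
    T_C = min(T_C, b.T_m)
    if engine == "fast":
        if T_C <= 0:
            segs, Cs, Es = [b.T_m], [0.0], [b.E_bar]
        elif T_C >= b.T_m:
            segs, Cs, Es = [b.T_m], [C_i], [b.E_bar]
        elif placement == "start":
            segs, Cs, Es = [T_C, b.T_m], [C_i, 0.0], [b.E_bar, b.E_bar]
        elif placement == "end":
            segs, Cs, Es = [b.T_m - T_C, b.T_m], [0.0, C_i], [b.E_bar, b.E_bar]
        else:
            raise ValueError(f"unknown placement {placement!r}")
        y, mode, devint, _ = _run_fast(init, segs, Cs, Es, p, targ, dt)
        final = DiseaseState(P=float(max(y[0], 0.0)),
                             B=float(min(max(y[1], 0.0), 1.0)),
                             D=float(max(y[2], 0.0)), mode=mode)
    elif engine == "events":
        sched = TreatmentSchedule.on_off(int(np.round(T_C)), C_i, b.E_bar,
                                         cycle_length=b.T_m,
                                         placement=placement)
        traj = simulate(init, sched, p, sample_dt=dt)
        final = traj.state_at_end()
        rel = (traj.states[:, 0] - targ) / targ
        devint = float(np.trapezoid(rel * rel, traj.times))
    else:
        raise ValueError(f"unknown engine {engine!r}")

    Pf = final.P
    J1 = (T_C / b.T_m) ** 2
    J2 = (C_i * T_C / (b.C_max_maintenance * b.T_m)) ** 2
    phi = phi_m(Pf, final.mode, p)
    J3 = ((Pf - targ) / targ) ** 2 + phi
    J4 = devint / b.T_m
    J = w.k1 * J1 + w.k2 * J2 + w.k3 * J3 + w.k4 * J4
    return ObjectiveBreakdown(J=J, J1=J1, J2=J2, J3=J3, J4=J4, phi=phi,
                              P_final=Pf, final_state=final)


def total_corticosteroid(plan) -> dict:
    """Corticosteroid amount (potency x days) of a therapy plan, by phase."""
    ind = plan.induction_days * plan.induction_potency
    maint = float(sum(tc * ci for tc, ci in plan.maintenance_cycles))
    return {"induction": ind, "maintenance": maint, "total": ind + maint}
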
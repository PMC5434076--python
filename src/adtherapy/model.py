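"""Core disease model: treated AD dynamics, hysteretic switches, steady states.

The continuous state is (P, B, D): infiltrated stressor load, skin barrier
integrity and inflammation-marker level.  Two binary hysteretic switches ride
on the continuous dynamics, both driven by P: the innate immune receptors R
(ON = AD flare) and kallikrein activity K (ON = desquamation-driven barrier
damage).  A switch turns ON when P rises above its activation threshold and
OFF only when P falls below its lower deactivation threshold, so the band in
between is bistable (perfect reversible switch with hysteresis).

Moderate-to-severe virtual patients are parameterizations for which the
untreated system has a unique flare-ON fixed point with a collapsed barrier;
that state is the initial condition for all therapy planning.
"""

from __future__ import annotations

import numpy as np

from . import _kernel
from .params import DiseaseState, ModelParameters, SwitchMode, TreatmentInput

__all__ = [
    "rhs",
    "effective_R",
    "effective_K",
    "update_switch",
    "pathological_steady_state",
    "check_severe_cohort",
]

#: long-horizon settling defaults (days)
SETTLE_HORIZON = 500.0
SETTLE_WINDOW = 50.0
SETTLE_RTOL = 1e-9
STEADY_STATE_TOL = 1e-6


def effective_R(mode: SwitchMode, p: ModelParameters) -> float:
    """Receptor level implied by the discrete mode (R_off or R_on)."""
    return p.R_on if mode.r_on else p.R_off


def effective_K(mode: SwitchMode, p: ModelParameters) -> float:
    """Kallikrein level implied by the discrete mode (K_off or K_on)."""
    return p.K_on if mode.k_on else p.K_off


def rhs(state: DiseaseState, u: TreatmentInput, p: ModelParameters) -> tuple[float, float, float]:
    """Time derivatives (dP/dt, dB/dt, dD/dt) at the given state and treatment.

    The algebraic form of each term is documented in
    :func:`adtherapy._kernel.rhs_arr`, which this wraps.
    """
    if u.C < 0 or u.E < 0:
        raise ValueError("treatment potencies must be non-negative")
    R = effective_R(state.mode, p)
    K = effective_K(state.mode, p)
    dP, dB, dD = _kernel.rhs_arr(state.y, R, K, u.C, u.E, p.as_array())
    return float(dP), float(dB), float(dD)


def update_switch(mode: SwitchMode, P: float, p: ModelParameters) -> SwitchMode:
    """Hysteresis update of both switches for stressor load ``P``.

    OFF -> ON only above the activation threshold; ON -> OFF only below the
    deactivation threshold; inside the band the mode is unchanged.
    """
    if P < 0:
        raise ValueError("P must be >= 0")
    r_on = mode.r_on
    if r_on and P < p.P_minus:
        r_on = False
    elif not r_on and P > p.P_plus:
        r_on = True
    k_on = mode.k_on
    if k_on and P < p.K_minus:
        k_on = False
    elif not k_on and P > p.K_plus:
        k_on = True
    return SwitchMode(r_on=r_on, k_on=k_on)


def _settle_from(y0: np.ndarray, mode: SwitchMode, p: ModelParameters,
                 horizon: float = SETTLE_HORIZON):
    y, r_on, k_on, converged = _kernel.settle(
        np.asarray(y0, dtype=np.float64), mode.r_on, mode.k_on,
        p.as_array(), 0.01, horizon, SETTLE_WINDOW, SETTLE_RTOL)
    return y, SwitchMode(r_on=bool(r_on), k_on=bool(k_on)), bool(converged)


def pathological_steady_state(p: ModelParameters,
                              horizon: float = SETTLE_HORIZON) -> DiseaseState:
    """Untreated flare-ON fixed point of a severe patient.

    Computed by long-horizon integration of the untreated dynamics from a
    flaring initial guess until the state is stationary (relative change
    below 1e-9 over a 50-day window).  Raises if the integration does not
    converge, or if the converged state is not a persistent flare (receptors
    ON with P locked inside or above the hysteresis band).
    """
    y0 = np.array([max(p.P_plus * 1.05, 1.0), 0.5, 0.0])
    y, mode, converged = _settle_from(y0, SwitchMode(r_on=True, k_on=True), p, horizon)
    if not converged:
        raise RuntimeError("steady-state integration did not converge "
                           f"within {horizon} days")
    if not mode.r_on or y[0] <= p.P_minus:
        raise ValueError("parameters do not yield a persistent-flare steady "
                         "state (severity violation)")
    return DiseaseState(P=float(y[0]), B=float(y[1]), D=float(y[2]), mode=mode)


def check_severe_cohort(p: ModelParameters, n_grid: int = 3,
                        tol: float = 1e-4) -> bool:
    """True iff the untreated dynamics have a unique flare-ON attractor.

    Simulates the untreated system from a grid of initial conditions spanning
    the state box and both switch modes; returns True only when every start
    converges to the same persistent-flare fixed point (pairwise distance
    below ``tol``).  A parameterization admitting an additional flare-free
    (receptors OFF) attractor is not a severe cohort.
    """
    try:
        ref = pathological_steady_state(p)
    except (RuntimeError, ValueError):
        return False
    ref_y = ref.y
    Ps = np.linspace(1.0, 1.5 * p.P_plus, n_grid)
    Bs = np.linspace(0.0, 1.0, n_grid)
    for P0 in Ps:
        for B0 in Bs:
            for r_on in (False, True):
                mode0 = update_switch(SwitchMode(r_on=r_on, k_on=r_on), P0, p)
                y, mode, converged = _settle_from(
                    np.array([P0, B0, 0.0]), mode0, p)
                if not converged or not mode.r_on:
                    return False
                if np.max(np.abs(y - ref_y)) > tol * max(1.0, np.max(np.abs(ref_y))):
                    return False
    return True
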
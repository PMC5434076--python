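"""Event-driven simulation of the switched dynamics under treatment schedules.

Treatment is piecewise constant on a daily grid (corticosteroid on/off days,
constant emollient).  Integration proceeds segment by segment with scipy's
adaptive solver; hysteresis threshold crossings are located by the solver's
event machinery, the discrete mode is flipped at the crossing and integration
restarts there, so trajectories are continuous while only the modes jump.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernel
from .model import effective_K, effective_R, update_switch
from .params import DiseaseState, ModelParameters, SwitchMode

__all__ = ["TreatmentSchedule", "Trajectory", "simulate", "flare_status",
           "FlareEpisode"]

RTOL = 1e-8
ATOL = 1e-10
SAMPLE_DT = 0.01


@dataclass(frozen=True)
class TreatmentSchedule:
    """Piecewise-constant treatment on integer-day breakpoints.

    ``breakpoints`` has one more entry than the level arrays; interval ``i``
    is the half-open [breakpoints[i], breakpoints[i+1]) with corticosteroid
    potency ``C_levels[i]`` and emollient potency ``E_levels[i]``.
    """

    breakpoints: tuple[float, ...]
    C_levels: tuple[float, ...]
    E_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size < 2:
            raise ValueError("need at least two breakpoints")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.max(np.abs(bp - np.round(bp))) > 1e-9:
            raise ValueError("breakpoints must fall on integer days "
                             "(daily on-off application)")
        if len(self.C_levels) != bp.size - 1 or len(self.E_levels) != bp.size - 1:
            raise ValueError("need exactly one (C, E) level per interval")
        if min(self.C_levels) < 0 or min(self.E_levels) < 0:
            raise ValueError("treatment levels must be non-negative")

    @classmethod
    def constant(cls, duration: float, C: float, E: float,
                 start: float = 0.0) -> "TreatmentSchedule":
        return cls((start, start + duration), (C,), (E,))

    @classmethod
    def on_off(cls, on_days: int, C: float, E: float, cycle_length: float = 7.0,
               start: float = 0.0, placement: str = "start") -> "TreatmentSchedule":
        """One maintenance cycle: C on ``on_days`` consecutive days, then off.

        ``placement`` 'start' applies corticosteroid on the first days of the
        cycle (block structure of the weekly schedules); 'end' gives the
        weekend-therapy variant.
        """
        on_days = int(on_days)
        if not 0 <= on_days <= cycle_length:
            raise ValueError("on_days must lie within the cycle")
        if on_days == 0:
            return cls((start, start + cycle_length), (0.0,), (E,))
        if on_days == cycle_length:
            return cls((start, start + cycle_length), (C,), (E,))
        if placement == "start":
            return cls((start, start + on_days, start + cycle_length),
                       (C, 0.0), (E, E))
        if placement == "end":
            off = cycle_length - on_days
            return cls((start, start + off, start + cycle_length),
                       (0.0, C), (E, E))
        raise ValueError(f"unknown placement {placement!r}")

    @property
    def t_start(self) -> float:
        return self.breakpoints[0]

    @property
    def t_end(self) -> float:
        return self.breakpoints[-1]

    def levels_at(self, t: float) -> tuple[float, float]:
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        idx = min(max(idx, 0), len(self.C_levels) - 1)
        return self.C_levels[idx], self.E_levels[idx]

    def segments(self):
        for i in range(len(self.C_levels)):
            yield (self.breakpoints[i], self.breakpoints[i + 1],
                   self.C_levels[i], self.E_levels[i])


@dataclass
class Trajectory:
    """Sampled result of a simulation with exact mode-change bookkeeping."""

    times: np.ndarray            # (n,)
    states: np.ndarray           # (n, 3): P, B, D
    modes: np.ndarray            # (n, 2) bool: r_on, k_on
    applied: np.ndarray          # (n, 2): C, E
    events: list = field(default_factory=list)  # (time, 'R'|'K', +1/-1)
    final_state: DiseaseState | None = None

    def state_at_end(self) -> DiseaseState:
        assert self.final_state is not None
        return self.final_state

    def to_frame(self, p: ModelParameters) -> pd.DataFrame:
        r = np.where(self.modes[:, 0], p.R_on, p.R_off)
        k = np.where(self.modes[:, 1], p.K_on, p.K_off)
        return pd.DataFrame({
            "time": self.times,
            "P": self.states[:, 0],
            "B": self.states[:, 1],
            "D": self.states[:, 2],
            "R_level": r,
            "K_level": k,
            "C": self.applied[:, 0],
            "E": self.applied[:, 1],
        })

    def export(self, csv_path, events_path, p: ModelParameters) -> None:
        """Tidy CSV of the sampled trajectory plus a JSON event sidecar."""
        self.to_frame(p).to_csv(csv_path, index=False)
        with open(events_path, "w") as fh:
            json.dump([{"time": t, "switch": sw, "direction": d}
                       for t, sw, d in self.events], fh, indent=2)

    def concat(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(
            times=np.concatenate([self.times, other.times]),
            states=np.vstack([self.states, other.states]),
            modes=np.vstack([self.modes, other.modes]),
            applied=np.vstack([self.applied, other.applied]),
            events=self.events + other.events,
            final_state=other.final_state,
        )


def _event_fns(mode: SwitchMode, p: ModelParameters):
    fns = []
    if mode.r_on:
        f = lambda t, y: y[0] - p.P_minus
        f.direction, f.terminal, f.tag = -1, True, ("R", -1)
    else:
        f = lambda t, y: y[0] - p.P_plus
        f.direction, f.terminal, f.tag = 1, True, ("R", 1)
    fns.append(f)
    if mode.k_on:
        g = lambda t, y: y[0] - p.K_minus
        g.direction, g.terminal, g.tag = -1, True, ("K", -1)
    else:
        g = lambda t, y: y[0] - p.K_plus
        g.direction, g.terminal, g.tag = 1, True, ("K", 1)
    fns.append(g)
    return fns


def simulate(initial: DiseaseState, schedule: TreatmentSchedule,
             p: ModelParameters, horizon: float | None = None,
             sample_dt: float = SAMPLE_DT, rtol: float = RTOL,
             atol: float = ATOL) -> Trajectory:
    """Integrate the switched system under a treatment schedule.

    ``horizon`` defaults to the schedule's end time and may not exceed it.
    The output grid is ``sample_dt``-spaced and additionally contains every
    breakpoint and every switching time.
    """
    if horizon is None:
        horizon = schedule.t_end
    if horizon <= schedule.t_start or horizon > schedule.t_end + 1e-9:
        raise ValueError("horizon must lie within the schedule span")

    pvec = p.as_array()
    t = schedule.t_start
    y = initial.y.astype(float)
    mode = initial.mode
    ts, ys, mds, apl, events = [], [], [], [], []

    for (t0, t1, C, E) in schedule.segments():
        t1 = min(t1, horizon)
        if t1 <= t:
            continue
        while t < t1 - 1e-12:
            R = effective_R(mode, p)
            K = effective_K(mode, p)
            sol = solve_ivp(
                lambda tt, yy: _kernel.rhs_arr(yy, R, K, C, E, pvec),
                (t, t1), y, method="LSODA", rtol=rtol, atol=atol,
                dense_output=True, events=_event_fns(mode, p))
            if sol.status == -1:
                raise RuntimeError(f"integration failed at t={sol.t[-1]:.6f}: "
                                   f"{sol.message}")
            t_stop = sol.t[-1]
            grid = np.arange(t, t_stop, sample_dt)
            if grid.size == 0 or grid[-1] < t_stop - 1e-12:
                grid = np.append(grid, t_stop)
            vals = sol.sol(grid)
            ts.append(grid)
            ys.append(vals.T)
            mds.append(np.tile([mode.r_on, mode.k_on], (grid.size, 1)))
            apl.append(np.tile([C, E], (grid.size, 1)))
            if sol.status == 1:
                # earliest crossing; flip every switch whose armed threshold
                # is reached there (coincident thresholds fire together, and
                # scipy reports only one root for identical event functions)
                fired = [(sol.t_events[i][0], i) for i in range(2)
                         if len(sol.t_events[i])]
                t_ev, i0 = min(fired)
                y = sol.y_events[i0][0].copy()
                P_ev = y[0]
                r_on, k_on = mode.r_on, mode.k_on
                tol = 1e-9
                if r_on and P_ev <= p.P_minus + tol:
                    r_on = False
                    events.append((float(t_ev), "R", -1))
                elif not r_on and P_ev >= p.P_plus - tol:
                    r_on = True
                    events.append((float(t_ev), "R", 1))
                if k_on and P_ev <= p.K_minus + tol:
                    k_on = False
                    events.append((float(t_ev), "K", -1))
                elif not k_on and P_ev >= p.K_plus - tol:
                    k_on = True
                    events.append((float(t_ev), "K", 1))
                mode = SwitchMode(r_on=r_on, k_on=k_on)
                t = float(t_ev)
            else:
                y = sol.y[:, -1].copy()
                t = t1

    times = np.concatenate(ts)
    states = np.vstack(ys)
    # numerical guard: tolerate integration noise only
    worst = max(float(np.max(-states[:, 0], initial=0.0)),
                float(np.max(-states[:, 1], initial=0.0)),
                float(np.max(states[:, 1] - 1.0, initial=0.0)),
                float(np.max(-states[:, 2], initial=0.0)))
    if worst > 1e-6:
        raise RuntimeError(f"state invariant violated by {worst:.2e}")
    states[:, 0] = np.maximum(states[:, 0], 0.0)
    states[:, 1] = np.clip(states[:, 1], 0.0, 1.0)
    states[:, 2] = np.maximum(states[:, 2], 0.0)

    final = DiseaseState(P=float(max(y[0], 0.0)),
                         B=float(min(max(y[1], 0.0), 1.0)),
                         D=float(max(y[2], 0.0)), mode=mode)
    return Trajectory(times=times, states=states,
                      modes=np.vstack(mds), applied=np.vstack(apl),
                      events=events, final_state=final)


@dataclass(frozen=True)
class FlareEpisode:
    start: float
    stop: float | None  # None: unresolved at the end of the horizon


def flare_status(traj: Trajectory) -> dict:
    """Flare episodes and remission flag derived from the event record.

    An episode spans from an R OFF->ON event (or the trajectory start, if it
    begins flaring) to the next R ON->OFF event.  Remission holds when the
    receptors are OFF at the end of the simulated horizon.
    """
    t0 = float(traj.times[0])
    t_end = float(traj.times[-1])
    r_events = [(t, d) for (t, sw, d) in traj.events if sw == "R"]
    episodes: list[FlareEpisode] = []
    open_start = t0 if traj.modes[0, 0] else None
    for t, d in r_events:
        if d > 0 and open_start is None:
            open_start = t
        elif d < 0 and open_start is not None:
            episodes.append(FlareEpisode(start=open_start, stop=t))
            open_start = None
    if open_start is not None:
        episodes.append(FlareEpisode(start=open_start, stop=None))
    final_mode = traj.state_at_end().mode
    return {
        "episodes": episodes,
        "n_flares": len(episodes),
        "remission_achieved": not final_mode.r_on,
    }
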
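"""Hybrid simulator: event bookkeeping, accuracy, associativity."""

import numpy as np
import pytest

from adtherapy import (DiseaseState, SwitchMode, TreatmentSchedule,
                       flare_status, simulate)
from adtherapy.model import effective_K, effective_R
from adtherapy.objectives import _run_fast


def rk4_reference(y0, mode, p, C, E, t0, t1, h):
    """Independent fixed-step RK4 oracle for a no-event segment.

    Deliberately written in plain python against the public ``rhs``-style
    algebra so it shares no code with either integration path.
    """
    R = effective_R(mode, p)
    K = effective_K(mode, p)

    def f(y):
        P, B, D = y
        dP = (p.kappa_P * p.P_env / (1 + p.gamma_B * B)
              - p.alpha_I * R * P / (1 + p.beta_1 * C) - p.delta_P * P)
        prod = p.kappa_B / ((1 + p.gamma_R * R / (1 + p.beta_2 * C))
                            * (1 + p.gamma_G * p.G / (1 + p.beta_3 * C)))
        dB = (prod + E) * (1 - B) - p.delta_B * K * B / (1 + p.beta_2 * C)
        dD = p.kappa_D * R / (1 + p.beta_4 * C) - p.delta_D * D
        return np.array([dP, dB, dD])

    y = np.asarray(y0, float).copy()
    n = int(round((t1 - t0) / h))
    for _ in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


class TestSimulate:
    def test_zero_treatment_is_constant_with_no_events(self, p, patho):
        traj = simulate(patho, TreatmentSchedule.constant(50.0, 0.0, 0.0), p)
        assert traj.events == []
        assert np.max(np.abs(traj.states - patho.y)) < 1e-6

    def test_agrees_with_reference_integrator(self, p, post):
        """7-day constant-treatment segment vs a 1e-4-step RK4 oracle."""
        sched = TreatmentSchedule.constant(7.0, 10.0, 0.04)
        traj = simulate(post, sched, p)
        ref = rk4_reference(post.y, post.mode, p,
                            10.0, 0.04, 0.0, 7.0, 1e-4)
        assert traj.state_at_end().y == pytest.approx(ref, rel=1e-5)

    def test_kernel_matches_event_simulator(self, p, patho):
        """The compiled objective kernel and the adaptive reference path
        agree on final state and switching time across an eventful run."""
        sched = TreatmentSchedule.constant(10.0, 17.0, 0.04)
        traj = simulate(patho, sched, p)
        y, mode, _, _ = _run_fast(patho, [10.0], [17.0], [0.04], p, 24.0, 0.01)
        assert y == pytest.approx(traj.state_at_end().y, rel=1e-5, abs=1e-7)
        assert mode == traj.state_at_end().mode

    def test_events_sit_on_thresholds(self, p, patho):
        sched = TreatmentSchedule.constant(10.0, 17.0, 0.04)
        traj = simulate(patho, sched, p)
        assert traj.events, "expected a flare-off event"
        for t_ev, sw, direction in traj.events:
            idx = np.searchsorted(traj.times, t_ev)
            P_ev = np.interp(t_ev, traj.times, traj.states[:, 0])
            thr = {("R", -1): p.P_minus, ("R", 1): p.P_plus,
                   ("K", -1): p.K_minus, ("K", 1): p.K_plus}[(sw, direction)]
            assert P_ev == pytest.approx(thr, abs=1e-4)

    def test_coincident_thresholds_flip_both_switches(self, p, patho):
        # K shares the receptor thresholds, so the flare-off event must
        # switch off both R and K at the same instant
        sched = TreatmentSchedule.constant(10.0, 17.0, 0.04)
        traj = simulate(patho, sched, p)
        r_off = [t for t, sw, d in traj.events if sw == "R" and d < 0]
        k_off = [t for t, sw, d in traj.events if sw == "K" and d < 0]
        assert len(r_off) == 1 and len(k_off) == 1
        assert r_off[0] == pytest.approx(k_off[0], abs=1e-9)

    def test_split_horizon_associativity(self, p, patho):
        """Simulating [0,14] equals [0,7] then [7,14] from the day-7 state."""
        whole = simulate(patho, TreatmentSchedule.constant(14.0, 17.0, 0.04), p)
        first = simulate(patho, TreatmentSchedule.constant(7.0, 17.0, 0.04), p)
        second = simulate(first.state_at_end(),
                          TreatmentSchedule((7.0, 14.0), (17.0,), (0.04,)), p)
        assert second.state_at_end().y == pytest.approx(
            whole.state_at_end().y, rel=1e-7, abs=1e-9)
        assert second.state_at_end().mode == whole.state_at_end().mode

    def test_refinement_stability(self, p, patho):
        sched = TreatmentSchedule.constant(7.0, 17.0, 0.04)
        a = simulate(patho, sched, p, rtol=1e-8, atol=1e-10)
        c = simulate(patho, sched, p, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(a.state_at_end().y - c.state_at_end().y)) < 1e-6

    def test_state_bounds_along_schedules(self, p, patho, rng):
        for _ in range(5):
            sched = TreatmentSchedule.on_off(int(rng.integers(0, 8)),
                                             float(rng.uniform(0, 50)), 0.04)
            traj = simulate(patho, sched, p)
            assert np.all(traj.states[:, 0] >= 0)
            assert np.all((traj.states[:, 1] >= 0)
                          & (traj.states[:, 1] <= 1))
            assert np.all(traj.states[:, 2] >= 0)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TreatmentSchedule((0.0, 1.5), (10.0,), (0.04,))  # non-integer day
        with pytest.raises(ValueError):
            TreatmentSchedule((0.0, 2.0, 1.0), (1.0, 1.0), (0.0, 0.0))
        with pytest.raises(ValueError):
            TreatmentSchedule((0.0, 2.0), (-1.0,), (0.0,))


class TestFlareStatus:
    def test_persistent_flare_is_one_unresolved_episode(self, p, patho):
        traj = simulate(patho, TreatmentSchedule.constant(20.0, 0.0, 0.0), p)
        status = flare_status(traj)
        assert status["n_flares"] == 1
        assert status["episodes"][0].start == 0.0
        assert status["episodes"][0].stop is None
        assert not status["remission_achieved"]

    def test_induction_resolves_single_episode_quickly(self, p, patho):
        traj = simulate(patho, TreatmentSchedule.constant(19.0, 17.0, 0.04), p)
        status = flare_status(traj)
        assert status["n_flares"] == 1
        assert status["episodes"][0].stop is not None
        assert status["episodes"][0].stop <= 3.0
        assert status["remission_achieved"]

    def test_episode_count_matches_event_record(self, p, patho):
        traj = simulate(patho, TreatmentSchedule.constant(19.0, 17.0, 0.04), p)
        n_on = sum(1 for _, sw, d in traj.events if sw == "R" and d > 0)
        initially_on = bool(traj.modes[0, 0])
        assert flare_status(traj)["n_flares"] == n_on + int(initially_on)
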
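"""Numba-compiled fixed-step integration kernel.

The planner evaluates tens of thousands of candidate schedules per phase, so
the objective path uses a classical RK4 integrator with per-step hysteresis
handling compiled with numba.  Switch crossings are located by bisection on
the step to 1e-9 day before the mode is flipped, so the discrete dynamics are
event-accurate despite the fixed step.  The adaptive, event-located scipy
path in :mod:`adtherapy.simulate` is the reference implementation; the two
are cross-validated in the test suite.

Parameter vector layout: see ``params.PARAM_ORDER``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Indices into the packed parameter vector (params.PARAM_ORDER).
(_P_ENV, _GAMMA_B, _KAPPA_P, _ALPHA_I, _DELTA_P,
 _KAPPA_B, _GAMMA_R, _DELTA_B, _GAMMA_G,
 _KAPPA_D, _DELTA_D,
 _P_MINUS, _P_PLUS, _R_OFF, _R_ON,
 _K_MINUS, _K_PLUS, _K_OFF, _K_ON,
 _G, _BETA_1, _BETA_2, _BETA_3, _BETA_4) = range(24)

MAX_EVENTS = 64


@njit(cache=True)
def rhs_arr(y, R, K, C, E, p):
    """Right-hand side of the treated AD dynamics.

    Term map (symbol -> code):
      dP/dt:  kappa_P * P_env / (1 + gamma_B * B)        infiltration through barrier
            - alpha_I * R * P / (1 + beta_1 * C)         AMP-mediated eradication,
                                                         reduced by corticosteroid
            - delta_P * P                                basal death
      dB/dt:  [ kappa_B / ( (1 + gamma_R * R / (1 + beta_2 * C))
                          * (1 + gamma_G * G / (1 + beta_3 * C)) )
                + E ] * (1 - B)                          self-restoring production,
                                                         inhibited by innate (gamma_R)
                                                         and Th2 (gamma_G) signalling,
                                                         both relieved by corticosteroid;
                                                         enhanced by emollient
            - delta_B * K * B / (1 + beta_2 * C)         kallikrein desquamation damage,
                                                         reduced by corticosteroid
      dD/dt:  kappa_D * R / (1 + beta_4 * C)             DC activation by receptors,
                                                         reduced by corticosteroid
            - delta_D * D                                degradation
    """
    P = y[0]
    B = y[1]
    D = y[2]
    dP = (p[_KAPPA_P] * p[_P_ENV] / (1.0 + p[_GAMMA_B] * B)
          - p[_ALPHA_I] * R * P / (1.0 + p[_BETA_1] * C)
          - p[_DELTA_P] * P)
    prod = p[_KAPPA_B] / ((1.0 + p[_GAMMA_R] * R / (1.0 + p[_BETA_2] * C))
                          * (1.0 + p[_GAMMA_G] * p[_G] / (1.0 + p[_BETA_3] * C)))
    dB = (prod + E) * (1.0 - B) - p[_DELTA_B] * K * B / (1.0 + p[_BETA_2] * C)
    dD = p[_KAPPA_D] * R / (1.0 + p[_BETA_4] * C) - p[_DELTA_D] * D
    return dP, dB, dD


@njit(cache=True)
def _rk4_step(y, h, R, K, C, E, p):
    k1P, k1B, k1D = rhs_arr(y, R, K, C, E, p)
    y2 = np.empty(3)
    y2[0] = y[0] + 0.5 * h * k1P
    y2[1] = y[1] + 0.5 * h * k1B
    y2[2] = y[2] + 0.5 * h * k1D
    k2P, k2B, k2D = rhs_arr(y2, R, K, C, E, p)
    y2[0] = y[0] + 0.5 * h * k2P
    y2[1] = y[1] + 0.5 * h * k2B
    y2[2] = y[2] + 0.5 * h * k2D
    k3P, k3B, k3D = rhs_arr(y2, R, K, C, E, p)
    y2[0] = y[0] + h * k3P
    y2[1] = y[1] + h * k3B
    y2[2] = y[2] + h * k3D
    k4P, k4B, k4D = rhs_arr(y2, R, K, C, E, p)
    out = np.empty(3)
    out[0] = y[0] + h / 6.0 * (k1P + 2.0 * k2P + 2.0 * k3P + k4P)
    out[1] = y[1] + h / 6.0 * (k1B + 2.0 * k2B + 2.0 * k3B + k4B)
    out[2] = y[2] + h / 6.0 * (k1D + 2.0 * k2D + 2.0 * k3D + k4D)
    # guard band: integration noise only, never a model effect
    if out[0] < 0.0:
        out[0] = 0.0
    if out[1] < 0.0:
        out[1] = 0.0
    elif out[1] > 1.0:
        out[1] = 1.0
    if out[2] < 0.0:
        out[2] = 0.0
    return out


@njit(cache=True)
def _crossing(y, h, R, K, C, E, p, thr, direction):
    """Bisection for the time offset in (0, h] at which P crosses ``thr``.

    ``direction`` +1: upward crossing, -1: downward.  Assumes a sign change
    of (P - thr) between offsets 0 and h.  Returns the offset, located to
    1e-9 day.
    """
    lo = 0.0
    hi = h
    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        ym = _rk4_step(y, mid, R, K, C, E, p)
        g = ym[0] - thr
        if (g > 0.0) == (direction > 0):
            hi = mid
        else:
            lo = mid
    return hi


@njit(cache=True)
def integrate_piecewise(y0, r_on, k_on, t0, seg_ends, Cs, Es, p, dt,
                        targ, one_sided,
                        ev_t, ev_sw, ev_dir,
                        sample_dt, ts_buf, ys_buf):
    """Integrate the switched system across piecewise-constant treatment segments.

    seg_ends/Cs/Es: per-segment end time and constant treatment levels.
    Accumulates the trajectory penalty integral of the (optionally one-sided)
    squared relative deviation of P from ``targ``.  Events (R or K switch
    flips) are appended to ev_t/ev_sw/ev_dir (sw: 0 = R, 1 = K; dir +1 ON).
    If ``sample_dt > 0`` the state is recorded into ts_buf/ys_buf on an
    equispaced grid.

    Returns (y_final, r_on, k_on, n_events, dev_integral, n_samples).
    """
    y = y0.copy()
    t = t0
    n_ev = 0
    n_s = 0
    dev = 0.0

    g_prev = (y[0] - targ) / targ
    if one_sided and g_prev < 0.0:
        g_prev = 0.0
    g_prev = g_prev * g_prev

    next_sample = 1e300
    if sample_dt > 0.0:
        ts_buf[n_s] = t
        ys_buf[n_s, 0] = y[0]
        ys_buf[n_s, 1] = y[1]
        ys_buf[n_s, 2] = y[2]
        n_s += 1
        next_sample = t0 + sample_dt

    for s in range(seg_ends.shape[0]):
        t_end = seg_ends[s]
        C = Cs[s]
        E = Es[s]
        while t < t_end - 1e-12:
            h = dt
            if t + h > t_end:
                h = t_end - t
            R = p[_R_ON] if r_on else p[_R_OFF]
            K = p[_K_ON] if k_on else p[_K_OFF]
            y_new = _rk4_step(y, h, R, K, C, E, p)

            # hysteresis crossings within this step; simultaneous crossings
            # (coincident thresholds) are flipped together
            h_r = -1.0
            dir_r = 0
            if r_on:
                if y_new[0] < p[_P_MINUS] and y[0] >= p[_P_MINUS]:
                    h_r = _crossing(y, h, R, K, C, E, p, p[_P_MINUS], -1)
                    dir_r = -1
            else:
                if y_new[0] > p[_P_PLUS] and y[0] <= p[_P_PLUS]:
                    h_r = _crossing(y, h, R, K, C, E, p, p[_P_PLUS], 1)
                    dir_r = 1
            h_k = -1.0
            dir_k = 0
            if k_on:
                if y_new[0] < p[_K_MINUS] and y[0] >= p[_K_MINUS]:
                    h_k = _crossing(y, h, R, K, C, E, p, p[_K_MINUS], -1)
                    dir_k = -1
            else:
                if y_new[0] > p[_K_PLUS] and y[0] <= p[_K_PLUS]:
                    h_k = _crossing(y, h, R, K, C, E, p, p[_K_PLUS], 1)
                    dir_k = 1

            h_ev = -1.0
            if h_r >= 0.0:
                h_ev = h_r
            if h_k >= 0.0 and (h_ev < 0.0 or h_k < h_ev):
                h_ev = h_k
            if h_ev >= 0.0:
                y_new = _rk4_step(y, h_ev, R, K, C, E, p)
                h = h_ev
                if h_r >= 0.0 and h_r <= h_ev + 1e-9:
                    r_on = not r_on
                    if n_ev < ev_t.shape[0]:
                        ev_t[n_ev] = t + h_ev
                        ev_sw[n_ev] = 0
                        ev_dir[n_ev] = dir_r
                        n_ev += 1
                if h_k >= 0.0 and h_k <= h_ev + 1e-9:
                    k_on = not k_on
                    if n_ev < ev_t.shape[0]:
                        ev_t[n_ev] = t + h_ev
                        ev_sw[n_ev] = 1
                        ev_dir[n_ev] = dir_k
                        n_ev += 1

            g = (y_new[0] - targ) / targ
            if one_sided and g < 0.0:
                g = 0.0
            g = g * g
            dev += 0.5 * (g_prev + g) * h
            g_prev = g
            t += h
            y = y_new

            if sample_dt > 0.0:
                while next_sample <= t + 1e-12 and n_s < ts_buf.shape[0]:
                    # nearest-step sample; grid spacing == integration step
                    ts_buf[n_s] = next_sample
                    ys_buf[n_s, 0] = y[0]
                    ys_buf[n_s, 1] = y[1]
                    ys_buf[n_s, 2] = y[2]
                    n_s += 1
                    next_sample += sample_dt

    return y, r_on, k_on, n_ev, dev, n_s


@njit(cache=True)
def settle(y0, r_on, k_on, p, dt, horizon, check_window, tol):
    """Integrate the untreated system until (near-)stationarity.

    Runs up to ``horizon`` days; every ``check_window`` days the maximum
    relative change of the state over the window is tested against ``tol``.
    Returns (y, r_on, k_on, converged_flag).
    """
    y = y0.copy()
    t = 0.0
    y_mark = y.copy()
    next_check = check_window
    ev_t = np.empty(MAX_EVENTS)
    ev_sw = np.empty(MAX_EVENTS, dtype=np.int64)
    ev_dir = np.empty(MAX_EVENTS, dtype=np.int64)
    dummy_ts = np.empty(1)
    dummy_ys = np.empty((1, 3))
    seg = np.empty(1)
    Cs = np.zeros(1)
    Es = np.zeros(1)
    while t < horizon:
        t_next = t + check_window
        if t_next > horizon:
            t_next = horizon
        seg[0] = t_next
        y, r_on, k_on, n_ev, _, _ = integrate_piecewise(
            y, r_on, k_on, t, seg, Cs, Es, p, dt, 1.0, False,
            ev_t, ev_sw, ev_dir, -1.0, dummy_ts, dummy_ys)
        t = t_next
        ok = True
        for i in range(3):
            scale = abs(y[i]) if abs(y[i]) > 1.0 else 1.0
            if abs(y[i] - y_mark[i]) / scale > tol:
                ok = False
        if ok and n_ev == 0 and t >= 2 * check_window:
            return y, r_on, k_on, True
        y_mark = y.copy()
    return y, r_on, k_on, False
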
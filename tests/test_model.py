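"""Model core: dynamics, switches, steady states, severity region."""

import numpy as np
import pytest

from adtherapy import (DiseaseState, ModelParameters, SwitchMode,
                       TreatmentInput, check_severe_cohort, effective_K,
                       effective_R, pathological_steady_state, rhs,
                       update_switch)
from adtherapy.simulate import TreatmentSchedule, simulate

ON = SwitchMode(r_on=True, k_on=True)
OFF = SwitchMode(r_on=False, k_on=False)


def untreated_fixed_point(p, mode):
    """Closed-form fixed point of the untreated dynamics at a frozen mode.

    dB/dt = 0 gives B* = prod/(prod + delta_B*K) with
    prod = kappa_B/((1+gamma_R*R)(1+gamma_G*G)); dP/dt = 0 then gives
    P* = kappa_P*P_env/(1+gamma_B*B*)/(alpha_I*R + delta_P), and
    dD/dt = 0 gives D* = kappa_D*R/delta_D.  Independent of the
    integration machinery.
    """
    R = p.R_on if mode.r_on else p.R_off
    K = p.K_on if mode.k_on else p.K_off
    prod = p.kappa_B / ((1 + p.gamma_R * R) * (1 + p.gamma_G * p.G))
    B = prod / (prod + p.delta_B * K)
    P = p.kappa_P * p.P_env / (1 + p.gamma_B * B) / (p.alpha_I * R + p.delta_P)
    D = p.kappa_D * R / p.delta_D
    return np.array([P, B, D])


class TestRhs:
    def test_zero_at_pathological_fixed_point(self, p, patho):
        d = rhs(patho, TreatmentInput(0.0, 0.0), p)
        assert np.max(np.abs(d)) < 1e-8

    def test_inflammation_balance_closed_form(self, p):
        # kappa_D*R_on/delta_D = 4*16.7/0.5 = 133.6 balances production/decay
        D_star = p.kappa_D * p.R_on / p.delta_D
        assert D_star == pytest.approx(133.6)
        s = DiseaseState(P=30.0, B=0.2, D=D_star, mode=ON)
        _, _, dD = rhs(s, TreatmentInput(0.0, 0.0), p)
        assert dD == pytest.approx(0.0, abs=1e-12)
        s2 = DiseaseState(P=30.0, B=0.2, D=100.0, mode=ON)
        _, _, dD2 = rhs(s2, TreatmentInput(0.0, 0.0), p)
        assert dD2 == pytest.approx(p.kappa_D * p.R_on - p.delta_D * 100.0)

    @pytest.mark.parametrize("mode", [ON, OFF])
    def test_corticosteroid_monotone_contract(self, p, mode, rng):
        """More potent C never raises dD/dt and never lowers dB/dt."""
        for _ in range(25):
            s = DiseaseState(P=float(rng.uniform(0, 60)),
                             B=float(rng.uniform(0, 1)),
                             D=float(rng.uniform(0, 150)), mode=mode)
            Cs = np.sort(rng.uniform(0, 50, size=4))
            dBs = [rhs(s, TreatmentInput(C=c, E=0.04), p)[1] for c in Cs]
            dDs = [rhs(s, TreatmentInput(C=c, E=0.04), p)[2] for c in Cs]
            assert np.all(np.diff(dBs) >= -1e-12)
            assert np.all(np.diff(dDs) <= 1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            TreatmentInput(C=-1.0)
        with pytest.raises(ValueError):
            DiseaseState(P=-1.0, B=0.5, D=0.0)
        with pytest.raises(ValueError):
            DiseaseState(P=1.0, B=1.5, D=0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(kappa_P=-1.0)
        with pytest.raises(ValueError):
            ModelParameters(P_minus=40.0, P_plus=26.6)


class TestSwitches:
    def test_effective_levels(self, p):
        assert effective_R(OFF, p) == 1.0
        assert effective_R(ON, p) == 16.7
        assert effective_K(OFF, p) == 1.0
        assert effective_K(ON, p) == p.K_on

    @pytest.mark.parametrize("mode,P,expect_r", [
        (OFF, 30.0, False),   # inside the band, stays off
        (ON, 30.0, True),     # inside the band, stays on (hysteresis)
        (ON, 26.0, False),    # below deactivation threshold
        (OFF, 41.0, True),    # above activation threshold
        (ON, 40.5, True),
        (OFF, 26.0, False),
    ])
    def test_hysteresis_rule(self, p, mode, P, expect_r):
        assert update_switch(mode, P, p).r_on is expect_r

    def test_k_switch_follows_its_own_thresholds(self):
        p = ModelParameters(K_minus=10.0, K_plus=20.0)
        m = update_switch(SwitchMode(r_on=True, k_on=True), 15.0, p)
        assert m.r_on is False and m.k_on is True  # 15 < P-: R off; in K band
        m2 = update_switch(m, 25.0, p)
        assert m2.k_on is True and m2.r_on is False


class TestPathologicalSteadyState:
    def test_invariance_under_untreated_simulation(self, p, patho):
        sched = TreatmentSchedule.constant(100.0, 0.0, 0.0)
        traj = simulate(patho, sched, p)
        end = traj.state_at_end()
        assert np.max(np.abs(end.y - patho.y)) < 1e-6
        assert end.mode == patho.mode
        assert traj.events == []

    def test_matches_algebraic_root(self, p, patho):
        expected = untreated_fixed_point(p, ON)
        assert patho.mode.r_on and patho.mode.k_on
        assert patho.y == pytest.approx(expected, rel=1e-6)
        assert patho.P > p.P_minus  # locked inside the hysteresis band

    def test_collapsed_barrier(self, patho):
        assert patho.B < 0.01

    def test_nonsevere_parameters_raise(self, p):
        with pytest.raises((ValueError, RuntimeError)):
            # strong innate immunity: the flare branch loses its band root
            pathological_steady_state(p.with_(alpha_I=1.0))


class TestSevereCohort:
    def test_nominal_and_barrier_compromised_are_severe(self, p):
        assert check_severe_cohort(p)
        assert check_severe_cohort(p.with_(kappa_P=0.95))

    def test_strong_innate_immunity_is_not_severe(self, p):
        # the OFF-branch fixed point drops below the activation threshold
        # once alpha_I > kappa_P*P_env/(1+gamma_B*B_off*)/P_plus - delta_P
        # (~0.103 nominally), creating a flare-free attractor
        prod = p.kappa_B / ((1 + p.gamma_R * p.R_off) * (1 + p.gamma_G * p.G))
        B_off = prod / (prod + p.delta_B * p.K_off)
        alpha_crit = (p.kappa_P * p.P_env / (1 + p.gamma_B * B_off)
                      / p.P_plus - p.delta_P)
        assert 0.09 < alpha_crit < 0.12
        assert not check_severe_cohort(p.with_(alpha_I=1.5 * alpha_crit))
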
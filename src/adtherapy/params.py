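"""Parameter containers for the AD treatment model and its optimal-control layer.

Three groups of constants drive everything downstream:

* :class:`ModelParameters` — rate constants, switch thresholds and
  corticosteroid-effect coefficients of the skin barrier / innate immunity
  model (time unit: days; stressor load in mg ml^-1).
* :class:`ObjectiveWeights` — penalty weights and target stressor levels of
  the induction- and maintenance-phase objective functions.
* :class:`ControlBounds` — box constraints on treatment potency and duration.
* :class:`DEConfig` — differential-evolution hyperparameters.

All defaults are the nominal values used throughout the scenario studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "ModelParameters",
    "ObjectiveWeights",
    "ControlBounds",
    "DEConfig",
    "SwitchMode",
    "DiseaseState",
    "TreatmentInput",
]


class _Switch(IntEnum):
    OFF = 0
    ON = 1


@dataclass(frozen=True)
class SwitchMode:
    """Discrete mode of the two hysteretic switches.

    ``r_on`` — innate immune receptors R (the AD flare indicator);
    ``k_on`` — kallikrein activity K (desquamation-driven barrier damage).
    """

    r_on: bool = False
    k_on: bool = False

    OFF = _Switch.OFF
    ON = _Switch.ON


@dataclass(frozen=True)
class DiseaseState:
    """Instantaneous disease status of a virtual patient.

    P: infiltrated stressor load (mg ml^-1, >= 0)
    B: skin barrier integrity (dimensionless, in [0, 1])
    D: inflammation-marker level (>= 0)
    mode: discrete switch modes for R and K
    """

    P: float
    B: float
    D: float
    mode: SwitchMode = field(default_factory=SwitchMode)

    def __post_init__(self) -> None:
        if self.P < 0 or self.D < 0:
            raise ValueError("P and D must be non-negative")
        if not (-1e-9 <= self.B <= 1 + 1e-9):
            raise ValueError("B must lie in [0, 1]")

    @property
    def y(self) -> np.ndarray:
        """Continuous state as a (3,) array (P, B, D)."""
        return np.array([self.P, self.B, self.D])


@dataclass(frozen=True)
class TreatmentInput:
    """Instantaneous treatment potencies: corticosteroid C and emollient E."""

    C: float = 0.0
    E: float = 0.0

    def __post_init__(self) -> None:
        if self.C < 0 or self.E < 0:
            raise ValueError("treatment potencies must be non-negative")


# Order of the packed parameter vector consumed by the integration kernels.
PARAM_ORDER = (
    "P_env", "gamma_B", "kappa_P", "alpha_I", "delta_P",
    "kappa_B", "gamma_R", "delta_B", "gamma_G",
    "kappa_D", "delta_D",
    "P_minus", "P_plus", "R_off", "R_on",
    "K_minus", "K_plus", "K_off", "K_on",
    "G", "beta_1", "beta_2", "beta_3", "beta_4",
)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and switch levels of the treated AD dynamics.

    Defaults are the nominal severe-patient values.  ``kappa_P`` (skin
    permeability, day^-1) and ``alpha_I`` (innate eradication rate, day^-1)
    encode the two genetic risk axes used to define virtual patient cohorts.
    The kallikrein switch shares the stressor load P as its driver; its
    thresholds default to the receptor thresholds and its on-level to 2
    (see docs/methods.md for the rationale); all four are configurable.
    """

    P_env: float = 95.0      # environmental stress load (mg ml^-1)
    gamma_B: float = 1.0     # barrier-mediated inhibition of infiltration
    kappa_P: float = 0.85    # nominal skin permeability (day^-1)
    alpha_I: float = 0.05    # innate eradication rate (day^-1)
    delta_P: float = 1.6     # basal pathogen death rate (day^-1)
    kappa_B: float = 0.5     # barrier production rate (day^-1)
    gamma_R: float = 10.0    # innate-immunity inhibition of barrier production
    delta_B: float = 0.1     # kallikrein-dependent barrier degradation
    gamma_G: float = 1.0     # adaptive-immunity inhibition of barrier production
    kappa_D: float = 4.0     # DC activation rate (cells (ml day)^-1)
    delta_D: float = 0.5     # DC degradation rate (day^-1)
    P_minus: float = 26.6    # receptor inactivation threshold (mg ml^-1)
    P_plus: float = 40.0     # receptor activation threshold (mg ml^-1)
    R_off: float = 1.0       # receptor-off level
    R_on: float = 16.7       # receptor-on level
    K_minus: float = 26.6    # kallikrein switch lower threshold (driver: P)
    K_plus: float = 40.0     # kallikrein switch upper threshold (driver: P)
    K_off: float = 1.0       # kallikrein-off level
    K_on: float = 2.0        # kallikrein-on level
    G: float = 1.0           # fixed Gata-3 level (systemic Th2 sensitization)
    beta_1: float = 0.005    # corticosteroid reduction of AMP-mediated eradication
    beta_2: float = 10.0     # corticosteroid reduction of barrier damage
    beta_3: float = 10.0     # corticosteroid reduction of Th2 cytokine production
    beta_4: float = 10.0     # corticosteroid reduction of DC maturation

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if not self.P_minus < self.P_plus:
            raise ValueError("need P_minus < P_plus (hysteresis band)")
        if not self.K_minus < self.K_plus:
            raise ValueError("need K_minus < K_plus (hysteresis band)")
        if self.R_off > self.R_on:
            raise ValueError("need R_off <= R_on")

    def with_(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given symbols replaced."""
        return replace(self, **overrides)

    def as_array(self) -> np.ndarray:
        """Pack into the (24,) float vector used by the integration kernels."""
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=np.float64)


@dataclass(frozen=True)
class ObjectiveWeights:
    """Penalty weights and target stressor levels.

    k1 multiplies the duration penalty, k2 the amount (duration x strength)
    penalty, k3 the final-state deviation (which carries the non-convex
    remission/flare penalty) and k4 the integrated trajectory deviation.
    The nominal configuration has k3 = k4.
    """

    k1: float = 0.5
    k2: float = 1.0
    k3: float = 10.0
    k4: float = 10.0
    P_target_induction: float = 24.0
    P_target_maintenance: float = 26.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def with_(self, **overrides: float) -> "ObjectiveWeights":
        return replace(self, **overrides)


@dataclass(frozen=True)
class ControlBounds:
    """Box constraints of the two planning problems (time unit: days)."""

    C_max_induction: float = 50.0
    C_max_maintenance: float = 50.0
    T_r_max: float = 56.0    # 8 weeks
    T_m: float = 7.0         # weekly maintenance cycle
    E_bar: float = 0.04      # constant emollient potency

    def __post_init__(self) -> None:
        if min(self.C_max_induction, self.C_max_maintenance,
               self.T_r_max, self.T_m) <= 0:
            raise ValueError("bounds must be positive")
        if self.E_bar < 0:
            raise ValueError("E_bar must be >= 0")

    def with_(self, **overrides: float) -> "ControlBounds":
        return replace(self, **overrides)


@dataclass(frozen=True)
class DEConfig:
    """Differential evolution settings (strategy DE/rand-to-best/1).

    The population is evolved for a fixed number of generations with
    differential weight ``F`` and binomial crossover rate ``CR``; there is
    no early stopping.
    """

    population_size: int = 30
    generations: int = 1000
    F: float = 0.6
    CR: float = 0.5
    seed: int = 0
    strategy: str = "rand-to-best/1"

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("DE/rand-to-best/1 needs a population of >= 4")
        if not 0 < self.CR <= 1:
            raise ValueError("need 0 < CR <= 1")
        if self.F <= 0:
            raise ValueError("need F > 0")
        if self.generations < 1:
            raise ValueError("need at least one generation")
        if self.strategy != "rand-to-best/1":
            raise ValueError(f"unsupported DE strategy: {self.strategy!r}")

    def with_(self, **overrides) -> "DEConfig":
        return replace(self, **overrides)
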
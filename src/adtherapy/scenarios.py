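"""Scenario drivers: maintenance-target sweeps, cohort stratification and
global sensitivity analysis.

All comparative quantities (fold-changes of corticosteroid amount, schedule
structure) are computed against a nominal baseline run under a common master
seed, so differences reflect the scenario and not optimizer noise.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import pathological_steady_state
from .objectives import induction_objective
from .params import (ControlBounds, DEConfig, ModelParameters,
                     ObjectiveWeights)
from .planner import ProactiveResult, plan_induction, run_proactive_therapy

__all__ = [
    "CohortSpec",
    "ComparisonReport",
    "modal_on_days",
    "sweep_maintenance_target",
    "run_cohorts",
    "global_sensitivity",
]

#: Table 2 rate constants and switch levels subject to global perturbation
MODEL_SENSITIVITY_PARAMS = (
    "P_env", "gamma_B", "kappa_P", "alpha_I", "delta_P",
    "kappa_B", "gamma_R", "delta_B", "gamma_G", "kappa_D", "delta_D",
    "P_minus", "P_plus", "R_off", "R_on",
)
WEIGHT_SENSITIVITY_PARAMS = ("k1", "k2", "k3", "k4")


@dataclass(frozen=True)
class CohortSpec:
    """A virtual patient cohort, defined by its genetic risk parameters."""

    label: str
    kappa_P: float
    alpha_I: float
    overrides: dict = field(default_factory=dict)

    def parameters(self, base: ModelParameters) -> ModelParameters:
        return base.with_(kappa_P=self.kappa_P, alpha_I=self.alpha_I,
                          **self.overrides)


@dataclass
class ComparisonReport:
    """Per-scenario plan summaries with fold-changes against the baseline."""

    rows: pd.DataFrame
    baseline_label: str
    results: dict = field(default_factory=dict)  # label -> ProactiveResult

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.rows.to_dict(orient="records"), fh, indent=2,
                      default=float)


def modal_on_days(result: ProactiveResult) -> int:
    """Most common number of corticosteroid on-days per maintenance cycle."""
    days = [c["suggested_days"] for c in result.cycles]
    return int(Counter(days).most_common(1)[0][0])


def _summary_row(label: str, res: ProactiveResult, base: dict | None) -> dict:
    amounts = res.amounts()
    row = {
        "label": label,
        "T_r": res.induction.T_r,
        "C_bar": res.induction.C_bar,
        "on_days_per_week": modal_on_days(res),
        "induction_amount": amounts["induction"],
        "maintenance_amount": amounts["maintenance"],
        "total_amount": amounts["total"],
        "remission_achieved": res.induction.remission_achieved,
        "flare_recurrences": res.flare_recurrences,
    }
    if base is not None:
        for phase in ("induction", "maintenance", "total"):
            denom = base[phase]
            row[f"{phase}_fold"] = (amounts[phase] / denom
                                    if denom > 0 else np.inf)
    return row


def sweep_maintenance_target(targets, p: ModelParameters, w: ObjectiveWeights,
                             b: ControlBounds, de_config: DEConfig,
                             n_cycles: int = 8) -> ComparisonReport:
    """Full proactive-therapy runs for a list of maintenance target levels.

    The run at the nominal target (``w.P_target_maintenance``) is the
    baseline for all fold-changes; it is added if absent from ``targets``.
    """
    targets = list(targets)
    nominal = w.P_target_maintenance
    if not any(abs(t - nominal) < 1e-12 for t in targets):
        targets.insert(0, nominal)
    for t in targets:
        if t >= p.P_plus:
            raise ValueError(f"maintenance target {t} must lie below the "
                             f"activation threshold {p.P_plus}")

    init = pathological_steady_state(p)
    results = {}
    for targ in targets:
        wt = w.with_(P_target_maintenance=float(targ))
        results[targ] = run_proactive_therapy(p, wt, b, de_config,
                                              n_cycles=n_cycles, init=init)
    base = results[nominal].amounts()
    rows = pd.DataFrame([
        _summary_row(f"target={targ:g}", results[targ],
                     base) | {"maintenance_target": targ}
        for targ in targets])
    return ComparisonReport(rows=rows, baseline_label=f"target={nominal:g}",
                            results={f"target={t:g}": r
                                     for t, r in results.items()})


def run_cohorts(cohorts, p: ModelParameters, w: ObjectiveWeights,
                b: ControlBounds, de_config: DEConfig,
                n_cycles: int = 8) -> ComparisonReport:
    """Optimal proactive therapy per cohort, compared with the nominal cohort.

    Cohorts for which the optimizer cannot achieve remission are flagged
    (``remission_achieved`` False): they stratify as requiring stronger or
    systemic treatment rather than the calculated schedules.
    """
    nominal = CohortSpec("nominal", p.kappa_P, p.alpha_I)
    all_cohorts = [nominal] + [c for c in cohorts
                               if not (c.kappa_P == p.kappa_P
                                       and c.alpha_I == p.alpha_I
                                       and not c.overrides)]
    results = {}
    for spec in all_cohorts:
        pc = spec.parameters(p)
        results[spec.label] = run_proactive_therapy(pc, w, b, de_config,
                                                    n_cycles=n_cycles)
    base = results["nominal"].amounts()
    rows = pd.DataFrame([
        _summary_row(spec.label, results[spec.label], base)
        | {"kappa_P": spec.kappa_P, "alpha_I": spec.alpha_I}
        for spec in all_cohorts])
    return ComparisonReport(rows=rows, baseline_label="nominal",
                            results=results)


def _draw_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master), 7919, int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def global_sensitivity(p: ModelParameters, w: ObjectiveWeights,
                       b: ControlBounds, de_config: DEConfig,
                       which: str = "model_params",
                       perturbation: float = 0.5,
                       n_samples: int | None = None,
                       mode: str = "reoptimize",
                       seed: int | None = None) -> dict:
    """Global sensitivity of the optimal induction strategy.

    Draws ``n_samples`` joint multiplicative perturbations, uniform within
    ``1 +/- perturbation``, of either the model rate constants
    (``which='model_params'``, default n=529) or the objective weights
    (``which='weights'``, default n=400).  Per draw the induction problem is
    re-optimized by DE (``mode='reoptimize'``) or the nominal optimal
    schedule is re-evaluated under the perturbed system
    (``mode='reevaluate'``).  Draws producing invalid parameterizations or
    failing to reach a pathological steady state are excluded and counted.

    Returns a dict with the per-draw DataFrame, the nominal reference, the
    exclusion count and robustness summaries.
    """
    if which == "model_params":
        names = MODEL_SENSITIVITY_PARAMS
        n_samples = 529 if n_samples is None else n_samples
    elif which == "weights":
        names = WEIGHT_SENSITIVITY_PARAMS
        n_samples = 400 if n_samples is None else n_samples
    else:
        raise ValueError(f"unknown sensitivity set {which!r}")
    if not 0 <= perturbation < 1:
        raise ValueError("perturbation must lie in [0, 1)")
    if mode not in ("reoptimize", "reevaluate"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_samples < 1:
        raise ValueError("need at least one sample")

    master = de_config.seed if seed is None else seed
    rng = np.random.default_rng(master)

    nominal = plan_induction(p, w, b, de_config)
    nominal_row = {"T_r": nominal.T_r, "C_bar": nominal.C_bar,
                   "amount": nominal.T_r * nominal.C_bar,
                   "J": nominal.objective.J,
                   "remission": nominal.remission_achieved}

    rows, n_excluded = [], 0
    for i in range(n_samples):
        factors = 1.0 + perturbation * (2.0 * rng.random(len(names)) - 1.0)
        try:
            if which == "model_params":
                pi = p.with_(**{k: getattr(p, k) * f
                                for k, f in zip(names, factors)})
                wi = w
            else:
                pi = p
                wi = w.with_(**{k: getattr(w, k) * f
                                for k, f in zip(names, factors)})
            if mode == "reoptimize":
                cfg = de_config.with_(seed=de_config.seed if perturbation == 0
                                      else _draw_seed(master, i))
                res = plan_induction(pi, wi, b, cfg)
                row = {"T_r": res.T_r, "C_bar": res.C_bar,
                       "amount": res.T_r * res.C_bar,
                       "J": res.objective.J,
                       "remission": res.remission_achieved}
            else:
                init = pathological_steady_state(pi)
                bd = induction_objective(float(nominal.T_r), nominal.C_bar,
                                         pi, wi, b, init)
                row = {"T_r": nominal.T_r, "C_bar": nominal.C_bar,
                       "amount": nominal.T_r * nominal.C_bar, "J": bd.J,
                       "remission": bd.phi == 0.0}
        except (ValueError, RuntimeError):
            n_excluded += 1
            continue
        rows.append(row | {"draw": i}
                    | {f"factor_{k}": f for k, f in zip(names, factors)})

    df = pd.DataFrame(rows)
    summary = {"which": which, "mode": mode, "perturbation": perturbation,
               "n_samples": n_samples, "n_excluded": n_excluded,
               "nominal": nominal_row, "draws": df}
    if len(df):
        summary["fraction_same_T_r"] = float(np.mean(df["T_r"] == nominal.T_r))
        summary["fraction_remission"] = float(np.mean(df["remission"]))
        summary["T_r_quantiles"] = {
            q: float(np.quantile(df["T_r"], q)) for q in (0.05, 0.5, 0.95)}
        summary["J_quantiles"] = {
            q: float(np.quantile(df["J"], q)) for q in (0.05, 0.5, 0.95)}
    return summary
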
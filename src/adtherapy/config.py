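"""Experiment configuration: YAML loading, validation and result bundles.

A configuration file is a nested mapping with blocks ``model`` (rate
constants, keyed by their ascii symbol names: ``kappa_P``, ``alpha_I``,
``P_minus``, ...), ``weights``, ``bounds``, ``de`` and ``experiment``.
Every omitted key falls back to its nominal default, so an empty file is the
nominal experiment; unknown keys are rejected with their path.  Each run
writes its fully-resolved configuration next to its outputs, and every JSON
artifact embeds the resolved-config hash, the master seed and the package
version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .params import ControlBounds, DEConfig, ModelParameters, ObjectiveWeights
from .planner import AdherenceScenario, run_proactive_therapy
from .scenarios import (CohortSpec, global_sensitivity, modal_on_days,
                        run_cohorts, sweep_maintenance_target)

__all__ = ["ExperimentConfig", "load_config", "dump_config", "run_experiment"]

log = logging.getLogger("adtherapy")

SCENARIOS = ("nominal", "target-sweep", "cohorts", "adherence", "sensitivity")


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully-resolved settings of one reproducible experiment."""

    model: ModelParameters = field(default_factory=ModelParameters)
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    bounds: ControlBounds = field(default_factory=ControlBounds)
    de: DEConfig = field(default_factory=DEConfig)
    scenario: str = "nominal"
    n_cycles: int = 8
    seed: int = 0
    out_dir: str = "out"
    # scenario-specific settings
    sweep_targets: tuple = (26.0, 32.0, 22.0)
    cohorts: tuple = ((0.85, 0.04), (0.85, 0.03), (0.9, 0.05),
                      (0.95, 0.05), (0.9, 0.04))
    adherence_induction_c_days: int | None = 5
    adherence_induction_e_on: bool = True
    adherence_cycle_overrides: tuple = ()   # ((cycle, c_on, e_on), ...)
    sensitivity_which: str = "model_params"
    sensitivity_perturbation: float = 0.5
    sensitivity_samples: int | None = None
    sensitivity_mode: str = "reoptimize"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    def hash(self) -> str:
        d = self.resolved()
        d.pop("out_dir")  # incidental to the science; keeps runs comparable
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_BLOCKS = {
    "model": ModelParameters,
    "weights": ObjectiveWeights,
    "bounds": ControlBounds,
    "de": DEConfig,
}

_TOP_KEYS = ("scenario", "n_cycles", "seed", "out_dir", "sweep_targets",
             "cohorts", "adherence_induction_c_days",
             "adherence_induction_e_on", "adherence_cycle_overrides",
             "sensitivity_which", "sensitivity_perturbation",
             "sensitivity_samples", "sensitivity_mode")


def load_config(path=None, overrides: dict | None = None) -> ExperimentConfig:
    """Load and validate a YAML configuration.

    ``path`` None or an empty file yields the full nominal defaults.
    ``overrides`` (same nesting as the file) are applied on top — used by
    the command line.  Unknown keys raise with their path.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw)}")
    for key, sub in (overrides or {}).items():
        if isinstance(sub, dict):
            raw.setdefault(key, {})
            raw[key].update(sub)
        else:
            raw[key] = sub

    kwargs: dict = {}
    for block, cls in _BLOCKS.items():
        sub = raw.pop(block, {}) or {}
        if not isinstance(sub, dict):
            raise ValueError(f"config block {block!r} must be a mapping")
        if block == "bounds" and "T_r_max_weeks" in sub:
            sub["T_r_max"] = 7.0 * float(sub.pop("T_r_max_weeks"))
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sub) - valid
        if unknown:
            raise ValueError(f"unknown key(s) {block}.{sorted(unknown)}")
        try:
            kwargs[block] = cls(**sub)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid {block} configuration: {exc}") from exc

    unknown = set(raw) - set(_TOP_KEYS)
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    for k in _TOP_KEYS:
        if k in raw:
            v = raw[k]
            if isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            kwargs[k] = v
    cfg = ExperimentConfig(**kwargs)
    # the master seed drives the optimizer unless the DE block pins its own
    if cfg.de.seed == 0 and cfg.seed != 0:
        cfg = dataclasses.replace(cfg, de=cfg.de.with_(seed=cfg.seed))
    return cfg


def dump_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.resolved(), fh, sort_keys=True)


def _artifact(cfg: ExperimentConfig, payload: dict) -> dict:
    return {"config_hash": cfg.hash(), "seed": cfg.seed,
            "version": __version__} | payload


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the configured scenario and write the output bundle.

    Writes plan JSON, trajectory CSV (+ events JSON), report CSV/JSON and
    the resolved config into ``cfg.out_dir``; returns the report dict.
    Deterministic for a given master seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "resolved_config.yaml")
    p, w, b, de = cfg.model, cfg.weights, cfg.bounds, cfg.de
    log.info("scenario=%s seed=%d generations=%d", cfg.scenario, cfg.seed,
             de.generations)

    report: dict
    if cfg.scenario in ("nominal", "adherence"):
        scenario = None
        if cfg.scenario == "adherence":
            scenario = AdherenceScenario(
                induction_c_days=cfg.adherence_induction_c_days,
                induction_e_on=cfg.adherence_induction_e_on,
                cycle_overrides={int(c): (bool(con), bool(eon))
                                 for c, con, eon in cfg.adherence_cycle_overrides})
        res = run_proactive_therapy(p, w, b, de, n_cycles=cfg.n_cycles,
                                    scenario=scenario)
        res.trajectory.export(out / "trajectory.csv", out / "events.json", p)
        plan = {
            "induction": {"T_r": res.induction.T_r,
                          "C_bar": res.induction.C_bar,
                          "remission_achieved": res.induction.remission_achieved},
            "maintenance_cycles": [
                {"cycle": c["cycle"], "on_days": c["suggested_days"],
                 "potency": c["suggested_potency"],
                 "applied_c": c["applied_c"], "applied_e": c["applied_e"]}
                for c in res.cycles],
            "emollient": b.E_bar,
            "amounts": res.amounts(),
            "modal_on_days": modal_on_days(res),
            "flare_recurrences": res.flare_recurrences,
        }
        _write_json(out / "plan.json", _artifact(cfg, plan))
        report = plan
        _write_json(out / "report.json", _artifact(cfg, report))
    elif cfg.scenario == "target-sweep":
        rep = sweep_maintenance_target(list(cfg.sweep_targets), p, w, b, de,
                                       n_cycles=cfg.n_cycles)
        rep.to_csv(out / "report.csv")
        report = {"rows": rep.rows.to_dict(orient="records")}
        _write_json(out / "report.json", _artifact(cfg, report))
    elif cfg.scenario == "cohorts":
        specs = [CohortSpec(f"kP={kp:g},aI={ai:g}", kp, ai)
                 for kp, ai in cfg.cohorts]
        rep = run_cohorts(specs, p, w, b, de, n_cycles=cfg.n_cycles)
        rep.to_csv(out / "report.csv")
        report = {"rows": rep.rows.to_dict(orient="records")}
        _write_json(out / "report.json", _artifact(cfg, report))
    else:  # sensitivity
        summ = global_sensitivity(p, w, b, de, which=cfg.sensitivity_which,
                                  perturbation=cfg.sensitivity_perturbation,
                                  n_samples=cfg.sensitivity_samples,
                                  mode=cfg.sensitivity_mode, seed=cfg.seed)
        draws = summ.pop("draws")
        draws.to_csv(out / "draws.csv", index=False)
        report = summ
        _write_json(out / "report.json", _artifact(cfg, report))
    return report
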
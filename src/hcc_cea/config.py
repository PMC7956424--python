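"""Configuration and pipeline layer.

A :class:`RunConfig` (YAML or JSON on disk) binds model settings, a
long-term survival scenario, parameter overrides and analysis toggles into
one validated, reproducible run.  Unknown keys are rejected; an empty file
reproduces the published base case.  ``run_pipeline`` writes a
deterministic file set (summary JSON plus delimiter-separated tables);
rerunning with the same config and seed is byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .analyses import one_way_dsa, price_threshold, psa
from .cohort_model import ModelSettings, run_cohort
from .parameters import PARAMETERS, build_strategies
from .scenarios import ScenarioSpec, apply_duration_cap
from .synthetic_data import LifeTable, default_life_table

__all__ = ["RunConfig", "load_config", "run_pipeline"]


class SettingsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cycle_days: float = 21.0
    horizon_years: float = Field(5.0, gt=0)
    discount_rate: float = Field(0.03, ge=0, lt=1)
    start_age: float = Field(65.0, ge=18, le=100)
    wtp_thresholds: list[float] = [100_000.0, 150_000.0]
    half_cycle_correction: bool = True

    def build(self) -> ModelSettings:
        return ModelSettings(
            cycle_days=self.cycle_days,
            horizon_years=self.horizon_years,
            discount_rate=self.discount_rate,
            start_age=self.start_age,
            wtp_thresholds=tuple(self.wtp_thresholds),
            half_cycle_correction=self.half_cycle_correction,
        )


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["extrapolate", "pessimistic", "optimistic"] = "extrapolate"
    switch_time: float = Field(17.0, gt=0)
    anchor_3yr: float = Field(0.278, gt=0, lt=1)

    def build(self) -> ScenarioSpec:
        return ScenarioSpec(mode=self.mode, switch_time=self.switch_time,
                            anchor_3yr=self.anchor_3yr)


class PSAConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    n_iter: int = Field(100_000, ge=1)
    wtp_grid_max: float = 300_000.0
    wtp_grid_step: float = 25_000.0


class RunConfig(BaseModel):
    """Validated end-to-end run description."""

    model_config = ConfigDict(extra="forbid")
    settings: SettingsConfig = SettingsConfig()
    scenario: ScenarioConfig = ScenarioConfig()
    overrides: dict[str, float] = {}
    societal: bool = False
    duration_cap_months: float | None = None
    run_dsa: bool = False
    psa: PSAConfig = PSAConfig()
    price_threshold_wtps: list[float] = []
    life_table_csv: str | None = None
    seed: int = 0
    output_dir: str = "results"

    @field_validator("overrides")
    @classmethod
    def _check_overrides(cls, v: dict[str, float]) -> dict[str, float]:
        for key, val in v.items():
            if key not in PARAMETERS:
                raise ValueError(f"overrides.{key}: unknown parameter")
            if PARAMETERS[key].is_cost and val < 0:
                raise ValueError(f"overrides.{key}: cost must be non-negative")
        return v

    def life_table(self) -> LifeTable:
        if self.life_table_csv:
            return LifeTable.from_csv(self.life_table_csv)
        return default_life_table()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config; empty file = base case."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return RunConfig.model_validate(data)


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the configured analyses and write results to disk.

    Writes ``summary.json`` (both arms' outcomes and their comparison),
    per-arm Markov traces, and optional tornado/CEAC tables.  All output is
    deterministic given the config and seed.  Returns the summary dict.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    settings = config.settings.build()
    scenario = config.scenario.build()
    life_table = config.life_table()
    values = dict(config.overrides)

    ab, sor = build_strategies(values or None, societal=config.societal)
    if config.duration_cap_months is not None:
        ab = apply_duration_cap(ab, config.duration_cap_months)
    trace_ab, out_ab = run_cohort(ab, settings, life_table, scenario=scenario)
    trace_sor, out_sor = run_cohort(sor, settings, life_table)
    trace_ab.to_csv(out / "trace_atezo_bev.csv")
    trace_sor.to_csv(out / "trace_sorafenib.csv")

    from .analyses import compare  # local import keeps module load cheap

    cmp_ = compare(out_ab, out_sor, settings.wtp_thresholds)
    summary: dict = {
        "arms": {
            ab.name: {
                "total_cost": round(float(out_ab.total_cost), 2),
                "life_years": round(float(out_ab.life_years), 4),
                "qalys": round(float(out_ab.qalys), 4),
            },
            sor.name: {
                "total_cost": round(float(out_sor.total_cost), 2),
                "life_years": round(float(out_sor.life_years), 4),
                "qalys": round(float(out_sor.qalys), 4),
            },
        },
        "comparison": {
            "delta_cost": round(cmp_.delta_cost, 2),
            "delta_qalys": round(cmp_.delta_qalys, 4),
            "delta_life_years": round(cmp_.delta_life_years, 4),
            "icer_per_qaly": cmp_.icer if isinstance(cmp_.icer, str)
            else round(cmp_.icer, 2),
            "icer_per_life_year": cmp_.icer_per_life_year
            if isinstance(cmp_.icer_per_life_year, str)
            else round(cmp_.icer_per_life_year, 2),
            "nmb": {f"{int(w)}": round(v, 2) for w, v in cmp_.nmb.items()},
        },
        "scenario": config.scenario.model_dump(),
        "seed": config.seed,
    }

    if config.run_dsa:
        tornado = one_way_dsa(scenario=scenario, settings=settings,
                              life_table=life_table)
        tornado.to_csv(out / "tornado.csv", index=False, float_format="%.6f")
        summary["dsa_top_parameter"] = str(tornado.iloc[0]["parameter"])

    if config.psa.enabled:
        res = psa(n_iter=config.psa.n_iter, seed=config.seed,
                  scenario=scenario, settings=settings, life_table=life_table,
                  societal=config.societal)
        import numpy as np

        wtps = np.arange(0.0, config.psa.wtp_grid_max + 1e-9,
                         config.psa.wtp_grid_step)
        ceac = res.ceac(wtps)
        ceac.to_csv(out / "ceac.csv", index=False, float_format="%.6f")
        summary["psa"] = {
            "n_iter": res.n_iter,
            "acceptability": {
                f"{int(w)}": round(res.acceptability(w), 4)
                for w in settings.wtp_thresholds
            },
            "icer_point": round(res.icer_point(), 2),
        }

    for wtp in config.price_threshold_wtps:
        summary.setdefault("price_thresholds", {})[f"{int(wtp)}"] = round(
            price_threshold(wtp, scenario=scenario, settings=settings,
                            life_table=life_table), 4
        )

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
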
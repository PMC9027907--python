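"""Run configuration: YAML/JSON schema, validation, and result serialization.

A run configuration names a design (preset or explicit wiring), a set of
response scenarios, interim counts, replicate count and seed, and is validated
with pydantic before any simulation starts. :func:`run_from_config` executes
the grid and writes tidy CSV/JSON operating-characteristics tables plus a run
manifest echoing the configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import __version__
from .designs import DESIGN_PRESETS, Boundaries, DesignSpec, design_preset
from .inference import PosteriorSettings
from .priors import COMMUNITY_LABELS, VariancePrior
from .simulator import (
    SCENARIO_PRESETS,
    AccrualModel,
    Scenario,
    scenario_preset,
)

__all__ = [
    "RunConfig",
    "load_config",
    "run_from_config",
    "preset_catalog",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid run configuration (schema violations carry field paths)."""


class BoundariesModel(BaseModel):
    early_success: float = 0.998
    early_futility: float = 0.70
    late_success: float = 0.975
    late_futility: float = 0.85

    def build(self) -> Boundaries:
        return Boundaries(**self.model_dump())


class DesignModel(BaseModel):
    """Either ``preset`` or an explicit prior wiring (not both)."""

    preset: Optional[str] = None
    name: str = "custom"
    success_prior: Optional[str] = None
    futility_prior: Optional[str] = None
    late_success_prior: Optional[str] = None
    late_futility_prior: Optional[str] = None
    boundaries: BoundariesModel = Field(default_factory=BoundariesModel)

    @model_validator(mode="after")
    def _check(self):
        if self.preset is not None:
            if self.preset not in DESIGN_PRESETS:
                raise ValueError(
                    f"unknown design preset {self.preset!r}; "
                    f"expected one of {sorted(DESIGN_PRESETS)}"
                )
            return self
        if self.late_success_prior is None or self.late_futility_prior is None:
            raise ValueError(
                "an explicit design needs late_success_prior and late_futility_prior"
            )
        valid = set(COMMUNITY_LABELS) | {"p_value"}
        for fieldname in (
            "success_prior",
            "futility_prior",
            "late_success_prior",
            "late_futility_prior",
        ):
            lab = getattr(self, fieldname)
            if lab is not None and lab not in valid:
                raise ValueError(f"{fieldname}={lab!r} is not a known prior label")
        return self

    def build(self) -> DesignSpec:
        bounds = self.boundaries.build()
        if self.preset is not None:
            return design_preset(self.preset).with_boundaries(bounds)
        return DesignSpec(
            name=self.name,
            success_prior=self.success_prior,
            futility_prior=self.futility_prior,
            late_success_prior=self.late_success_prior,
            late_futility_prior=self.late_futility_prior,
            boundaries=bounds,
        )


class ScenarioModel(BaseModel):
    preset: Optional[str] = None
    label: str = "custom"
    control_mean: float = 0.0
    treatment_mean: float = 0.0
    subject_sd: float = 0.07

    @model_validator(mode="after")
    def _check(self):
        if self.preset is not None and self.preset not in SCENARIO_PRESETS:
            raise ValueError(
                f"unknown scenario preset {self.preset!r}; "
                f"expected one of {sorted(SCENARIO_PRESETS)}"
            )
        return self

    def build(self) -> Scenario:
        if self.preset is not None:
            return scenario_preset(self.preset)
        return Scenario(self.label, self.control_mean, self.treatment_mean, self.subject_sd)


class AccrualModelConfig(BaseModel):
    mean_rate: float = 2.0
    visit_delay: float = 12.0
    dropout_rate: float = 0.0
    kind: str = "poisson"

    def build(self) -> AccrualModel:
        return AccrualModel(**self.model_dump())


class VariancePriorModel(BaseModel):
    weight: float = 1.0
    scale: float = 0.07

    def build(self) -> VariancePrior:
        return VariancePrior(**self.model_dump())


class PosteriorModel(BaseModel):
    draws: int = 4500
    burn_in: int = 500
    seed: int = 0
    estimator: str = "sigma_marginal_quadrature"
    grid_size: int = 160

    def build(self) -> PosteriorSettings:
        return PosteriorSettings(**self.model_dump())


class RunConfig(BaseModel):
    """Top-level schema for a simulation run."""

    design: DesignModel
    scenarios: list[ScenarioModel] = Field(min_length=1)
    interim_counts: list[int] = Field(default=[6], min_length=1)
    n_sims: int = Field(default=1000, ge=1)
    seed: int
    max_n: int = Field(default=256, ge=4)
    accrual: AccrualModelConfig = Field(default_factory=AccrualModelConfig)
    variance_prior: VariancePriorModel = Field(default_factory=VariancePriorModel)
    posterior: PosteriorModel = Field(default_factory=PosteriorModel)
    interim_data: str = "completed"
    common_random_numbers: bool = True
    write_traces: bool = False
    output_dir: str = "commtrial_out"

    @model_validator(mode="after")
    def _check(self):
        if self.interim_data not in ("completed", "concurrent"):
            raise ValueError("interim_data must be 'completed' or 'concurrent'")
        for k in self.interim_counts:
            if not 0 <= k < self.max_n:
                raise ValueError(f"interim count {k} outside [0, max_n)")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            "/".join(str(loc) for loc in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: {paths}") from exc


def _write_traces_csv(traces, design_name: str, path: Path) -> None:
    rows = []
    n_looks = traces.n_looks
    for i in range(traces.n_sims):
        for j in range(n_looks + 1):
            row = {
                "sim": i,
                "scenario": traces.scenario.label,
                "design": design_name,
                "look": j + 1 if j < n_looks else "final",
                "n_control": int(traces.n_c[i, j]),
                "n_treatment": int(traces.n_t[i, j]),
            }
            for label, arr in traces.probs.items():
                row[f"prob_{label}"] = arr[i, j]
            if traces.p_values is not None:
                row["p_value"] = traces.p_values[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def run_from_config(path: str | Path, verbose: bool = False) -> Path:
    """Execute the configured grid; returns the output directory.

    Writes ``oc.csv`` and ``oc.json`` (tidy operating characteristics),
    optional per-look trace CSVs, and ``manifest.json`` (config echo, seed,
    package version). Partial outputs are removed if the run fails.
    """
    from .oc import oc_grid  # local import keeps module load light
    from .simulator import apply_design, build_interim_schedule, simulate_traces

    cfg = load_config(path)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        spec = cfg.design.build()
        scenarios = [s.build() for s in cfg.scenarios]
        table = oc_grid(
            [spec],
            scenarios,
            cfg.interim_counts,
            n_sims=cfg.n_sims,
            seed=cfg.seed,
            accrual=cfg.accrual.build(),
            vprior=cfg.variance_prior.build(),
            settings=cfg.posterior.build(),
            max_n=cfg.max_n,
            common_random_numbers=cfg.common_random_numbers,
            interim_data=cfg.interim_data,
        )
        oc_csv = out / "oc.csv"
        table.to_csv(oc_csv, index=False)
        written.append(oc_csv)
        oc_json = out / "oc.json"
        oc_json.write_text(json.dumps(table.to_dict(orient="records"), indent=2))
        written.append(oc_json)
        if cfg.write_traces:
            for scenario in scenarios:
                for k in cfg.interim_counts:
                    schedule = build_interim_schedule(k, cfg.max_n)
                    traces = simulate_traces(
                        spec, scenario,
                        cfg.accrual.build(), schedule,
                        cfg.variance_prior.build(), cfg.posterior.build(),
                        n_sims=cfg.n_sims, seed=cfg.seed,
                        interim_data=cfg.interim_data,
                    )
                    tpath = out / f"trace_{scenario.label}_{k}interims.csv"
                    _write_traces_csv(traces, spec.name, tpath)
                    written.append(tpath)
                    if verbose:
                        print(f"wrote {tpath}")
        manifest = {
            "config": cfg.model_dump(),
            "seed": cfg.seed,
            "commtrial_version": __version__,
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        written.append(mpath)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return out


def preset_catalog() -> dict:
    """Named presets: the six designs, five scenarios, and interim schedules."""
    from .simulator import _SCHEDULE_TABLE

    return {
        "designs": dict(DESIGN_PRESETS),
        "scenarios": dict(SCENARIO_PRESETS),
        "schedules": {k: list(v) for k, v in sorted(_SCHEDULE_TABLE.items())},
    }
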
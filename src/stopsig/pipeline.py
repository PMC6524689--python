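"""Pipeline orchestration: simulate -> estimate -> analyze as one command.

A :class:`PipelineConfig` (read from YAML or JSON) fully determines a run:
the task design, the cohort's generative parameters, the master seed, and
the analysis options. ``run_pipeline`` executes the three stages, logging one
structured record per stage, and writes the trial CSV, the per-participant
summary CSV, and the report (JSON + markdown). Reports are validated with
pydantic models; the equivalent JSON schema is bundled under
``stopsig/schemas/report.schema.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import model as model_mod
from . import ssrt, task
from .exceptions import ConfigError

log = logging.getLogger("stopsig")

__all__ = [
    "PipelineConfig",
    "default_config",
    "load_config",
    "run_pipeline",
    "make_fixtures",
    "validate_report",
]


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trials: int = 288
    stop_fraction: float = 0.25
    n_choice_trials: int = 48
    ssd_initial_ms: float = 100.0
    ssd_step_ms: float = 50.0
    ssd_min_ms: float = 0.0
    ssd_max_ms: float = 900.0

    def to_design(self) -> task.TaskDesign:
        return task.TaskDesign(**self.model_dump())


class ParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    go_mu_ms: float
    go_sigma_ms: float
    go_tau_ms: float
    ssrt_mean_ms: float
    ssrt_sd_ms: float
    slowing_factor: float = 1.0
    choice_error_rate: float = 0.0
    omission_rate: float = 0.0

    def to_params(self) -> task.RaceModelParams:
        return task.RaceModelParams(**self.model_dump())


class VariationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    go_mu_sd_ms: float = 0.0
    ssrt_sd_ms: float = 0.0
    cross_effector_rho: float = 0.6

    def to_variation(self) -> task.BetweenSubjectVariation:
        return task.BetweenSubjectVariation(**self.model_dump())


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_group: int = 30
    groups: dict[str, dict[str, ParamsConfig]]
    subject_variation: VariationConfig = Field(default_factory=VariationConfig)


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    basis: str = "go_trials"
    conf_level: float = 0.95
    side: str = "positive"
    priors: list[tuple[float, float]] = [(0.0, 0.707), (0.5, 0.5)]
    robustness_scales: list[float] = [0.5, 0.707, 1.0]
    group_order: tuple[str, str] = ("expert", "control")


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    trials_csv: str = "trials.csv"
    summary_csv: str = "summary.csv"
    report_json: str = "report.json"
    report_md: str = "report.md"


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int
    design: DesignConfig = Field(default_factory=DesignConfig)
    cohort: CohortConfig
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    outputs: OutputConfig = Field(default_factory=OutputConfig)


def default_config(seed: int = 0, n_per_group: int = 30) -> PipelineConfig:
    """Study-like configuration: the cohort conditions of the reference design."""
    specs, variation = task.study_cohort_spec()
    groups = {
        g: {e: ParamsConfig(**vars(p)) for e, p in eff.items()} for g, eff in specs.items()
    }
    return PipelineConfig(
        seed=seed,
        cohort=CohortConfig(
            n_per_group=n_per_group,
            groups=groups,
            subject_variation=VariationConfig(**vars(variation)),
        ),
    )


def load_config(path) -> PipelineConfig:
    path = Path(path)
    try:
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return PipelineConfig.model_validate(raw)
    except (ValidationError, yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# report schema (pydantic mirror of StopSignalResults.to_dict)


class AnovaEffectReport(BaseModel):
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


class BayesFactorReport(BaseModel):
    bf10: float
    prior_location: float
    prior_scale: float
    side: str
    numerical_error: float


class ContrastReport(BaseModel):
    groups: dict[str, dict[str, float]]
    d: float
    d_ci: list[float]
    t: float
    df: int
    p: float
    side: str
    bayes_factors: list[BayesFactorReport]
    robustness: list[dict[str, float]]


class ReportModel(BaseModel):
    model_config = ConfigDict(extra="allow")
    group_order: list[str]
    effectors: list[str]
    conf_level: float
    anova: dict[str, dict[str, AnovaEffectReport]]
    contrasts: dict[str, ContrastReport]
    correlations: dict
    slowing: Optional[dict] = None


def validate_report(report: dict) -> ReportModel:
    """Validate a report dictionary against the bundled schema; raises on failure."""
    try:
        return ReportModel.model_validate(report)
    except ValidationError as exc:
        raise ConfigError(f"report does not match schema: {exc}") from exc


# ---------------------------------------------------------------------------
# stages


def _stage(name: str, **params) -> None:
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in sorted(params.items())))


def simulate_stage(config: PipelineConfig, outdir: Path) -> Path:
    design = config.design.to_design()
    specs = {
        g: {e: p.to_params() for e, p in eff.items()} for g, eff in config.cohort.groups.items()
    }
    _stage(
        "simulate",
        seed=config.seed,
        n_per_group=config.cohort.n_per_group,
        n_trials=design.n_trials,
        groups=sorted(specs),
    )
    sessions = task.simulate_cohort(
        specs,
        config.cohort.n_per_group,
        design,
        config.seed,
        config.cohort.subject_variation.to_variation(),
    )
    path = outdir / config.outputs.trials_csv
    task.write_trials_csv(sessions, path)
    return path


def estimate_stage(config: PipelineConfig, trials_csv: Path, outdir: Path) -> Path:
    _stage("estimate", basis=config.analysis.basis, trials=str(trials_csv))
    sessions = task.read_trials_csv(trials_csv)
    summary = ssrt.summarize_sessions(sessions, config.analysis.basis)
    path = outdir / config.outputs.summary_csv
    summary.to_csv(path, index=False, float_format="%.6f")
    return path


def analyze_stage(config: PipelineConfig, summary_csv: Path, outdir: Path) -> dict:
    a = config.analysis
    _stage("analyze", conf_level=a.conf_level, side=a.side, priors=a.priors)
    m = model_mod.StopSignalModel.from_summary_csv(summary_csv, group_order=a.group_order)
    results = m.fit(
        conf_level=a.conf_level,
        priors=a.priors,
        robustness_scales=a.robustness_scales,
        side=a.side,
    )
    report = results.to_dict()
    validate_report(report)
    (outdir / config.outputs.report_json).write_text(json.dumps(report, indent=2))
    (outdir / config.outputs.report_md).write_text(
        "# Stop-signal analysis report\n\n```\n" + results.summary() + "\n```\n"
    )
    return report


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run simulate -> estimate -> analyze; returns the report dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = simulate_stage(config, outdir)
    summary = estimate_stage(config, trials, outdir)
    return analyze_stage(config, summary, outdir)


def make_fixtures(seed: int, outdir) -> Path:
    """Generate the tiny test cohort: 4 participants, 8 + 48 trials per session.

    2 participants per group, both effectors, 48 stop-signal trials with 12
    stop trials each — 448 data rows in total. Deterministic in ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = task.TaskDesign(n_trials=48, stop_fraction=0.25, n_choice_trials=8)
    specs, variation = task.study_cohort_spec()
    sessions = task.simulate_cohort(specs, 2, design, seed, variation)
    path = outdir / "fixture_trials.csv"
    task.write_trials_csv(sessions, path)
    return path
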
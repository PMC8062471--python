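"""Reproducible end-to-end pipeline: simulate -> fit -> compare -> analyze.

A JSON run configuration (validated by pydantic) names the stages to run,
the task and cohort settings, the prior set, restart counts and seeds.
Every stage writes plain CSV into the output directory and the run ends
with a manifest recording seeds, file hashes, package version and per-stage
runtimes, so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .analysis import (
    group_contrasts,
    parameter_performance_regression,
    performance_table,
    sex_difference_glm,
    validate_model_regression,
)
from .cohort import CohortSpec, default_cohort_spec, generate_cohort
from .fit import compare_models, fit_subject, fits_to_frame
from .io import (
    assemble_subjects,
    fitted_param_table,
    read_fits,
    read_subjects,
    read_trials,
    write_fits,
    write_subjects,
    write_trials,
)
from .models import MODEL_NAMES, AgentParams
from .task import TaskConfig

logger = logging.getLogger("stressrl")

Stage = Literal["simulate", "fit", "compare", "analyze"]


class TaskSettings(BaseModel):
    n_trials: int = 60
    block_length: int = 20
    p_high: float = 0.75
    adjustment_enabled: bool = True

    def to_config(self, seed: Optional[int] = None) -> TaskConfig:
        return TaskConfig(
            n_trials=self.n_trials,
            block_length=self.block_length,
            p_high=self.p_high,
            adjustment_enabled=self.adjustment_enabled,
            rng_seed=seed,
        )


class CohortSettings(BaseModel):
    n_per_group: int = 16
    model_name: str = "s1w"


class RunConfig(BaseModel):
    """Validated run configuration for :func:`run_pipeline`."""

    stages: list[Stage] = Field(default=["simulate", "fit", "compare", "analyze"])
    task: TaskSettings = Field(default_factory=TaskSettings)
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    priors: str = "default"
    models: list[str] = Field(default=list(MODEL_NAMES))
    n_restarts: int = 100
    seed: int = 0
    output_dir: str = "stressrl_output"
    log_level: str = "INFO"

    @field_validator("models")
    @classmethod
    def _known_models(cls, models: list[str]) -> list[str]:
        unknown = [m for m in models if m not in MODEL_NAMES]
        if unknown:
            raise ValueError(f"unknown models {unknown}; choose from {MODEL_NAMES}")
        return models

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as handle:
            return cls.model_validate(json.load(handle))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    spec = CohortSpec(
        n_per_group=config.cohort.n_per_group,
        model_name=config.cohort.model_name,
        task=config.task.to_config(),
        seed=config.seed,
    )
    subjects = generate_cohort(spec)
    write_subjects(subjects, out / "cohort.csv")
    write_trials({s.subject_id: s.trials for s in subjects}, out / "trials.csv")
    logger.info("simulated %d subjects", len(subjects))
    return [out / "cohort.csv", out / "trials.csv"]


def stage_fit(config: RunConfig, out: Path) -> list[Path]:
    trials_path = out / "trials.csv"
    if not trials_path.exists():
        raise FileNotFoundError(f"fit stage needs trial logs at {trials_path}")
    trials = read_trials(trials_path)
    fits = []
    for i, (sid, log) in enumerate(sorted(trials.items())):
        for j, model in enumerate(config.models):
            fits.append(
                fit_subject(
                    model,
                    log,
                    priors=config.priors,
                    n_restarts=config.n_restarts,
                    seed=config.seed + 1_000 + i * len(config.models) + j,
                    subject_id=sid,
                )
            )
        logger.info("fitted subject %s (%d models)", sid, len(config.models))
    write_fits(fits_to_frame(fits), out / "fits.csv")
    return [out / "fits.csv"]


def stage_compare(config: RunConfig, out: Path) -> list[Path]:
    fits = read_fits(out / "fits.csv")
    table = compare_models(fits)
    table.to_csv(out / "model_comparison.csv", index=False)
    logger.info("winning model: %s", table.loc[table.winner, "model"].iloc[0])
    return [out / "model_comparison.csv"]


def stage_analyze(config: RunConfig, out: Path) -> list[Path]:
    manifest = read_subjects(out / "cohort.csv")
    trials = read_trials(out / "trials.csv")
    fits = read_fits(out / "fits.csv")
    comparison = pd.read_csv(out / "model_comparison.csv")
    winner = comparison.loc[comparison.winner, "model"].iloc[0]
    subjects = assemble_subjects(manifest, trials, config.cohort.model_name)
    task = config.task.to_config()

    perf = performance_table(subjects, task)
    perf.to_csv(out / "performance.csv", index=False)
    contrasts = group_contrasts(perf)
    contrasts.anova.to_csv(out / "anova.csv")
    contrasts.posthoc.to_csv(out / "posthoc.csv", index=False)

    params = fitted_param_table(fits, winner)
    # covariates follow the winning model's parameter names: its first
    # learning-rate-like parameter and, when present, gamma
    winner_params = [c for c in params.columns if c != "subject_id"]
    rate = next((p for p in winner_params if p not in ("gamma", "beta")), None)
    cov_sets: list[tuple[str, ...]] = [()]
    if rate:
        cov_sets.append((rate,))
    if "gamma" in winner_params:
        cov_sets.append(("gamma",))
    glm = sex_difference_glm(perf, params, covariate_sets=cov_sets)
    glm.to_csv(out / "sex_glm.csv", index=False)
    reg = parameter_performance_regression(
        perf, params, parameters=[p for p in ("gamma", rate) if p]
    )
    reg.to_csv(out / "parameter_regression.csv", index=False)

    fitted = {
        str(r.subject_id): AgentParams.from_vector(
            winner, [getattr(r, c) for c in params.columns if c != "subject_id"]
        )
        for r in params.itertuples(index=False)
    }
    per_subject, group = validate_model_regression(subjects, fitted)
    per_subject.to_csv(out / "validation_per_subject.csv", index=False)
    group.to_csv(out / "validation_group.csv", index=False)

    lines = [
        f"stressrl analysis summary (winning model: {winner})",
        "",
        "Two-way sex x stress ANOVA on proportion correct:",
        contrasts.anova.to_string(),
        "",
        "Post-hoc sex contrasts by stress level:",
        contrasts.posthoc.to_string(index=False),
        "",
        "High-stress sex-difference GLM (male=1):",
        glm.to_string(index=False),
        "",
        "Performance ~ fitted-parameter regressions:",
        reg.to_string(index=False),
        "",
        "Model-validation regression (group level):",
        group.to_string(index=False),
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    try:
        from . import plotting

        figures = plotting.standard_figures(perf, params, out)
    except Exception as exc:  # plotting must never sink a run
        logger.warning("figure generation failed: %s", exc)
        figures = []
    return [
        out / name
        for name in (
            "performance.csv",
            "anova.csv",
            "posthoc.csv",
            "sex_glm.csv",
            "parameter_regression.csv",
            "validation_per_subject.csv",
            "validation_group.csv",
            "summary.txt",
        )
    ] + figures


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "compare": stage_compare,
    "analyze": stage_analyze,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and write a run manifest.

    On a stage failure, outputs of completed stages are retained and the
    manifest records the failure point before the exception propagates.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.model_dump(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "status": "ok",
    }
    try:
        for stage in config.stages:
            start = time.perf_counter()
            paths = _STAGE_FUNCS[stage](config, out)
            manifest["stages"][stage] = {
                "runtime_s": round(time.perf_counter() - start, 3)
            }
            for p in paths:
                manifest["outputs"][p.name] = _sha256(p)
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage!r}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
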
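"""End-to-end orchestration of the sensitivity analysis.

Runs, in order: simulate (or load) a registry -> MAR imputation by chained
equations -> MAR stage profile per pattern cell -> questionnaire template /
elicited prior -> moment-matched Dirichlet prior -> MNAR re-imputation ->
substantive model under both assumptions -> Rubin pooling -> sensitivity
report.  Every artifact is written to a run directory and listed, with a
content hash, in a manifest so that re-runs are auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._core import ValidationError
from .elicitation import (
    DEMO_ELICITED_MEANS,
    DEMO_ELICITED_VARIANCES,
    LATE_STAGE_SHIFT_MEANS,
    LATE_STAGE_SHIFT_VARIANCES,
    aggregate_experts,
    fit_dirichlet,
    make_questionnaire_template,
    read_questionnaire,
    synthesize_questionnaire,
)
from .impute import FcsConfig, fcs_impute
from .pooling import DEFAULT_COVARIATES, compare_assumptions, pool_stack
from .profile import cell_probabilities
from .reimpute import mnar_reimpute
from .synthesis import GeneratorConfig, apply_missingness, generate_registry, read_registry_csv

log = logging.getLogger("patmix")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; mirrors the CLI flags one to one."""

    out_dir: str = "patmix_run"
    seed: int = 0
    registry_csv: str | None = None  # if None, simulate with `generator`
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    questionnaire_csv: str | None = None  # if None, synthesize a demo panel
    synthetic_prior: str = "cell-anchored"  # or "late-stage"; see elicitation module
    n_synthetic_experts: int = 6
    assumption: str = "both"  # 'mar' skips elicitation/MNAR stages
    m: int = 10
    cycles: int = 10
    ridge: float = 1e-4
    substantive_covariates: tuple[str, ...] = DEFAULT_COVARIATES
    draw_granularity: str = "cell"
    s_aggregator: str = "mean"
    emit_template: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        gen = payload.pop("generator", None)
        cfg = cls(**payload)
        if gen is not None:
            cfg = dataclasses.replace(cfg, generator=GeneratorConfig(**gen))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk).

    Stage failures are re-raised annotated with the stage name and the run
    directory so a run can be diagnosed and resumed from its artifacts.
    Two runs with the same config produce byte-identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "setup"

    def emit(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)
        log.info("stage %-12s wrote %s", stage, path)

    try:
        stage = "simulate"
        if config.registry_csv is not None:
            registry = read_registry_csv(config.registry_csv)
        else:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            complete = generate_registry(gen)
            registry, truth_mask = apply_missingness(complete, gen)
            complete.to_csv(out / "registry_complete.csv", index=False)
            emit("registry_complete", out / "registry_complete.csv")
        registry.to_csv(out / "registry.csv", index=False)
        emit("registry", out / "registry.csv")
        log.info("registry: n=%d, missing stage=%d", len(registry), int(registry["stage"].isna().sum()))

        stage = "impute-mar"
        fcs = FcsConfig(m=config.m, cycles=config.cycles, ridge=config.ridge, seed=config.seed)
        mar_stack = fcs_impute(registry, fcs)
        mar_stack.save(out / "mar_stack")
        for p in sorted((out / "mar_stack").iterdir()):
            emit(f"mar_stack/{p.name}", p)

        stage = "profile"
        cells = cell_probabilities(mar_stack)
        cells.to_csv(out / "cell_probabilities.csv")
        emit("cell_probabilities", out / "cell_probabilities.csv")

        stage = "pool-mar"
        pooled_mar = pool_stack(mar_stack, covariates=config.substantive_covariates)
        pooled_mar.to_csv(out / "pooled_mar.csv")
        emit("pooled_mar", out / "pooled_mar.csv")

        if config.assumption == "mar":
            manifest = _write_manifest(out, config, artifacts)
            return manifest

        stage = "template"
        if config.emit_template:
            make_questionnaire_template(cells, out / "questionnaire_template.csv")
            emit("questionnaire_template", out / "questionnaire_template.csv")

        stage = "elicit"
        if config.questionnaire_csv is not None:
            responses = read_questionnaire(config.questionnaire_csv)
        else:
            if config.synthetic_prior == "cell-anchored":
                means, variances = DEMO_ELICITED_MEANS, DEMO_ELICITED_VARIANCES
            elif config.synthetic_prior == "late-stage":
                means, variances = LATE_STAGE_SHIFT_MEANS, LATE_STAGE_SHIFT_VARIANCES
            else:
                raise ValidationError(
                    f"unknown synthetic_prior {config.synthetic_prior!r}; "
                    "expected 'cell-anchored' or 'late-stage'"
                )
            synth = synthesize_questionnaire(
                means,
                variances,
                n_experts=config.n_synthetic_experts,
                seed=config.seed,
            )
            synth.to_csv(out / "questionnaire_synthetic.csv", index=False)
            emit("questionnaire_synthetic", out / "questionnaire_synthetic.csv")
            responses = read_questionnaire(synth)
        prior = aggregate_experts(responses)
        prior.pi.to_csv(out / "elicited_means.csv")
        prior.var.to_csv(out / "elicited_variances.csv")
        emit("elicited_means", out / "elicited_means.csv")
        emit("elicited_variances", out / "elicited_variances.csv")

        stage = "fit-prior"
        spec = fit_dirichlet(prior, aggregator=config.s_aggregator)
        (out / "dirichlet_spec.json").write_text(spec.to_json())
        emit("dirichlet_spec", out / "dirichlet_spec.json")

        stage = "reimpute-mnar"
        mnar_stack = mnar_reimpute(
            mar_stack, spec, seed=config.seed, granularity=config.draw_granularity
        )
        mnar_stack.save(out / "mnar_stack")
        for p in sorted((out / "mnar_stack").iterdir()):
            emit(f"mnar_stack/{p.name}", p)

        stage = "pool-mnar"
        pooled_mnar = pool_stack(mnar_stack, covariates=config.substantive_covariates)
        pooled_mnar.to_csv(out / "pooled_mnar.csv")
        emit("pooled_mnar", out / "pooled_mnar.csv")

        stage = "compare"
        report = compare_assumptions(pooled_mar, pooled_mnar)
        report.to_csv(out / "sensitivity_report.csv")
        (out / "sensitivity_report.json").write_text(report.to_json())
        emit("sensitivity_report", out / "sensitivity_report.csv")
        emit("sensitivity_report_json", out / "sensitivity_report.json")

        manifest = _write_manifest(out, config, artifacts)
        return manifest
    except ValidationError as exc:
        raise ValidationError(f"pipeline stage {stage!r} failed in {out}: {exc}") from exc


def _write_manifest(out: Path, config: PipelineConfig, artifacts: dict) -> dict:
    cfg = config.to_dict()
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}  # location is not config
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(hashed, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
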
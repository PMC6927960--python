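"""End-to-end pipeline driver: generate/load -> filter -> analyze -> write.

The run configuration comes from a YAML file (or a :class:`RunConfig`
built in code).  Every output is deterministic given the master seed:
rerunning the same configuration reproduces the result bundle
byte-for-byte, and the manifest echoes everything needed to do so.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .choice import (
    RegressionSpec,
    fit_covariate_regression,
    fit_stay_regression,
    fit_valence_split,
    reward_rate_comparison,
)
from .cohort import CohortDataset, GroupSpec, ParamDist, default_specs, sample_cohort
from .io import read_cohort, write_cohort
from .preprocessing import apply_engagement_filters, build_lagged_table
from .rt import rt1_outcome_anova, rt2_transition_anova, severity_rt_correlation
from .task import TaskConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]


@dataclass(frozen=True)
class AnalysisSwitches:
    stay_regression: bool = True
    valence_split: bool = True
    covariates: tuple[str, ...] = ()
    reward_rate: bool = True
    rt_anovas: bool = True
    severity_correlation: bool = True
    random_effects: str = "slopes"


@dataclass(frozen=True)
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    specs: tuple[GroupSpec, GroupSpec] | None = None  # None + no paths -> defaults
    trials_path: str | None = None
    subjects_path: str | None = None
    analysis: AnalysisSwitches = field(default_factory=AnalysisSwitches)
    seed: int = 0
    out_dir: str = "twostep_out"

    def __post_init__(self) -> None:
        if self.specs is not None and self.trials_path is not None:
            raise ValueError("give either cohort specs or input paths, not both")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


def _dist_from_cfg(v) -> ParamDist:
    if isinstance(v, (list, tuple)) and len(v) == 4:
        return ParamDist(*[float(x) for x in v])
    raise ValueError(f"parameter distribution must be [mean, sd, low, high], got {v!r}")


def _spec_from_cfg(base: GroupSpec, cfg: dict) -> GroupSpec:
    params = dict(base.params)
    for name, v in cfg.get("params", {}).items():
        params[name] = _dist_from_cfg(v)
    covs = dict(base.covariates)
    for name, v in cfg.get("covariates", {}).items():
        covs[name] = (float(v[0]), float(v[1]))
    return replace(
        base,
        n_subjects=int(cfg.get("n_subjects", base.n_subjects)),
        params=params,
        k_sev=float(cfg.get("k_sev", base.k_sev)),
        covariates=covs,
    )


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclasses)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    task = TaskConfig(**cfg.get("task", {}))
    cohort_cfg = cfg.get("cohort", {}) or {}
    specs = None
    trials_path = cohort_cfg.get("trials")
    subjects_path = cohort_cfg.get("subjects")
    if trials_path is None and ("pg" in cohort_cfg or "cp" in cohort_cfg):
        pg0, cp0 = default_specs()
        specs = (
            _spec_from_cfg(pg0, cohort_cfg.get("pg", {})),
            _spec_from_cfg(cp0, cohort_cfg.get("cp", {})),
        )
    ana_cfg = cfg.get("analysis", {}) or {}
    if "covariates" in ana_cfg:
        ana_cfg["covariates"] = tuple(ana_cfg["covariates"])
    analysis = AnalysisSwitches(**ana_cfg)
    return RunConfig(
        task=task,
        specs=specs,
        trials_path=trials_path,
        subjects_path=subjects_path,
        analysis=analysis,
        seed=int(cfg.get("seed", 0)),
        out_dir=str(cfg.get("out_dir", "twostep_out")),
    )


def _write_regression(res, path: Path) -> None:
    res.table.to_csv(path, index=False, float_format="%.6g")


def _write_anova(res, stem: Path) -> None:
    res.effects.to_csv(stem.with_suffix(".csv"), index=False, float_format="%.6g")
    res.posthoc.to_csv(
        stem.parent / (stem.name + "_posthoc.csv"), index=False, float_format="%.6g"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the result bundle as a dict.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "analysis": asdict(config.analysis),
        "task": asdict(config.task),
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("data")
        if config.trials_path is not None:
            cohort = read_cohort(config.trials_path, config.subjects_path)
            manifest["source"] = {"trials": config.trials_path,
                                  "subjects": config.subjects_path}
        else:
            cohort = sample_cohort(config.specs, seed=config.seed, config=config.task)
            manifest["source"] = "synthetic"
        write_cohort(cohort, out)
        bundle["cohort"] = cohort
    except Exception as exc:
        raise PipelineError("data", exc) from exc

    try:
        stage("filter")
        filtered, report = apply_engagement_filters(cohort)
        report.table.to_csv(out / "filter_report.csv", index=False, float_format="%.6g")
        manifest["n_subjects_in"] = int(cohort.subjects.shape[0])
        manifest["n_subjects_kept"] = int(filtered.subjects.shape[0])
        manifest["n_excluded"] = report.n_excluded
        manifest["excluded_subjects"] = report.excluded_ids()
        bundle["filter_report"] = report
        bundle["filtered"] = filtered
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    try:
        stage("lag")
        lagged = build_lagged_table(filtered)
        manifest["n_lagged_rows"] = int(len(lagged))
        bundle["lagged"] = lagged
    except Exception as exc:
        raise PipelineError("lag", exc) from exc

    sw = config.analysis
    spec = RegressionSpec(random_effects=sw.random_effects)
    convergence: dict[str, bool] = {}

    if sw.stay_regression:
        try:
            stage("stay_regression")
            res = fit_stay_regression(lagged, spec)
            _write_regression(res, out / "stay_regression.csv")
            convergence["stay_regression"] = res.converged
            bundle["stay_regression"] = res
        except Exception as exc:
            raise PipelineError("stay_regression", exc) from exc

    if sw.valence_split:
        try:
            stage("valence_split")
            rew, unrew = fit_valence_split(lagged, spec)
            _write_regression(rew, out / "valence_rewarded.csv")
            _write_regression(unrew, out / "valence_unrewarded.csv")
            convergence["valence_rewarded"] = rew.converged
            convergence["valence_unrewarded"] = unrew.converged
            bundle["valence_split"] = (rew, unrew)
        except Exception as exc:
            raise PipelineError("valence_split", exc) from exc

    for cov in sw.covariates:
        try:
            stage(f"covariate_{cov}")
            res = fit_covariate_regression(lagged, cov, spec)
            _write_regression(res, out / f"covariate_{cov}.csv")
            convergence[f"covariate_{cov}"] = res.converged
            bundle[f"covariate_{cov}"] = res
        except Exception as exc:
            raise PipelineError(f"covariate_{cov}", exc) from exc

    if sw.reward_rate:
        try:
            stage("reward_rate")
            rr = reward_rate_comparison(filtered)
            (out / "reward_rate.json").write_text(
                json.dumps(asdict(rr), indent=2, sort_keys=True) + "\n"
            )
            bundle["reward_rate"] = rr
        except Exception as exc:
            raise PipelineError("reward_rate", exc) from exc

    if sw.rt_anovas:
        try:
            stage("rt_anovas")
            a2 = rt2_transition_anova(filtered)
            a1 = rt1_outcome_anova(filtered)
            _write_anova(a2, out / "rt2_transition_anova")
            _write_anova(a1, out / "rt1_outcome_anova")
            bundle["rt2_anova"] = a2
            bundle["rt1_anova"] = a1
        except Exception as exc:
            raise PipelineError("rt_anovas", exc) from exc

    if sw.severity_correlation:
        try:
            stage("severity_correlation")
            has_pg = (filtered.subjects["group"] == "PG").sum() >= 3
            if has_pg:
                r, p, n = severity_rt_correlation(filtered)
                payload = {"r": r, "p": p, "n": n}
            else:
                payload = {"r": None, "p": None, "n": 0,
                           "note": "fewer than 3 PG subjects"}
            (out / "severity_correlation.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n"
            )
            bundle["severity_correlation"] = payload
        except Exception as exc:
            raise PipelineError("severity_correlation", exc) from exc

    manifest["convergence"] = convergence
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    bundle["manifest"] = manifest
    return bundle
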
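"""End-to-end orchestration: simulate/load → extract → stats → classify → report.

A single :class:`RunConfig` (YAML on disk) drives the run; every numeric cell
in the emitted reports is a pure function of the cohort and the config, so
identical configs give byte-identical CSV/JSON artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .classify import ModelConfig, TaskClassifier, ablation_suite
from .errors import PipelineError, SpiralDxError
from .features import SpectralConfig, extract_feature_table
from .io import load_cohort, save_cohort
from .preprocess import PIPELINE_ORDER
from .simulate import CohortConfig, generate_cohort
from .spiral import SpiralTemplate
from .stats import TASKS, mann_whitney_tests, spearman_table, feature_boxplots

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    out_dir: str = "spiraldx_run"
    manifest: str | None = None  # load this cohort; None -> simulate one
    n_cg: int = 27
    n_pd: int = 24
    n_dd: int = 26
    seed: int = 0
    tasks: tuple[str, ...] = ("Task1", "Task2", "Task3")
    feature_sets: tuple[str, ...] = ("questionnaire_only", "tablet_only", "integrated")
    max_radius: float = 3.75
    n_loops: int = 4
    f_lo: float = 3.0
    f_hi: float = 15.0
    n_spectral_bins: int = 20
    n_folds: int = 5
    pca_variance_retained: float = 0.95
    make_figures: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.tasks = tuple(cfg.tasks)
        cfg.feature_sets = tuple(cfg.feature_sets)
        return cfg

    def to_file(self, path) -> None:
        data = asdict(self)
        data["tasks"] = list(self.tasks)
        data["feature_sets"] = list(self.feature_sets)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def template(self) -> SpiralTemplate:
        return SpiralTemplate(max_radius=self.max_radius, n_loops=self.n_loops)

    @property
    def spectral(self) -> SpectralConfig:
        return SpectralConfig(f_lo=self.f_lo, f_hi=self.f_hi, n_bins=self.n_spectral_bins)

    @property
    def model(self) -> ModelConfig:
        return ModelConfig(n_folds=self.n_folds,
                           pca_variance_retained=self.pca_variance_retained,
                           seed=self.seed)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except SpiralDxError as exc:
        pid = getattr(exc, "participant_id", None)
        raise PipelineError(name, str(exc), pid) from exc


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and emit all artifacts; returns the run report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.manifest is None:
        logger.info("stage simulate: %d/%d/%d participants, seed %d",
                    cfg.n_cg, cfg.n_pd, cfg.n_dd, cfg.seed)
        cohort = _stage("simulate", generate_cohort,
                        CohortConfig(n_cg=cfg.n_cg, n_pd=cfg.n_pd, n_dd=cfg.n_dd,
                                     seed=cfg.seed, template=cfg.template))
        manifest_path = _stage("simulate", save_cohort, cohort, out / "cohort")
    else:
        logger.info("stage load: %s", cfg.manifest)
        manifest_path = Path(cfg.manifest)
        cohort = _stage("load", load_cohort, manifest_path)

    logger.info("stage extract: %d participants", len(cohort))
    features = _stage("extract", extract_feature_table, cohort,
                      cfg.template, cfg.spectral)
    features.to_csv(out / "features.csv")

    logger.info("stage stats")
    tasks = {name: TASKS[name] for name in cfg.tasks}
    spearman = _stage("stats", spearman_table, features, tasks)
    spearman.to_csv(out / "spearman.csv", index=False)
    mw_tables = []
    for name, task in tasks.items():
        mw_tables.append(_stage("stats", mann_whitney_tests, features, task))
    import pandas as pd

    mw = pd.concat(mw_tables, ignore_index=True)
    mw.to_csv(out / "mann_whitney.csv", index=False)

    logger.info("stage classify")
    ablation = _stage("classify", ablation_suite, features, cfg.model, tasks)
    with open(out / "ablation.json", "w") as fh:
        json.dump(ablation, fh, indent=2, sort_keys=True)
        fh.write("\n")

    errors = {}
    importances = {}
    for name, task in tasks.items():
        results = _stage("classify", lambda: TaskClassifier(
            features, task, "integrated", cfg.model).fit())
        errors[name] = results.error_analysis().to_dict(orient="records")
        imp = results.shap_importance().per_fold_mean
        importances[name] = imp
        imp.to_csv(out / f"importance_{name}.csv")
        if cfg.make_figures:
            results.plot_importance(out / f"importance_{name}.png")
    with open(out / "errors.json", "w") as fh:
        json.dump(errors, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")

    if cfg.make_figures:
        for name, task in tasks.items():
            top = (spearman[(spearman["target"] == name)]
                   .assign(absrho=lambda d: d["rho"].abs())
                   .sort_values("absrho", ascending=False)["feature"].head(3))
            _stage("stats", feature_boxplots, features, list(top), task,
                   path=out / f"boxplots_{name}.png")

    run_log = {
        "spiraldx_version": __version__,
        "seed": cfg.seed,
        "config": {**asdict(cfg), "tasks": list(cfg.tasks),
                   "feature_sets": list(cfg.feature_sets)},
        "pipeline_order": list(PIPELINE_ORDER),
        "manifest": str(manifest_path),
        "n_participants": len(cohort),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return {"ablation": ablation, "errors": errors, "out_dir": str(out),
            "manifest": str(manifest_path)}
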
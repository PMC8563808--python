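"""End-to-end orchestration: simulate -> preprocess -> features -> classify
-> importance -> clinical, as one reproducible, configured run.

Configuration is a strict schema (unknown keys rejected); the run report is
a JSON document carrying every stage's results plus provenance (config hash,
seed, library versions, per-stage wall time). Intermediate artifacts
(feature table, CV results, clinical table) are persisted so stages can be
re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from . import classify, clinical, interpret, preprocess, spectral
from .sigio import ClinicalTable, write_clinical_table, write_feature_table
from .simulate import generate_cohort, reference_cohort_spec

__all__ = ["RunConfig", "ConfigError", "run_all", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration (raised before any computation)."""


class BandConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    low_hz: float
    high_hz: float


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low_hz: float = 0.5
    high_hz: float = 80.0
    order: int = 4


class EnetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mixing: float = Field(0.5, ge=0.0, le=1.0)
    lambda_min: float = 1e-4
    lambda_max: float = 1e2
    n_lambdas: int = 50


class CvConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    subject_outer_folds: int = 5
    subject_inner_folds: int = 5
    min_segments: int = 10


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Literal["scc-8"] = "scc-8"
    n_subjects: int = 8
    fs: float = 2000.0
    epoch_seconds: float = 60.0
    save_recordings: bool = False
    recording_format: Literal["internal", "edf"] = "internal"


class QcConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    rms_factor: float = 10.0


class RunConfig(BaseModel):
    """Every tunable of the pipeline, with strict validation."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    bands: list[BandConfig] = Field(
        default_factory=lambda: [
            BandConfig(name="theta", low_hz=4.0, high_hz=8.0),
            BandConfig(name="alpha", low_hz=9.0, high_hz=12.0),
            BandConfig(name="beta", low_hz=13.0, high_hz=30.0),
        ]
    )
    filter: FilterConfig = Field(default_factory=FilterConfig)
    target_fs: float = 1000.0
    segment_seconds: float = 1.0
    enet: EnetConfig = Field(default_factory=EnetConfig)
    cv: CvConfig = Field(default_factory=CvConfig)
    selection_rule: Literal["nonzero", "positive"] = "nonzero"
    n_permutations: int = 5000
    alpha: float = 0.05
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    qc: QcConfig = Field(default_factory=QcConfig)

    def validate_consistency(self) -> None:
        if self.target_fs > self.simulate.fs:
            raise ConfigError(
                f"target_fs ({self.target_fs}) must not exceed the simulated "
                f"sampling rate ({self.simulate.fs})"
            )
        if self.filter.high_hz >= self.target_fs / 2:
            raise ConfigError(
                f"filter high_hz ({self.filter.high_hz}) must be below the "
                f"post-decimation Nyquist ({self.target_fs / 2})"
            )

    def lambda_grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.enet.lambda_min), np.log10(self.enet.lambda_max), self.enet.n_lambdas
        )

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        cfg = RunConfig(**raw)
    except PydanticValidationError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate_consistency()
    return cfg


def _library_versions() -> dict[str, str]:
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _corr_to_dict(res: clinical.CorrelationResult) -> dict:
    return {
        "feature": res.name,
        "r": res.r,
        "n": res.n,
        "p_uncorrected": res.p_uncorrected,
        "p_permutation": res.p_permutation,
        "p_corrected": res.p_corrected,
    }


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in fixed order and write the run report.

    Returns the report dictionary; artifacts land under ``outdir``
    (``features.tsv``, ``clinical.tsv``, ``cv_<contrast>.json``,
    ``report.json``).
    """
    try:
        config.validate_consistency()
    except ConfigError:
        raise
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config": config.model_dump(mode="json"),
            "config_hash": config.hash(),
            "seed": config.seed,
            "versions": _library_versions(),
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "stages": {},
        "warnings": [],
    }
    timings: dict[str, float] = {}
    captured: list[str] = []

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                self.ctx = warnings.catch_warnings(record=True)
                self.log = self.ctx.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                self.ctx.__exit__(exc_type, exc, tb)
                for w in self.log:
                    captured.append(f"{name}: {w.message}")
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc_type is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Timer()

    # -- simulate ----------------------------------------------------------
    with _stage("simulate"):
        spec = reference_cohort_spec(
            n_subjects=config.simulate.n_subjects,
            fs=config.simulate.fs,
            epoch_seconds=config.simulate.epoch_seconds,
        )
        recordings, clin_table, truth = generate_cohort(spec, config.seed)
        write_clinical_table(clin_table, outdir / "clinical.tsv")
        (outdir / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
        if config.simulate.save_recordings:
            from .sigio import write_recording

            ext = ".edf" if config.simulate.recording_format == "edf" else ".json"
            for rec in recordings:
                write_recording(rec, outdir / f"{rec.subject_id}{ext}")
    report["stages"]["simulate"] = {
        "n_subjects": len(recordings),
        "fs": config.simulate.fs,
        "epoch_seconds": config.simulate.epoch_seconds,
    }

    # -- preprocess + features --------------------------------------------
    with _stage("preprocess"):
        drops = (
            preprocess.qc_screen_hemispheres(recordings, rms_factor=config.qc.rms_factor)
            if config.qc.enabled
            else {}
        )
        for sid, hemis in sorted(drops.items()):
            warnings.warn(f"QC excluded hemisphere(s) {sorted(hemis)} of subject {sid}")
        segmented = []
        provenance = None
        for rec in recordings:
            signals, provenance = preprocess.preprocess_recording(
                rec,
                target_fs=config.target_fs,
                low_hz=config.filter.low_hz,
                high_hz=config.filter.high_hz,
                order=config.filter.order,
                drop_hemispheres=drops.get(rec.subject_id),
            )
            for sig in signals:
                for epoch in sig.epochs:
                    segmented.append(
                        preprocess.segment_epoch(sig, epoch, config.segment_seconds)
                    )
    report["stages"]["preprocess"] = {
        "provenance": provenance,
        "qc_excluded": {k: sorted(v) for k, v in drops.items()},
    }

    with _stage("features"):
        from .simulate import BandSpec

        bands = tuple(BandSpec(b.name, b.low_hz, b.high_hz) for b in config.bands)
        features = spectral.build_feature_table(segmented, bands, config.segment_seconds)
        write_feature_table(features, outdir / "features.tsv")
    report["stages"]["features"] = {"n_rows": int(len(features))}

    # -- classification ----------------------------------------------------
    grid = config.lambda_grid()
    cv_results: dict[str, classify.CvResult] = {}
    with _stage("classify"):
        for contrast in (("PRE", "POST"), ("PRE", "MID"), ("MID", "POST")):
            key = f"{contrast[0]}-{contrast[1]}"
            cv = classify.nested_cv(
                features,
                contrast=contrast,
                lambda_grid=grid,
                mixing=config.enet.mixing,
                seed=config.seed,
            )
            cv.save(outdir / f"cv_{key}.json")
            cv_results[key] = cv
    report["stages"]["classify"] = {
        key: {
            "auc_mean": cv.auc_mean,
            "auc_sd": cv.auc_sd,
            "n_outer_folds": len(cv.outer),
            "outer_aucs": cv.outer_aucs.tolist(),
        }
        for key, cv in cv_results.items()
    }

    # -- importance --------------------------------------------------------
    with _stage("importance"):
        scores = interpret.importance_from_cv(cv_results["PRE-POST"], rule=config.selection_rule)
        anova = interpret.importance_anova(scores, alpha=config.alpha)
        weighted = {
            key: interpret.weighted_importance(
                interpret.importance_from_cv(cv, rule=config.selection_rule), cv
            )
            for key, cv in cv_results.items()
        }
        (outdir / "importance.json").write_text(
            json.dumps({"pre_post": scores.to_dict(), "weighted": weighted}, indent=1)
        )
    report["stages"]["importance"] = {
        "overall": scores.as_dict(),
        "anova": {
            "F": anova.F,
            "p": anova.p,
            "significant_subset": list(anova.significant_subset),
            "defined": anova.defined,
        },
        "weighted": weighted,
    }

    # -- subject-level classification -------------------------------------
    with _stage("subject_cv"):
        subject_aucs = classify.subject_level_cv(
            features,
            lambda_grid=grid,
            mixing=config.enet.mixing,
            seed=config.seed,
            outer_folds=config.cv.subject_outer_folds,
            inner_folds=config.cv.subject_inner_folds,
            min_segments=config.cv.min_segments,
        )
        subject_aucs.to_csv(outdir / "subject_aucs.tsv", sep="\t", index=False)
        sub_anova = classify.compare_subject_aucs(subject_aucs)
    report["stages"]["subject_cv"] = {
        "table": subject_aucs.to_dict(orient="records"),
        "rmanova": {"F": sub_anova.F, "df": list(sub_anova.df), "p": sub_anova.p},
    }

    # -- clinical ----------------------------------------------------------
    with _stage("clinical"):
        summary = clinical.summarize_hdrs(clin_table)
        score_anova = clinical.pre_post_rmanova(clin_table)
        correlations = clinical.beta_outcome_correlation(
            features,
            clin_table,
            n_perm=config.n_permutations,
            alpha=config.alpha,
            seed=config.seed,
        )
    report["stages"]["clinical"] = {
        "hdrs_summary": summary.rounded(),
        "rmanova": {"F": score_anova.F, "df": list(score_anova.df), "p": score_anova.p},
        "correlations": [_corr_to_dict(c) for c in correlations],
    }

    report["warnings"] = captured
    report["provenance"]["stage_seconds"] = timings
    report["provenance"]["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    _write_summary(report, outdir / "report.txt")
    return report


def _write_summary(report: dict, path: Path) -> None:
    lines = ["lfpstate run summary", "====================", ""]
    cls = report["stages"]["classify"]
    for key, r in cls.items():
        lines.append(
            f"{key}: AUC_mean = {r['auc_mean']:.3f} (SD {r['auc_sd']:.3f}, "
            f"N = {r['n_outer_folds']})"
        )
    imp = report["stages"]["importance"]["overall"]
    peak = max(imp.values())
    top = [k for k, v in imp.items() if v == peak]
    lines.append(f"top importance {peak:.2f}: {', '.join(top)}")
    hs = report["stages"]["clinical"]["hdrs_summary"]
    lines.append(
        f"HDRS-17: {hs['mean_baseline']} -> {hs['mean_post']} "
        f"({hs['percent_decline']}% decline, {hs['n_responders']} responders)"
    )
    for c in report["stages"]["clinical"]["correlations"]:
        lines.append(
            f"{c['feature']}: r({c['n']}) = {c['r']:.3f}, corrected p = {c['p_corrected']:.3f}"
        )
    path.write_text("\n".join(lines) + "\n")
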
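"""End-to-end orchestration: simulate -> filter -> detect-onset ->
extract-features -> screen -> fit -> evaluate, with a run manifest.

Every stage is a pure function of its inputs plus the run configuration,
so re-running with an identical configuration reproduces byte-identical
result tables.  The manifest records the configuration hash, per-stage
outputs and attrition counts (how many patients were dropped at the
inclusion filter and at onset detection, and why).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cio
from . import features as feat
from . import model as mod
from . import onset as ons
from . import screen as scr
from . import synthetic as syn


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; defaults match the published rules."""

    sirs: ons.SirsConfig = field(default_factory=ons.SirsConfig)
    shock: ons.ShockConfig = field(default_factory=ons.ShockConfig)
    window_h: float = feat.WINDOW_H                       # 48
    mortality_horizon_h: float = feat.MORTALITY_HORIZON_H  # 168
    alpha: float = scr.ALPHA                               # 0.05
    alpha_mix: float = mod.DEFAULT_ALPHA_MIX
    fold_counts: tuple[int, ...] = (3, 4, 5)
    eval_folds: int = 5
    seed: int = 0
    cohort: syn.CohortSpec = field(default_factory=syn.CohortSpec)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["sampling_rates"] = dict(d["cohort"]["sampling_rates"])
        d["cohort"]["effect_profile"] = {
            k: list(v) for k, v in d["cohort"]["effect_profile"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sirs" in d:
            d["sirs"] = ons.SirsConfig(**d["sirs"])
        if "shock" in d:
            d["shock"] = ons.ShockConfig(**d["shock"])
        if "fold_counts" in d:
            d["fold_counts"] = tuple(d["fold_counts"])
        if "cohort" in d:
            c = dict(d["cohort"])
            if "effect_profile" in c:
                c["effect_profile"] = {
                    k: tuple(v) for k, v in c["effect_profile"].items()}
            if "shock_profile" in c:
                sp = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in c["shock_profile"].items()}
                c["shock_profile"] = syn.ShockProfile(**sp)
            if "post_onset_margin_h" in c:
                c["post_onset_margin_h"] = tuple(c["post_onset_margin_h"])
            d["cohort"] = syn.CohortSpec(**c)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def cohort_paths(directory: str | Path) -> tuple[Path, Path, Path]:
    d = Path(directory)
    return d / "vitals.csv", d / "fluids.csv", d / "outcomes.csv"


# ---------------------------------------------------------------------------
# stages, each returning the tables it wrote

def stage_simulate(config: RunConfig, out_dir: Path) -> dict:
    records, truth = syn.generate_cohort(config.cohort)
    cio.write_cohort(records, *cohort_paths(out_dir))
    syn.write_ground_truth(truth, out_dir / "ground_truth.csv")
    return {"n_patients": len(records),
            "outputs": ["vitals.csv", "fluids.csv", "outcomes.csv",
                        "ground_truth.csv"]}


def stage_filter(records: list[cio.PatientRecord],
                 out_dir: Path) -> tuple[list[cio.PatientRecord], dict]:
    kept, reports = cio.filter_cohort(records)
    df = pd.DataFrame(
        [(r.patient_id, r.included, ";".join(r.failed_rules))
         for r in reports],
        columns=["patient_id", "included", "failed_rules"])
    df.to_csv(out_dir / "inclusion.csv", index=False)
    return kept, {"n_in": len(records), "n_included": len(kept),
                  "outputs": ["inclusion.csv"]}


def stage_detect_onset(records: list[cio.PatientRecord], config: RunConfig,
                       out_dir: Path) -> tuple[dict[str, float], dict]:
    onset_rows, episode_rows = [], []
    onsets: dict[str, float] = {}
    reasons: dict[str, int] = {}
    for rec in records:
        result = ons.detect_shock_onset(rec, config.sirs, config.shock)
        reasons[result.reason] = reasons.get(result.reason, 0) + 1
        onset_rows.append((rec.patient_id,
                           "" if result.onset_h is None else result.onset_h,
                           result.reason))
        for ep in result.episodes:
            episode_rows.append((rec.patient_id, ep.kind, ep.start_h,
                                 ep.end_h,
                                 "" if ep.fluid_ml is None else ep.fluid_ml))
        if result.onset_h is not None:
            onsets[rec.patient_id] = result.onset_h
    pd.DataFrame(onset_rows,
                 columns=["patient_id", "onset_h", "reason"]).to_csv(
        out_dir / "onsets.csv", index=False)
    pd.DataFrame(episode_rows,
                 columns=["patient_id", "kind", "start_h", "end_h",
                          "fluid_ml"]).to_csv(
        out_dir / "episodes.csv", index=False)
    return onsets, {"n_labeled": len(onsets),
                    "dropped_by_reason": {k: v for k, v in reasons.items()
                                          if k != "labeled"},
                    "outputs": ["onsets.csv", "episodes.csv"]}


def stage_extract_features(
    records: list[cio.PatientRecord], onsets: dict[str, float],
    config: RunConfig, out_dir: Path,
) -> tuple[feat.CohortMatrix | None, dict]:
    vectors = [
        feat.extract_features(rec, onsets[rec.patient_id],
                              config.window_h, config.mortality_horizon_h)
        for rec in records if rec.patient_id in onsets
    ]
    if len(vectors) < 2:
        return None, {"n_patients": len(vectors), "outputs": [],
                      "skipped": "fewer than 2 patients with an onset"}
    matrix = feat.assemble_matrix(vectors)
    matrix.to_frame(imputed=False).to_csv(out_dir / "features.csv",
                                          index=False)
    matrix.to_frame(imputed=True).to_csv(out_dir / "features_imputed.csv",
                                         index=False)
    return matrix, {"n_patients": len(vectors),
                    "n_imputed_cells": int(matrix.missing_mask.sum()),
                    "outputs": ["features.csv", "features_imputed.csv"]}


def stage_screen(matrix: feat.CohortMatrix, config: RunConfig,
                 out_dir: Path) -> dict:
    results = scr.screen(matrix, config.alpha)
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        out_dir / "screen.csv", index=False)
    n_sig = sum(r.significant for r in results)
    return {"n_significant": n_sig, "outputs": ["screen.csv"]}


def _curve_to_dict(curve: mod.CvCurve) -> dict:
    return {
        "n_folds": curve.n_folds,
        "lambdas": [float(x) for x in curve.lambdas],
        "cv_error": [float(x) for x in curve.cv_error],
        "cv_se": [float(x) for x in curve.cv_se],
        "lambda_min": curve.lambda_min,
        "lambda_1se": curve.lambda_1se,
    }


def report_to_dict(report: mod.ModelReport) -> dict:
    d = dataclasses.asdict(report)
    d["cv_curves"] = {str(k): _curve_to_dict(v)
                      for k, v in report.cv_curves.items()}
    return d


def stage_fit(
    matrix: feat.CohortMatrix, config: RunConfig,
    out_dir: Path, screen_path: Path | None = None,
) -> tuple[mod.ModelReport, dict]:
    report = mod.fit_mortality_model(
        matrix, alpha_mix=config.alpha_mix, fold_counts=config.fold_counts,
        seed=config.seed, eval_folds=config.eval_folds)
    with open(out_dir / "model_report.json", "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)

    sig_univariate: set[str] = set()
    if screen_path is not None and screen_path.exists():
        sdf = pd.read_csv(screen_path)
        sig_univariate = set(sdf.loc[sdf["significant"], "feature"])
    rows = [(f, report.coefficients.get(f),
             report.standardized_coefficients.get(f),
             report.vif.get(f), f in sig_univariate)
            for f in report.selected_features]
    pd.DataFrame(rows, columns=["feature", "coefficient",
                                "coefficient_std", "vif",
                                "significant_univariate"]).to_csv(
        out_dir / "coefficients.csv", index=False)
    return report, {"n_selected": len(report.selected_features),
                    "chosen_folds": report.chosen_folds,
                    "mse": report.mse, "auc_mean": report.auc_mean,
                    "auc_sd": report.auc_sd,
                    "outputs": ["model_report.json", "coefficients.csv"]}


def stage_evaluate(matrix: feat.CohortMatrix, config: RunConfig,
                   out_dir: Path,
                   report: mod.ModelReport | None = None) -> dict:
    """Per-fold-count CV AUC of the final refit model."""
    if report is None:
        report = mod.fit_mortality_model(
            matrix, alpha_mix=config.alpha_mix,
            fold_counts=config.fold_counts,
            seed=config.seed, eval_folds=config.eval_folds)
    rows = []
    if report.selected_features:
        for k in config.fold_counts:
            _, _, auc_mean, auc_sd = mod.finalize_model(
                matrix, report.selected_features, seed=config.seed,
                eval_folds=k)
            rows.append((k, auc_mean, auc_sd))
    pd.DataFrame(rows, columns=["folds", "auc_mean", "auc_sd"]).to_csv(
        out_dir / "auc.csv", index=False)
    return {"outputs": ["auc.csv"]}


def run_all(config: RunConfig, out_dir: str | Path,
            cohort_dir: str | Path | None = None) -> dict:
    """Run every stage in order and write ``manifest.json``.

    When ``cohort_dir`` is given its cohort files are used instead of
    simulating.  Stages whose inputs are empty are skipped with an
    explanatory manifest entry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(),
                      "config_hash": config.config_hash(), "stages": {}}

    if cohort_dir is None:
        manifest["stages"]["simulate"] = stage_simulate(config, out_dir)
        cohort_dir = out_dir
    records = cio.read_cohort(*cohort_paths(cohort_dir))

    records, info = stage_filter(records, out_dir)
    manifest["stages"]["filter"] = info
    onsets, info = stage_detect_onset(records, config, out_dir)
    manifest["stages"]["detect_onset"] = info
    matrix, info = stage_extract_features(records, onsets, config, out_dir)
    manifest["stages"]["extract_features"] = info

    if matrix is None or len(set(matrix.labels)) < 2:
        why = ("no onset-labeled patients" if matrix is None
               else "only one outcome class present")
        manifest["stages"]["screen"] = {"skipped": why, "outputs": []}
        manifest["stages"]["fit"] = {"skipped": why, "outputs": []}
        manifest["stages"]["evaluate"] = {"skipped": why, "outputs": []}
    else:
        manifest["stages"]["screen"] = stage_screen(matrix, config, out_dir)
        report, info = stage_fit(matrix, config, out_dir,
                                 out_dir / "screen.csv")
        manifest["stages"]["fit"] = info
        manifest["stages"]["evaluate"] = stage_evaluate(matrix, config,
                                                        out_dir, report)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def matrix_from_feature_frame(df: pd.DataFrame) -> feat.CohortMatrix:
    """Rebuild a cohort matrix from a wide feature table (NaN = missing)."""
    vectors = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        values = {name: (None if pd.isna(d[name]) else float(d[name]))
                  for name in feat.FEATURE_NAMES}
        vectors.append(feat.FeatureVector(str(d["patient_id"]), values,
                                          str(d["label"])))
    return feat.assemble_matrix(vectors)
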
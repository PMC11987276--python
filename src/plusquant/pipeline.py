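"""Batch orchestration: preprocess -> segment -> quantify -> model.

Runs over a cohort directory in the layout written by
:func:`plusquant.phantom.generate_cohort` (images/, masks/, discs.csv,
grades.csv) and produces per-image feature rows, severity predictions
and cross-validation metrics, together with a machine-readable run
manifest.  Failures are isolated per image unless strict mode is on.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    FeatureVector,
    FEATURE_NAMES,
    SELECTED_ALIASES,
    OpticDiscAnnotation,
    compute_feature_vector,
)
from .grading import GradeTable
from .model import fit_linear, kfold_cv, predict_severity
from .morphometry import measure_graph


@dataclass
class PipelineConfig:
    min_segment_length_px: float = 10.0
    smoothing_sigma_px: float = 2.0
    resample_spacing_px: float = 1.0
    top_curvature_percent: float = 1.0
    n_selected_features: int = 4
    cv_folds: int = 5
    seed: int = 0
    strict_mode: bool = False

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    version: str = __version__
    started: float = field(default_factory=time.time)
    finished: float = 0.0
    outputs: list = field(default_factory=list)
    per_image: dict = field(default_factory=dict)  # image_id -> "ok" | error text

    def record(self, image_id: str, status: str) -> None:
        self.per_image[image_id] = status

    def save(self, path) -> None:
        self.finished = time.time()
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def read_discs(path) -> dict:
    df = pd.read_csv(path)
    return {
        str(r.image_id): OpticDiscAnnotation(
            center=(float(r.center_row), float(r.center_col)), diameter_px=float(r.diameter_px)
        )
        for r in df.itertuples()
    }


def _load_mask(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("L")) > 127


def quantify_image(mask: np.ndarray, disc: OpticDiscAnnotation,
                   config: PipelineConfig, image_id: str = "") -> FeatureVector:
    """Mask + disc annotation -> 10-feature morphometric vector."""
    graph = measure_graph(
        mask,
        min_length_px=config.min_segment_length_px,
        sigma_px=config.smoothing_sigma_px,
        spacing_px=config.resample_spacing_px,
    )
    return compute_feature_vector(
        graph,
        mask,
        disc,
        top_percent=config.top_curvature_percent,
        strict=config.strict_mode,
        image_id=image_id,
    )


def run_quantify(cohort_dir, config: PipelineConfig | None = None, out_dir=None) -> tuple:
    """Quantify every image in a cohort directory.

    Returns ``(features DataFrame, RunManifest)``; the DataFrame has one
    row per successfully processed image and the 10 feature columns plus
    F1-F4 aliases.
    """
    config = config or PipelineConfig()
    cohort = Path(cohort_dir)
    manifest = RunManifest(command="quantify", config_hash=config.hash(), seed=config.seed)
    discs = read_discs(cohort / "discs.csv")
    rows = []
    for mask_path in sorted((cohort / "masks").glob("*.png")):
        image_id = mask_path.stem
        if image_id not in discs:
            msg = "missing optic-disc annotation"
            if config.strict_mode:
                raise ValueError(f"{image_id}: {msg}")
            manifest.record(image_id, f"skipped: {msg}")
            continue
        try:
            fv = quantify_image(_load_mask(mask_path), discs[image_id], config, image_id)
        except Exception as exc:  # noqa: BLE001 - per-image fault isolation
            if config.strict_mode:
                raise
            manifest.record(image_id, f"failed: {exc}")
            continue
        row = {"image_id": image_id, **{k: fv.values[k] for k in FEATURE_NAMES}}
        for alias, name in SELECTED_ALIASES.items():
            row[alias] = fv.values[name]
        rows.append(row)
        manifest.record(image_id, "ok")
    features = pd.DataFrame(rows).set_index("image_id") if rows else pd.DataFrame()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fpath = out / "features.csv"
        features.to_csv(fpath, float_format="%.10g")
        manifest.outputs.append(str(fpath))
        manifest.save(out / "manifest_quantify.json")
    return features, manifest


def run_end_to_end(cohort_dir, config: PipelineConfig | None = None, out_dir=None,
                   model=None) -> dict:
    """Quantify, fit the severity model against the average score, predict, cross-validate.

    When the cohort ships a grade table the model is fitted to the
    experts' average score and cross-validated; without grades a
    pre-fitted ``model`` must be supplied and only predictions are made.
    Returns a dict with features, predictions, the model, and the CV
    report (None without grades).
    """
    config = config or PipelineConfig()
    cohort = Path(cohort_dir)
    features, manifest = run_quantify(cohort, config, out_dir=out_dir)
    manifest.command = "end_to_end"
    if features.empty:
        raise ValueError("no image could be quantified")
    selected = ["F1", "F2", "F3", "F4"]
    X = features[selected].to_numpy(dtype=float)
    finite = np.isfinite(X).all(axis=1)
    X, idx = X[finite], features.index[finite]

    grades_path = cohort / "grades.csv"
    cv_report = None
    if grades_path.exists():
        table = GradeTable.from_csv(grades_path)
        avg = table.average_scores()
        orphans = sorted(set(idx) ^ set(avg.index))
        if orphans:
            raise ValueError(f"grade/feature image-id mismatch: {orphans}")
        y = avg.loc[idx].to_numpy(dtype=float)
        model = fit_linear(X, y, feature_names=selected)
        cv_report = kfold_cv(X, y, k=config.cv_folds, seed=config.seed)
    elif model is None:
        raise FileNotFoundError(
            "cohort has no grades.csv: supply a pre-fitted model to predict with"
        )
    preds = [predict_severity(model, xi) for xi in X]
    predictions = pd.DataFrame(
        {"raw": [p[0] for p in preds], "clamped": [p[1] for p in preds]}, index=idx
    )
    if out_dir is not None:
        out = Path(out_dir)
        ppath = out / "predictions.csv"
        predictions.to_csv(ppath, float_format="%.10g")
        manifest.outputs.append(str(ppath))
        if cv_report is not None:
            cvpath = out / "cv_report.json"
            blob = asdict(cv_report)
            blob["fold_assignments"] = blob["fold_assignments"].tolist()
            cvpath.write_text(json.dumps(blob, indent=2))
            manifest.outputs.append(str(cvpath))
        manifest.save(out / "manifest_end_to_end.json")
    return {
        "features": features,
        "predictions": predictions,
        "model": model,
        "cv_report": cv_report,
        "manifest": manifest,
    }
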
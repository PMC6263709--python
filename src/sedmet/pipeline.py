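"""End-to-end orchestration of the measurement pipeline.

The minute-by-minute cascade: (1) classify each minute's posture from the
thigh accelerometer with the fixed tree; (2) route sitting minutes to the
sitting MET model and standing minutes to the standing MET model (walking
minutes are excluded from MET classification — they are used to recognise
non-stationary office activity, not to grade it); (3) report the activity as
sedentary behavior / active sitting / inactive standing / active standing.

`run_calibration_study` reproduces the calibration protocol on a labeled
dataset: stepwise feature inclusion under LOPO cross-validation, run once
per objective (AUC, MCC) for sitting and standing separately, plus a
channel-restricted run, and OR-combinations of the picked models when they
improve performance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .calorimetry import CATEGORY_INACTIVE
from .features import FeatureConfig, feature_matrix
from .metrics import PerformanceReport, evaluate_predictions, percent
from .selection import (
    GroupedDataset,
    SelectionConfig,
    StepwiseForwardSelector,
    emg_channels_of,
    lopo_cv_combined,
)
from .synth import GeneratorConfig
from .tree import PostureThresholds, TreeConfig, posture_tree

logger = logging.getLogger("sedmet")

ACTIVITY_SB = "SB"
ACTIVITY_ACTIVE_SITTING = "active sitting"
ACTIVITY_INACTIVE_STANDING = "inactive standing"
ACTIVITY_ACTIVE_STANDING = "active standing"
ACTIVITY_EXCLUDED = "excluded"


@dataclass
class PipelineConfig:
    """One config object for the whole pipeline; round-trips through YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    posture: PostureThresholds = field(default_factory=PostureThresholds)
    output_dir: str = "sedmet_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sel = dict(d.get("selection", {}))
        if "tree" in sel:
            sel["tree"] = TreeConfig(**sel["tree"])
        return cls(
            generator=GeneratorConfig(**d.get("generator", {})),
            features=FeatureConfig(**d.get("features", {})),
            tree=TreeConfig(**d.get("tree", {})),
            selection=SelectionConfig(**sel),
            posture=PostureThresholds(**d.get("posture", {})),
            output_dir=d.get("output_dir", "sedmet_out"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class MinuteClassification:
    """Cascade output for one minute."""

    minute_index: int
    participant_id: str
    posture: str
    activity: str
    score: float | None = None  # inactive-class score of the MET model used

    def __post_init__(self):
        if (self.activity == ACTIVITY_EXCLUDED) != (self.posture == "walking"):
            raise ValueError("walking minutes, and only them, are excluded")


_ACTIVITY_BY = {
    ("sitting", True): ACTIVITY_SB,
    ("sitting", False): ACTIVITY_ACTIVE_SITTING,
    ("standing", True): ACTIVITY_INACTIVE_STANDING,
    ("standing", False): ACTIVITY_ACTIVE_STANDING,
}


def classify(minutes, sitting_model, standing_model,
             thresholds: PostureThresholds | None = None,
             feature_config: FeatureConfig | None = None) -> list[MinuteClassification]:
    """Run the posture -> MET cascade over labeled minutes.

    ``sitting_model`` / ``standing_model`` are calibrated binary classifiers
    over the MET feature set (plain trees or OR-combinations) predicting
    inactive/active.  Walking minutes are excluded from MET classification.
    """
    if sitting_model is None or standing_model is None:
        raise ValueError("both a sitting and a standing MET model are required")
    clf = posture_tree(thresholds)
    X = feature_matrix(minutes, kind="met", config=feature_config, with_labels=False)
    out = []
    for i, m in enumerate(minutes):
        posture = clf.classify_minute(m.accel_y)
        if posture == "walking":
            out.append(
                MinuteClassification(m.minute_index, m.participant_id, posture,
                                     ACTIVITY_EXCLUDED)
            )
            continue
        model = sitting_model if posture == "sitting" else standing_model
        row = X.iloc[[i]]
        pred = str(model.predict(row)[0])
        try:
            score = model.predict_score(row, positive_class=CATEGORY_INACTIVE)
        except TypeError:
            score = model.predict_score(row)
        score = float(np.asarray(score).ravel()[0])
        out.append(
            MinuteClassification(
                m.minute_index,
                m.participant_id,
                posture,
                _ACTIVITY_BY[(posture, pred == CATEGORY_INACTIVE)],
                score=score,
            )
        )
    return out


@dataclass
class CalibrationResult:
    posture: str
    label: str  # e.g. "AUC", "MCC", "AUC-3ch", "AUC|MCC OR inactive"
    features: tuple[str, ...]
    used_features: tuple[str, ...]
    emg_channels: tuple[str, ...]
    report: PerformanceReport
    selector: StepwiseForwardSelector | None = None
    predictions: pd.DataFrame | None = None


@dataclass
class CalibrationArtifacts:
    results: list[CalibrationResult]

    def table(self) -> pd.DataFrame:
        """Model roster with pooled and individual metrics, one row each."""
        rows = []
        for r in self.results:
            row = {"posture": r.posture, "model": r.label,
                   "n_input_features": len(r.features),
                   "n_used_features": len(r.used_features),
                   "n_emg_channels": len(r.emg_channels),
                   "emg_channels": ",".join(sorted(r.emg_channels))}
            row.update(r.report.as_row())
            rows.append(row)
        return pd.DataFrame(rows)

    def get(self, posture: str, label: str) -> CalibrationResult:
        for r in self.results:
            if r.posture == posture and r.label == label:
                return r
        raise KeyError((posture, label))


def _dataset_for_posture(minutes, posture: str,
                         feature_config: FeatureConfig | None) -> GroupedDataset:
    X = feature_matrix(minutes, kind="met", config=feature_config, with_labels=True)
    sub = X[X["posture"] == posture]
    if sub.empty:
        raise ValueError(f"no minutes with posture {posture!r}")
    y = sub["met_category"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError(
            f"degenerate labels for posture {posture!r}: only class "
            f"{np.unique(y)[0]!r} present — cannot calibrate a binary model"
        )
    groups = sub["participant_id"].to_numpy()
    feats = sub.drop(columns=["participant_id", "task", "posture", "met", "met_category"])
    return GroupedDataset(X=feats.reset_index(drop=True), y=y, groups=groups)


def run_calibration_study(
    minutes,
    selection: SelectionConfig | None = None,
    feature_config: FeatureConfig | None = None,
    max_emg_channels: int | None = 3,
    postures=("sitting", "standing"),
    n_boot: int = 2000,
    seed: int = 0,
) -> CalibrationArtifacts:
    """The full MET calibration: per posture, stepwise selection with the AUC
    and the MCC objective, a channel-restricted run, and OR-combinations of
    the two picks when they beat the single models.
    """
    base = selection or SelectionConfig()
    results: list[CalibrationResult] = []
    for posture in postures:
        dataset = _dataset_for_posture(minutes, posture, feature_config)
        picks = {}
        runs = [("AUC", dataclasses.replace(base, objective="auc")),
                ("MCC", dataclasses.replace(base, objective="mcc"))]
        if max_emg_channels is not None:
            runs.append(
                (
                    f"AUC-{max_emg_channels}ch",
                    dataclasses.replace(
                        base, objective="auc", max_emg_channels=max_emg_channels
                    ),
                )
            )
        for label, cfg in runs:
            logger.info("calibrating %s / %s", posture, label)
            sel = StepwiseForwardSelector(config=cfg).fit(
                dataset.X, dataset.y, dataset.groups
            )
            report = evaluate_predictions(
                sel.best_result_.predictions, positive_class=CATEGORY_INACTIVE,
                n_boot=n_boot, seed=seed,
            )
            logger.info(
                "picked %s / %s: %d input features, objective %.4f",
                posture, label, len(sel.best_features_), sel.best_objective_,
            )
            res = CalibrationResult(
                posture=posture,
                label=label,
                features=sel.best_features_,
                used_features=sel.used_features_,
                emg_channels=tuple(sorted(emg_channels_of(sel.used_features_))),
                report=report,
                selector=sel,
                predictions=sel.best_result_.predictions,
            )
            results.append(res)
            picks[label] = res

        # OR-combinations of the AUC and MCC picks, either trigger class
        a, b = picks["AUC"], picks["MCC"]
        if set(a.features) != set(b.features):
            best_single_perf = max(a.report.perf, b.report.perf)
            for trigger in ("inactive", "active"):
                res = lopo_cv_combined(
                    dataset, list(a.features), list(b.features), trigger,
                    tree_config=base.tree, positive_class=CATEGORY_INACTIVE,
                )
                report = evaluate_predictions(
                    res.predictions, positive_class=CATEGORY_INACTIVE,
                    n_boot=n_boot, seed=seed,
                )
                if report.perf > best_single_perf:
                    feats = tuple(sorted(set(a.features) | set(b.features)))
                    used = tuple(sorted(set(a.used_features) | set(b.used_features)))
                    results.append(
                        CalibrationResult(
                            posture=posture,
                            label=f"AUC&MCC OR {trigger}",
                            features=feats,
                            used_features=used,
                            emg_channels=tuple(sorted(emg_channels_of(used))),
                            report=report,
                            predictions=res.predictions,
                        )
                    )
    return CalibrationArtifacts(results=results)


def summarize_time_budget(minutes) -> dict[str, float]:
    """Per posture, the percentage of minutes at <= 1.5 MET.

    Only postures with at least one labeled minute appear; minutes without a
    MET category are ignored.
    """
    rows = [(m.posture, m.met_category) for m in minutes if m.met_category is not None]
    out: dict[str, float] = {}
    for posture in dict.fromkeys(p for p, _ in rows):
        cats = [c for p, c in rows if p == posture]
        out[posture] = percent(sum(c == CATEGORY_INACTIVE for c in cats), len(cats))
    return out


def weighted_inactive_fraction(minute_counts, pct_inactive) -> float:
    """Aggregate sedentary/inactive share of a posture's time, in percent.

    Combines per-task minute counts with per-task percentages of time at
    <= 1.5 MET into the overall share, rounded to the nearest integer
    percent (the form in which such study summaries are reported).
    """
    counts = np.asarray(minute_counts, dtype=float)
    pct = np.asarray(pct_inactive, dtype=float)
    if counts.shape != pct.shape or counts.size == 0:
        raise ValueError("minute counts and percentages must align")
    if np.any(counts < 0) or np.any((pct < 0) | (pct > 100)):
        raise ValueError("invalid counts or percentages")
    return float(round(np.sum(counts * pct) / np.sum(counts)))


# ---------------------------------------------------------------------------
# Study loading (the real-data path accepts exactly the generator's formats)


def load_study_minutes(directory, schema: sio.SignalSchema | None = None,
                       min_run: int = 30) -> list[sio.LabeledMinute]:
    """Load a study directory written by ``synth.write_study`` (or real data
    in the same CSV formats) and return labeled minutes.

    Expects per-participant ``<pid>_emg.csv`` / ``<pid>_accel.csv`` /
    ``<pid>_calorimeter.csv``, an ``annotations.csv``, and optionally a
    ``ground_truth.csv`` with per-task MET values to attach.
    """
    directory = Path(directory)
    schema = schema or sio.SignalSchema()
    annotations = sio.read_annotations_csv(directory / "annotations.csv")
    truth = None
    gt_path = directory / "ground_truth.csv"
    if gt_path.exists():
        truth = pd.read_csv(gt_path)
    minutes: list[sio.LabeledMinute] = []
    for pid in dict.fromkeys(a.participant_id for a in annotations):
        emg, accel, cal = sio.read_signals(
            {
                "emg": directory / f"{pid}_emg.csv",
                "accel": directory / f"{pid}_accel.csv",
                "calorimeter": directory / f"{pid}_calorimeter.csv",
            },
            schema,
        )
        anns = [a for a in annotations if a.participant_id == pid]
        part = sio.epoch_minutes(emg, accel, cal, anns, min_run=min_run)
        if truth is not None:
            lookup = {
                (r.task, r.posture): (float(r.met), str(r.met_category))
                for r in truth[truth["participant_id"] == pid].itertuples(index=False)
            }
            for m in part:
                if (m.task, m.posture) in lookup:
                    m.met, m.met_category = lookup[(m.task, m.posture)]
        minutes.extend(part)
    return minutes
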
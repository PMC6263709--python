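"""Classification performance metrics.

Conventions: the positive class throughout is the *inactive* one (sedentary
behavior while sitting, inactive standing while standing) — sensitivity is
the rate at which truly inactive minutes are recognised.  AUC is the
trapezoidal area under the ROC over all score thresholds, equal to the
tie-corrected Mann-Whitney concordance probability.  MCC of a confusion
matrix with a zero marginal is defined as 0 (holdout participants may lack a
class entirely).  Rates with a zero denominator are reported as absent
(None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def roc_auc(scores, labels, positive_class=None) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Computed as the tie-corrected Mann-Whitney statistic (average ranks), so
    identical scores contribute 1/2 concordance.  Raises if only one class is
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"AUC needs exactly 2 classes, got {classes.size}")
    if positive_class is None:
        positive_class = classes[-1]
    pos = labels == positive_class
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = inactive (SB)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive_class) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive_class
        pos_p = y_pred == positive_class
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
        )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any marginal is 0."""
    tp, fn, tn, fp = cm.tp, cm.fn, cm.tn, cm.fp
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom_sq))


@dataclass(frozen=True)
class Rates:
    sensitivity: float | None
    specificity: float | None
    ppv_inactive: float | None
    ppv_active: float | None
    perf: float | None


def rates(cm: ConfusionMatrix) -> Rates:
    """Sensitivity/specificity toward the inactive class, both PPVs, and the
    overall fraction of correctly classified minutes (Perf)."""

    def ratio(num, den):
        return num / den if den > 0 else None

    return Rates(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        ppv_inactive=ratio(cm.tp, cm.tp + cm.fp),
        ppv_active=ratio(cm.tn, cm.tn + cm.fn),
        perf=ratio(cm.tp + cm.tn, cm.total),
    )


@dataclass
class ParticipantSummary:
    """Median per-participant statistic with a bootstrap percentile 95% CI."""

    statistic: str
    median: float
    ci_low: float
    ci_high: float
    per_participant: dict[str, float] = field(default_factory=dict)
    skipped: tuple[str, ...] = ()


def _bootstrap_median_ci(values: np.ndarray, n_boot: int, rng) -> tuple[float, float]:
    if values.size == 1:
        v = float(values[0])
        return v, v
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    return float(np.percentile(medians, 2.5)), float(np.percentile(medians, 97.5))


def per_participant_summary(
    predictions: pd.DataFrame,
    positive_class: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, ParticipantSummary]:
    """Individual-level AUC and MCC medians with bootstrap 95% CIs.

    ``predictions`` must carry columns ``participant_id``, ``y_true``,
    ``score`` and ``y_pred``.  Participants with only one true class are
    skipped (and reported) — neither AUC nor a meaningful MCC exists for
    them.  CIs are percentile bootstrap over participants (default 2000
    resamples, seeded).
    """
    rng = np.random.default_rng(seed)
    auc_by, mcc_by, skipped = {}, {}, []
    for pid, grp in predictions.groupby("participant_id", sort=True):
        if np.unique(grp["y_true"]).size < 2:
            skipped.append(str(pid))
            continue
        auc_by[str(pid)] = roc_auc(grp["score"], grp["y_true"], positive_class)
        mcc_by[str(pid)] = mcc(
            ConfusionMatrix.from_predictions(grp["y_true"], grp["y_pred"], positive_class)
        )
    if len(auc_by) < 1:
        raise ValueError("no participant has both classes present")
    out = {}
    for name, values in (("auc", auc_by), ("mcc", mcc_by)):
        arr = np.asarray(list(values.values()), dtype=float)
        lo, hi = _bootstrap_median_ci(arr, n_boot, rng)
        out[name] = ParticipantSummary(
            statistic=name,
            median=float(np.median(arr)),
            ci_low=lo,
            ci_high=hi,
            per_participant=dict(values),
            skipped=tuple(skipped),
        )
    return out


@dataclass
class PerformanceReport:
    """Pooled and individual-level performance of one binary model."""

    auc: float
    mcc: float
    perf: float | None
    sensitivity: float | None
    specificity: float | None
    ppv_inactive: float | None
    ppv_active: float | None
    individual: dict[str, ParticipantSummary] | None = None

    def as_row(self) -> dict[str, object]:
        def pct(v):
            return None if v is None else round(100.0 * v, 1)

        row: dict[str, object] = {
            "AUC": round(self.auc, 3),
            "MCC": round(self.mcc, 3),
            "Perf_%": pct(self.perf),
            "Sensitivity_%": pct(self.sensitivity),
            "Specificity_%": pct(self.specificity),
            "PPV_inactive_%": pct(self.ppv_inactive),
            "PPV_active_%": pct(self.ppv_active),
        }
        if self.individual:
            for name, s in self.individual.items():
                row[f"individual_{name}_median"] = round(s.median, 3)
                row[f"individual_{name}_ci95"] = (
                    f"[{s.ci_low:.3f} {s.ci_high:.3f}]"
                )
        return row


def evaluate_predictions(
    predictions: pd.DataFrame,
    positive_class: str = "inactive",
    with_individual: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> PerformanceReport:
    """Full report from pooled holdout predictions.

    ``predictions``: columns ``y_true``, ``y_pred``, ``score`` and (when
    individual summaries are requested) ``participant_id``.
    """
    cm = ConfusionMatrix.from_predictions(
        predictions["y_true"], predictions["y_pred"], positive_class
    )
    r = rates(cm)
    individual = (
        per_participant_summary(predictions, positive_class, n_boot=n_boot, seed=seed)
        if with_individual
        else None
    )
    return PerformanceReport(
        auc=roc_auc(predictions["score"], predictions["y_true"], positive_class),
        mcc=mcc(cm),
        perf=r.perf,
        sensitivity=r.sensitivity,
        specificity=r.specificity,
        ppv_inactive=r.ppv_inactive,
        ppv_active=r.ppv_active,
        individual=individual,
    )


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Share of a total as a rounded percentage (bookkeeping helper)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return round(100.0 * numerator / denominator, ndigits)
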
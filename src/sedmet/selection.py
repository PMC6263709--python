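"""Feature-subset calibration under grouped cross-validation.

Model validity is always measured with hold-one-participant-out (LOPO)
cross-validation: a tree is trained on all minutes of all but one
participant, scores the holdout participant's minutes, and the objective
(AUC or MCC) is computed once over the pooled holdout predictions of all
folds.  This keeps every person strictly out of the training folds that
score them — the property that makes the calibration honest for new users.

Feature inclusion is the greedy forward wrapper: (1) build a model per
candidate feature, (2) evaluate each by LOPO, (3) keep the best, (4) try
adding each remaining feature to the kept set and repeat until no feature
remains.  The final model is the recorded pass winner maximising
objective - penalty * n_input_features, with a per-feature penalty of 1e-3
so equal-objective models resolve toward fewer inputs.  The tree that comes
out does not necessarily *use* every inputted feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger("sedmet")

from .metrics import ConfusionMatrix, mcc, roc_auc
from .tree import GiniTreeClassifier, TreeConfig


@dataclass
class GroupedDataset:
    """Feature matrix + binary labels + participant id per minute."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        n = len(self.X)
        if self.y.shape[0] != n or self.groups.shape[0] != n:
            raise ValueError("X, y and groups must have equal length")
        if np.unique(self.groups).size < 2:
            raise ValueError("need at least 2 participants")


@dataclass
class SelectionConfig:
    """Knobs of the stepwise search.

    ``penalty`` is the per-input-feature complexity penalty applied when the
    final model is picked from the recorded pass winners.  ``max_passes``
    caps the number of greedy passes (None = run until no candidate feature
    remains).  ``max_emg_channels`` restricts the subsets the search may
    visit to those touching at most that many distinct EMG channels
    (``restriction_mode='constrained'``) or filters the recorded models after
    an unrestricted run (``'posthoc'``).
    """

    objective: str = "auc"  # or "mcc"
    penalty: float = 1e-3
    tree: TreeConfig = field(default_factory=TreeConfig)
    positive_class: str | None = None
    max_passes: int | None = None
    max_emg_channels: int | None = None
    restriction_mode: str = "constrained"
    direction: str = "forward"  # "backward" available as the costlier variant

    def __post_init__(self):
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.objective not in ("auc", "mcc"):
            raise ValueError("objective must be 'auc' or 'mcc'")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if self.restriction_mode not in ("constrained", "posthoc"):
            raise ValueError("restriction_mode must be 'constrained' or 'posthoc'")


@dataclass
class LopoResult:
    predictions: pd.DataFrame  # participant_id, y_true, score, y_pred
    auc: float
    mcc: float

    def objective(self, name: str) -> float:
        return self.auc if name == "auc" else self.mcc


def emg_channels_of(features) -> frozenset[str]:
    """Distinct EMG channels touched by a feature-name collection."""
    out = set()
    for name in features:
        parts = str(name).split(".")
        if parts[0] == "emg":
            out.add(parts[1])
    return frozenset(out)


def lopo_cv(
    dataset: GroupedDataset,
    features,
    tree_config: TreeConfig | None = None,
    positive_class=None,
) -> LopoResult:
    """Hold-one-participant-out CV of a tree on a feature subset.

    Trains one tree per participant (on everyone else), scores that
    participant's minutes exactly once, and computes AUC and MCC over the
    pooled holdout predictions.  Asserts on every fold that the holdout
    participant is absent from the training fold.
    """
    features = list(features)
    if not features:
        raise ValueError("feature subset must be non-empty")
    tree_config = tree_config or TreeConfig()
    participants = np.unique(dataset.groups)
    if participants.size < 2:
        raise ValueError("LOPO needs at least 2 participants")
    if positive_class is None:
        positive_class = np.unique(dataset.y)[-1]

    # numpy views for the hot loop; feature names are irrelevant inside a fold
    Xv = np.ascontiguousarray(dataset.X[features].to_numpy(dtype=float))
    pid_col, true_col, score_col, pred_col = [], [], [], []
    for holdout in participants:
        train = dataset.groups != holdout
        assert holdout not in set(dataset.groups[train]), "participant leakage"
        est = GiniTreeClassifier(
            max_depth=tree_config.max_depth, min_leaf=tree_config.min_leaf
        ).fit(Xv[train], dataset.y[train])
        test = ~train
        logger.debug(
            "LOPO fold: holdout=%s, %d training / %d holdout minutes",
            holdout, int(train.sum()), int(test.sum()),
        )
        counts = est._leaf_counts(Xv[test])
        proba = counts / counts.sum(axis=1, keepdims=True)
        k = int(np.flatnonzero(est.classes_ == positive_class)[0])
        pid_col.append(dataset.groups[test])
        true_col.append(dataset.y[test])
        score_col.append(proba[:, k])
        pred_col.append(est.classes_[np.argmax(counts, axis=1)])
    pooled = pd.DataFrame(
        {
            "participant_id": np.concatenate(pid_col),
            "y_true": np.concatenate(true_col),
            "score": np.concatenate(score_col),
            "y_pred": np.concatenate(pred_col),
        }
    )
    assert len(pooled) == len(dataset.X), "every minute must be scored exactly once"
    cm = ConfusionMatrix.from_predictions(pooled["y_true"], pooled["y_pred"], positive_class)
    return LopoResult(
        predictions=pooled,
        auc=roc_auc(pooled["score"], pooled["y_true"], positive_class),
        mcc=mcc(cm),
    )


@dataclass
class PassRecord:
    """The winning model of one greedy pass."""

    features: tuple[str, ...]
    objective: float
    result: LopoResult


class StepwiseForwardSelector(BaseEstimator):
    """Greedy stepwise feature inclusion with a penalized final pick.

    ``fit(X, y, groups)`` runs the wrapper search; fitted attributes:

    - ``history_``: the winning model of each pass, in order;
    - ``best_features_``: input features of the penalized final pick;
    - ``best_result_``: its pooled LOPO predictions and objectives;
    - ``best_model_``: a tree refit on all data with those input features;
    - ``used_features_``: the features that tree actually splits on
      (a subset of the inputs).

    Ties in a pass break toward the lexicographically smallest feature name;
    ties in the final pick toward fewer input features.  A backward
    elimination variant (start full, drop one per pass) is available via
    ``direction='backward'``.
    """

    def __init__(self, config: SelectionConfig | None = None, **overrides):
        self.config = config
        self.overrides = overrides

    def _config(self) -> SelectionConfig:
        cfg = self.config or SelectionConfig()
        if self.overrides:
            cfg = replace(cfg, **self.overrides)
        return cfg

    def fit(self, X: pd.DataFrame, y, groups):
        cfg = self._config()
        dataset = GroupedDataset(X=X, y=np.asarray(y), groups=np.asarray(groups))
        candidates = sorted(str(c) for c in X.columns)
        if not candidates:
            raise ValueError("need at least one candidate feature")
        positive = cfg.positive_class
        if positive is None:
            positive = np.unique(dataset.y)[-1]

        if cfg.direction == "forward":
            history = self._forward(dataset, candidates, cfg, positive)
        else:
            history = self._backward(dataset, candidates, cfg, positive)

        eligible = history
        if cfg.max_emg_channels is not None and cfg.restriction_mode == "posthoc":
            eligible = [
                rec
                for rec in history
                if len(emg_channels_of(rec.features)) <= cfg.max_emg_channels
            ]
            if not eligible:
                raise ValueError("no recorded model satisfies the channel restriction")

        best = None
        for rec in sorted(eligible, key=lambda r: (len(r.features), r.features)):
            penalized = rec.objective - cfg.penalty * len(rec.features)
            if best is None or penalized > best[0]:
                best = (penalized, rec)
        pick = best[1]
        logger.info(
            "final pick: %d input features, %s=%.4f (penalized %.4f)",
            len(pick.features), cfg.objective, pick.objective, best[0],
        )

        self.history_ = history
        self.best_features_ = pick.features
        self.best_result_ = pick.result
        self.best_objective_ = pick.objective
        self.best_penalized_objective_ = best[0]
        self.positive_class_ = positive
        self.best_model_ = GiniTreeClassifier(
            max_depth=cfg.tree.max_depth, min_leaf=cfg.tree.min_leaf
        ).fit(dataset.X[list(pick.features)], dataset.y)
        self.used_features_ = self.best_model_.used_features_
        return self

    # -- search loops -----------------------------------------------------
    def _forward(self, dataset, candidates, cfg, positive) -> list[PassRecord]:
        selected: tuple[str, ...] = ()
        remaining = list(candidates)  # sorted: lexicographic tie-break
        history: list[PassRecord] = []
        while remaining:
            if cfg.max_passes is not None and len(history) >= cfg.max_passes:
                break
            best = None
            for f in remaining:
                subset = selected + (f,)
                if (
                    cfg.max_emg_channels is not None
                    and cfg.restriction_mode == "constrained"
                    and len(emg_channels_of(subset)) > cfg.max_emg_channels
                ):
                    continue
                res = lopo_cv(dataset, list(subset), cfg.tree, positive)
                obj = res.objective(cfg.objective)
                if best is None or obj > best[1]:
                    best = (f, obj, res)
            if best is None:  # every remaining feature violates the restriction
                break
            f, obj, res = best
            selected = selected + (f,)
            remaining.remove(f)
            logger.info(
                "pass %d: added %s -> %d features, %s=%.4f",
                len(history) + 1, f, len(selected), cfg.objective, obj,
            )
            history.append(PassRecord(features=selected, objective=obj, result=res))
        return history

    def _backward(self, dataset, candidates, cfg, positive) -> list[PassRecord]:
        selected = tuple(candidates)
        res = lopo_cv(dataset, list(selected), cfg.tree, positive)
        history = [
            PassRecord(features=selected, objective=res.objective(cfg.objective), result=res)
        ]
        while len(selected) > 1:
            if cfg.max_passes is not None and len(history) >= cfg.max_passes:
                break
            best = None
            for f in selected:
                subset = tuple(g for g in selected if g != f)
                res = lopo_cv(dataset, list(subset), cfg.tree, positive)
                obj = res.objective(cfg.objective)
                if best is None or obj > best[1]:
                    best = (subset, obj, res)
            selected, obj, res = best
            history.append(PassRecord(features=selected, objective=obj, result=res))
        return history

    # -- prediction with the final pick -----------------------------------
    def predict(self, X) -> np.ndarray:
        return self.best_model_.predict(X[list(self.best_features_)])

    def predict_score(self, X) -> np.ndarray:
        return self.best_model_.predict_score(
            X[list(self.best_features_)], positive_class=self.positive_class_
        )


def stepwise_include(X, y, groups, config: SelectionConfig | None = None) -> StepwiseForwardSelector:
    """Functional wrapper over :class:`StepwiseForwardSelector`."""
    return StepwiseForwardSelector(config=config).fit(X, y, groups)


class OrCombinedClassifier(BaseEstimator):
    """OR-combination of two binary classifiers on a trigger class.

    A minute is assigned the trigger class iff *either* component predicts
    it; otherwise the other class.  The combined score for the trigger class
    is the maximum of the component scores, so sensitivity for the trigger
    class can only grow relative to each component.
    """

    def __init__(self, model_a, model_b, trigger_class):
        self.model_a = model_a
        self.model_b = model_b
        self.trigger_class = trigger_class

    def _classes(self) -> np.ndarray:
        ca = np.asarray(self.model_a.classes_)
        cb = np.asarray(self.model_b.classes_)
        if ca.size != 2 or set(ca) != set(cb):
            raise ValueError("both models must be binary over the same classes")
        if self.trigger_class not in set(ca):
            raise ValueError(f"trigger class {self.trigger_class!r} unknown to the models")
        return ca

    def fit(self, X=None, y=None):
        self.classes_ = self._classes()
        return self

    def predict(self, X) -> np.ndarray:
        classes = self._classes()
        other = classes[classes != self.trigger_class][0]
        trigger = (self.model_a.predict(X) == self.trigger_class) | (
            self.model_b.predict(X) == self.trigger_class
        )
        return np.where(trigger, self.trigger_class, other)

    def predict_score(self, X) -> np.ndarray:
        return np.maximum(
            self.model_a.predict_score(X, positive_class=self.trigger_class)
            if isinstance(self.model_a, GiniTreeClassifier)
            else self.model_a.predict_score(X),
            self.model_b.predict_score(X, positive_class=self.trigger_class)
            if isinstance(self.model_b, GiniTreeClassifier)
            else self.model_b.predict_score(X),
        )


def combine_or(model_a, model_b, trigger_class) -> OrCombinedClassifier:
    """Build and validate the OR-combination of two binary models."""
    return OrCombinedClassifier(model_a, model_b, trigger_class).fit()


def lopo_cv_combined(
    dataset: GroupedDataset,
    features_a,
    features_b,
    trigger_class,
    tree_config: TreeConfig | None = None,
    positive_class=None,
) -> LopoResult:
    """LOPO evaluation of an OR-combined pair, trained fold-by-fold."""
    tree_config = tree_config or TreeConfig()
    if positive_class is None:
        positive_class = np.unique(dataset.y)[-1]
    participants = np.unique(dataset.groups)
    frames = []
    for holdout in participants:
        train = dataset.groups != holdout
        assert holdout not in set(dataset.groups[train]), "participant leakage"
        test = ~train
        trees = []
        for feats in (features_a, features_b):
            Xf = dataset.X[list(feats)]
            trees.append(
                GiniTreeClassifier(
                    max_depth=tree_config.max_depth, min_leaf=tree_config.min_leaf
                ).fit(Xf[train], dataset.y[train])
            )
        combined = combine_or(trees[0], trees[1], trigger_class)
        Xa = dataset.X[list(features_a)][test]
        Xb = dataset.X[list(features_b)][test]
        score = np.maximum(
            trees[0].predict_score(Xa, positive_class=trigger_class),
            trees[1].predict_score(Xb, positive_class=trigger_class),
        )
        other = [c for c in trees[0].classes_ if c != trigger_class][0]
        pred = np.where(
            (trees[0].predict(Xa) == trigger_class) | (trees[1].predict(Xb) == trigger_class),
            trigger_class,
            other,
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": dataset.groups[test],
                    "y_true": dataset.y[test],
                    "score": score,
                    "y_pred": pred,
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    cm = ConfusionMatrix.from_predictions(pooled["y_true"], pooled["y_pred"], positive_class)
    return LopoResult(
        predictions=pooled,
        auc=roc_auc(pooled["score"], pooled["y_true"], positive_class),
        mcc=mcc(cm),
    )
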
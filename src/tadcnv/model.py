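"""Random-forest pathogenicity classifier: training, prediction, CV and metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from tadcnv import __version__
from tadcnv.preprocessing import Imputer, Scaler

DEFAULT_HYPERPARAMS = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "class_weight": "balanced_subsample",
}

DEFAULT_GRID = {
    "n_estimators": [200, 500, 1000],
    "max_depth": [None, 10, 20],
    "min_samples_leaf": [1, 5],
}


def encode_labels(labels: Sequence) -> np.ndarray:
    """Map labels to {0, 1} with 1 = pathogenic."""
    out = []
    for l in labels:
        if l in (1, True, "pathogenic"):
            out.append(1)
        elif l in (0, False, "nonpathogenic", "benign"):
            out.append(0)
        else:
            raise ValueError(f"cannot encode label {l!r}")
    return np.asarray(out, dtype=int)


@dataclass
class TrainedModel:
    """Fitted imputer + scaler + random forest with OOB bookkeeping."""

    imputer: Imputer
    scaler: Scaler
    forest: RandomForestClassifier
    feature_names: List[str]
    svtype: str = "DEL"
    training_seed: int = 0
    metadata: Dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        return self.scaler.transform(self.imputer.transform(features[self.feature_names]))


def train(
    train_features: pd.DataFrame,
    train_labels: Sequence,
    hyperparams: Optional[Dict] = None,
    seed: int = 0,
    svtype: str = "DEL",
    tune: bool = False,
    tuning_grid: Optional[Dict] = None,
    cv_folds: int = 5,
) -> TrainedModel:
    """Fit imputer, scaler and random forest (OOB scoring on) on training data.

    With ``tune=True`` a stratified grid search over ``tuning_grid`` is run on
    the training set only before the final fit.
    """
    y = encode_labels(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    imputer = Imputer().fit(train_features)
    scaler = Scaler().fit(imputer.transform(train_features))
    X = scaler.transform(imputer.transform(train_features))

    params = dict(DEFAULT_HYPERPARAMS)
    params.update(hyperparams or {})
    if tune:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(
            RandomForestClassifier(random_state=seed, **params),
            tuning_grid or DEFAULT_GRID,
            scoring="roc_auc",
            cv=cv,
        )
        search.fit(X.to_numpy(), y)
        params.update(search.best_params_)

    forest = RandomForestClassifier(
        random_state=seed, oob_score=True, bootstrap=True, n_jobs=1, **params
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(X.to_numpy(), y)
    return TrainedModel(
        imputer=imputer,
        scaler=scaler,
        forest=forest,
        feature_names=list(train_features.columns),
        svtype=svtype,
        training_seed=seed,
        metadata={
            "version": __version__,
            "hyperparams": params,
            "oob_score": float(forest.oob_score_),
            "n_training_rows": int(len(X)),
        },
    )


def predict(model: TrainedModel, cnv_features: pd.DataFrame) -> np.ndarray:
    """Pathogenicity score (probability of the pathogenic class) per row."""
    X = model.transform(cnv_features)
    pos = list(model.forest.classes_).index(1)
    return model.forest.predict_proba(X.to_numpy())[:, pos]


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence,
    k: int = 5,
    seed: int = 0,
    hyperparams: Optional[Dict] = None,
    return_models: bool = False,
):
    """Stratified k-fold CV with preprocessing re-fitted inside each fold
    (no leakage); returns the per-fold ROC-AUC list.

    ``return_models`` additionally returns the per-fold fitted models so the
    train-only fitting contract can be verified externally."""
    y = encode_labels(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes")
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members < k={k}")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs, models = [], []
    for train_idx, test_idx in cv.split(features, y):
        m = train(features.iloc[train_idx], y[train_idx], hyperparams=hyperparams, seed=seed)
        scores = predict(m, features.iloc[test_idx])
        aucs.append(roc_auc(scores, y[test_idx]))
        models.append(m)
    if return_models:
        return aucs, models
    return aucs


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """P(random pathogenic outscores random non-pathogenic), ties counted 1/2."""
    y = encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC undefined with a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def macro_f1(scores: Sequence[float], labels: Sequence, threshold: float = 0.5) -> float:
    """Macro-averaged F1 with score strictly greater than ``threshold`` called
    pathogenic; an empty predicted class contributes F1 = 0 with a warning."""
    y = encode_labels(labels)
    pred = (np.asarray(scores, dtype=float) > threshold).astype(int)
    for cls in (0, 1):
        if not np.any(pred == cls):
            warnings.warn(f"no variants predicted as class {cls}; its F1 is 0")
    return float(f1_score(y, pred, average="macro", zero_division=0))


def calibration_curve(
    scores: Sequence[float], labels: Sequence, n_bins: int = 10
) -> List[Tuple[float, float]]:
    """(mean predicted score, fraction of true positives) per equal-width bin
    on [0, 1]; empty bins are omitted."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    scores = np.asarray(scores, dtype=float)
    y = encode_labels(labels)
    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        out.append((float(scores[mask].mean()), float(y[mask].mean())))
    return out


# ---------------------------------------------------------------------------
# Out-of-bag predictions (used by the permutation-importance analysis)
# ---------------------------------------------------------------------------

def oob_votes(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Per-class OOB vote counts, shape (n_rows, n_classes).

    Each tree votes only on the rows absent from its bootstrap sample.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    votes = np.zeros((n, len(forest.classes_)), dtype=int)
    for tree, inbag in zip(forest.estimators_, forest.estimators_samples_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[inbag] = False
        if not oob_mask.any():
            continue
        pred = tree.predict(X[oob_mask]).astype(int)
        rows = np.flatnonzero(oob_mask)
        for cls_idx, cls in enumerate(forest.classes_):
            votes[rows[pred == cls], cls_idx] += 1
    return votes


def oob_accuracy(forest: RandomForestClassifier, X: np.ndarray, y: Sequence) -> float:
    """Accuracy of majority-vote OOB predictions, over rows with >= 1 vote."""
    y = np.asarray(y, dtype=int)
    votes = oob_votes(forest, X)
    voted = votes.sum(axis=1) > 0
    if not voted.any():
        raise ValueError("no out-of-bag predictions available; grow more trees")
    pred = forest.classes_[votes[voted].argmax(axis=1)]
    return float(np.mean(pred == y[voted]))
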
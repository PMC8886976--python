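"""Train/test splitting, imputation and [0,1] scaling with train-only fitting."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split


def stratified_split(
    features: pd.DataFrame,
    labels: Sequence,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Label-stratified split into (train_X, test_X, train_y, test_y)."""
    labels = np.asarray(labels)
    if not (0 <= test_fraction < 1):
        raise ValueError("test_fraction must be in [0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes to stratify")
    if test_fraction == 0:
        return features, features.iloc[:0], labels, labels[:0]
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has < 2 members; cannot stratify")
    train_X, test_X, train_y, test_y = train_test_split(
        features, labels, test_size=test_fraction, stratify=labels, random_state=seed
    )
    return train_X, test_X, train_y, test_y


class Imputer:
    """Fills missing values with the per-feature mean of the training rows."""

    def __init__(self) -> None:
        self.means_: Optional[pd.Series] = None

    def fit(self, train: pd.DataFrame) -> "Imputer":
        means = train.mean(axis=0, skipna=True)
        all_missing = means.index[means.isna()].tolist()
        if all_missing:
            raise ValueError(
                f"feature(s) with no non-missing training value: {all_missing}"
            )
        self.means_ = means
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None:
            raise RuntimeError("imputer is not fitted")
        return table.fillna(self.means_)

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


class Scaler:
    """Min-max scaler fitted on training rows; x -> (x - min) / (max - min).

    Constant training columns map to 0; values outside the training range are
    NOT clipped, so test values may fall outside [0, 1].
    """

    def __init__(self) -> None:
        self.min_: Optional[pd.Series] = None
        self.scale_: Optional[pd.Series] = None

    def fit(self, train: pd.DataFrame) -> "Scaler":
        self.min_ = train.min(axis=0)
        rng = train.max(axis=0) - self.min_
        self.scale_ = rng.where(rng > 0, 1.0)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.min_ is None:
            raise RuntimeError("scaler is not fitted")
        return (table - self.min_) / self.scale_

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


def fit_apply_imputer(train: pd.DataFrame, *others: pd.DataFrame):
    """Fit on ``train`` only, transform train and all ``others``; returns the
    transformed tables followed by the fitted imputer."""
    imp = Imputer().fit(train)
    return tuple(imp.transform(t) for t in (train, *others)) + (imp,)


def fit_apply_scaler(train: pd.DataFrame, *others: pd.DataFrame):
    """Fit on ``train`` only, transform train and all ``others``; returns the
    transformed tables followed by the fitted scaler."""
    sc = Scaler().fit(train)
    return tuple(sc.transform(t) for t in (train, *others)) + (sc,)
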
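"""Ranking analysis (1 pathogenic vs 99 size-matched controls) and
correlated-cluster permutation feature importance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from tadcnv.model import TrainedModel, oob_accuracy
from tadcnv.variants_io import ecdf_size_bins


@dataclass(frozen=True)
class ScoredVariant:
    id: str
    size: int
    score: float


@dataclass
class RankingBatch:
    pathogenic: ScoredVariant
    controls: List[ScoredVariant]
    seed: int


@dataclass
class ImportanceResult:
    clusters: List[List[str]]
    mean_loss: np.ndarray
    sd_loss: np.ndarray
    baseline_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_members": [",".join(c) for c in self.clusters],
                "mean_loss": self.mean_loss,
                "sd_loss": self.sd_loss,
            }
        )


def build_batches(
    pathogenic: Sequence[ScoredVariant],
    controls: Sequence[ScoredVariant],
    batch_size: int = 100,
    n_bins: int = 60,
    seed: int = 0,
) -> Tuple[List[RankingBatch], List[str]]:
    """One batch per eligible pathogenic variant: itself plus ``batch_size - 1``
    controls sampled without replacement from its closest control size bin.

    Pathogenic variants larger than the largest control, and variants whose
    bin holds fewer than ``batch_size - 1`` controls, are skipped and reported
    in the second return value.
    """
    controls = list(controls)
    if not controls:
        raise ValueError("controls must be non-empty")
    n_controls_needed = batch_size - 1
    binning = ecdf_size_bins([c.size for c in controls], n_bins=n_bins)
    ctrl_bins = binning.assign([c.size for c in controls])
    per_bin: Dict[int, List[ScoredVariant]] = {}
    for c, b in zip(controls, ctrl_bins):
        per_bin.setdefault(int(b), []).append(c)
    max_ctrl_size = max(c.size for c in controls)

    rng = np.random.default_rng(seed)
    batches, skipped = [], []
    for p in pathogenic:
        if p.size > max_ctrl_size:
            skipped.append(p.id)
            continue
        b = int(binning.assign([p.size])[0])
        pool = per_bin.get(b, [])
        if len(pool) < n_controls_needed:
            skipped.append(p.id)
            continue
        if len(pool) == n_controls_needed:
            chosen = list(pool)
        else:
            idx = rng.choice(len(pool), size=n_controls_needed, replace=False)
            chosen = [pool[i] for i in sorted(idx)]
        batches.append(RankingBatch(pathogenic=p, controls=chosen, seed=seed))
    return batches, skipped


def rank_in_batch(batch: RankingBatch, tie_mode: str = "random") -> int:
    """1-based rank of the pathogenic variant when the batch is sorted by
    descending score. Ties are broken uniformly at random under the batch seed
    (``tie_mode='random'``) or pessimistically (``'pathogenic_last'``)."""
    p = batch.pathogenic.score
    greater = sum(1 for c in batch.controls if c.score > p)
    ties = sum(1 for c in batch.controls if c.score == p)
    if ties == 0:
        return 1 + greater
    if tie_mode == "pathogenic_last":
        return 1 + greater + ties
    if tie_mode != "random":
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    # stable per-variant stream: python's hash() is salted across processes
    tag = zlib.crc32(batch.pathogenic.id.encode())
    rng = np.random.default_rng(np.random.SeedSequence([batch.seed, tag]))
    return 1 + greater + int(rng.integers(0, ties + 1))


def ranking_summary(
    ranks_by_replicate: Sequence[Sequence[int]],
    rank_bins: Sequence[Tuple[int, int]] = ((1, 5), (6, 10), (11, 20), (21, 50), (51, 100)),
) -> pd.DataFrame:
    """Mean percentage (and SD over replicates) of variants placed in each
    inclusive rank bin."""
    if len(ranks_by_replicate) == 0:
        raise ValueError("need at least one replicate")
    pct = np.zeros((len(ranks_by_replicate), len(rank_bins)))
    for i, ranks in enumerate(ranks_by_replicate):
        ranks = np.asarray(ranks)
        if ranks.size == 0:
            raise ValueError("replicate with no ranks")
        for j, (lo, hi) in enumerate(rank_bins):
            pct[i, j] = 100.0 * np.mean((ranks >= lo) & (ranks <= hi))
    return pd.DataFrame(
        {
            "rank_bin": [f"{lo}-{hi}" for lo, hi in rank_bins],
            "mean_pct": pct.mean(axis=0),
            "sd_pct": pct.std(axis=0),
        }
    )


def partial_correlation(features: pd.DataFrame, regularize: bool = True) -> pd.DataFrame:
    """Pairwise partial correlations (each pair conditioned on all remaining
    features), from the inverse covariance matrix.

    With ``regularize`` a ridge term 1e-6 * mean(diag) * I is added; without it,
    fewer rows than features + 2 (or a singular covariance) is an error.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if not regularize and n < p + 2:
        raise ValueError(f"need >= {p + 2} rows for {p} features without regularization")
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    if regularize:
        cov = cov + 1e-6 * np.mean(np.diag(cov)) * np.eye(p)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance; enable regularization") from exc
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    return pd.DataFrame(pcorr, index=features.columns, columns=features.columns)


def cluster_features(pcorr: pd.DataFrame, max_distance: float = 1.0) -> List[List[str]]:
    """Average-linkage hierarchical clustering on distance 1 - |pcorr|, cut at
    ``max_distance``; returns a partition of the feature names.

    Note: with many mutually independent features the sample |pcorr| stays
    slightly above 0, so a cut at exactly 1 tends to merge everything; use a
    smaller cut for structure on weakly correlated data.
    """
    names = list(pcorr.columns)
    if len(names) == 1:
        return [names]
    d = 1.0 - np.abs(pcorr.to_numpy(dtype=float))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    flat = fcluster(Z, t=max_distance, criterion="distance")
    clusters: Dict[int, List[str]] = {}
    for name, cid in zip(names, flat):
        clusters.setdefault(int(cid), []).append(name)
    return [clusters[c] for c in sorted(clusters)]


def cluster_permutation_importance(
    model: TrainedModel,
    train_features: pd.DataFrame,
    labels: Sequence,
    clusters: Sequence[Sequence[str]],
    n_seeds: int = 30,
    base_seed: int = 0,
) -> ImportanceResult:
    """Mean OOB-accuracy loss after jointly permuting each correlated feature
    cluster (one shared row permutation per cluster per seed), over ``n_seeds``
    repeats. The baseline OOB accuracy is computed once.
    """
    from tadcnv.model import encode_labels

    y = encode_labels(labels)
    X = model.transform(train_features)
    for cluster in clusters:
        unknown = [f for f in cluster if f not in X.columns]
        if unknown:
            raise ValueError(f"cluster references unknown feature(s): {unknown}")
    Xv = X.to_numpy()
    baseline = oob_accuracy(model.forest, Xv, y)
    col_idx = {c: i for i, c in enumerate(X.columns)}

    losses = np.zeros((len(clusters), n_seeds))
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    for s, seed in enumerate(seeds):
        srng = np.random.default_rng(int(seed))
        for ci, cluster in enumerate(clusters):
            perm = srng.permutation(len(Xv))
            Xp = Xv.copy()
            cols = [col_idx[f] for f in cluster]
            Xp[:, cols] = Xv[perm][:, cols]
            losses[ci, s] = baseline - oob_accuracy(model.forest, Xp, y)
    return ImportanceResult(
        clusters=[list(c) for c in clusters],
        mean_loss=losses.mean(axis=1),
        sd_loss=losses.std(axis=1),
        baseline_accuracy=baseline,
    )
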
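"""Per-CNV functional feature vectors restricted to the TAD environment.

The default registry holds the 12 documented features; user-supplied BED
tracks each add one distance feature. Missing values are encoded as NaN and
resolved later by the preprocessing imputer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from tadcnv.tad_annotation import TADEnvironment
from tadcnv.variants_io import CNV, GenomicInterval

DEFAULT_FEATURES = (
    "dist_gene",
    "dist_ddg2p_gene",
    "dist_enhancer",
    "dist_ctcf",
    "dist_boundary",
    "loeuf_closest_gene",
    "p_hi_closest_gene",
    "hi_log_odds_closest_gene",
    "enh_conservation_closest",
    "boundary_stability_closest",
    "pchic_score",
    "exon_overlap",
)

CODING_PENALTY_VALUES = {
    "p_hi_closest_gene": 0.0,
    "hi_log_odds_closest_gene": -10.0,
    "loeuf_closest_gene": 2.0,
}


@dataclass(frozen=True)
class PchicInteraction:
    """A promoter–other-end interaction fragment with its significance score."""

    promoter_gene_id: str
    fragment: GenomicInterval
    neg_log10_p: float

    def __post_init__(self) -> None:
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")


def distance_to_closest(
    cnv: CNV, elements: Sequence[GenomicInterval]
) -> Optional[int]:
    """Minimum gap (bp) from the CNV to any element; 0 on overlap, None if empty."""
    if not elements:
        return None
    return min(cnv.interval.distance_to(e) for e in elements)


def closest_element(cnv: CNV, elements: Sequence, key=lambda e: e):
    """Element achieving the minimum distance (ties: smaller start, then order).

    ``key`` extracts the GenomicInterval from richer records. Returns
    ``(element, distance)`` or ``(None, None)`` on an empty list.
    """
    if not elements:
        return None, None
    best, best_k = None, None
    for e in elements:
        iv = key(e)
        k = (cnv.interval.distance_to(iv), iv.start)
        if best_k is None or k < best_k:
            best, best_k = e, k
    return best, best_k[0]


def pchic_score(
    cnv: CNV,
    interactions: Sequence[PchicInteraction],
    gene_loeuf: Dict[str, Optional[float]],
    aggregation: str = "max",
    min_neg_log10_p: float = 3.0,
) -> float:
    """Regulatory-hit score from promoter-capture Hi-C fragments.

    Per gene g: (number of g's significant fragments the CNV overlaps) divided
    by LOEUF(g); the feature aggregates per-gene scores with ``max`` (default)
    or ``sum``. Genes with missing or zero LOEUF are skipped with a warning.
    """
    if aggregation not in ("max", "sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    counts: Dict[str, int] = {}
    for it in interactions:
        if it.neg_log10_p < min_neg_log10_p:
            continue
        if cnv.interval.overlaps(it.fragment):
            counts[it.promoter_gene_id] = counts.get(it.promoter_gene_id, 0) + 1
    scores = []
    for gene, n in counts.items():
        loeuf = gene_loeuf.get(gene)
        if loeuf is None or loeuf == 0:
            warnings.warn(f"gene {gene!r} skipped in pchic score: missing/zero LOEUF")
            continue
        scores.append(n / loeuf)
    if not scores:
        return 0.0
    return float(max(scores) if aggregation == "max" else sum(scores))


def exon_overlap(cnv: CNV, exons: Sequence[GenomicInterval]) -> int:
    """Number of distinct exon intervals the CNV intersects by >= 1 bp."""
    return sum(1 for e in exons if cnv.interval.overlaps(e))


def cnv_environments(cnv: CNV, environments: Sequence[TADEnvironment]) -> List[TADEnvironment]:
    return [env for env in environments if env.region.overlaps(cnv.interval)]


def annotate(
    cnvs: Sequence[CNV],
    environments: Sequence[TADEnvironment],
    pchic: Sequence[PchicInteraction] = (),
    feature_config: Optional[Sequence[str]] = None,
    extra_tracks: Optional[Dict[str, Sequence[GenomicInterval]]] = None,
    pchic_aggregation: str = "max",
) -> Tuple[pd.DataFrame, List[CNV]]:
    """Compute the feature table for all CNVs intersecting >= 1 TAD environment.

    Candidate elements for a CNV are the union over all environments it
    intersects. Returns ``(table, unscored)`` where ``unscored`` lists CNVs
    outside every environment. Row index is the CNV id, in input order.
    """
    extra_tracks = extra_tracks or {}
    available = list(DEFAULT_FEATURES) + [f"dist_{name}" for name in extra_tracks]
    enabled = list(feature_config) if feature_config is not None else list(DEFAULT_FEATURES) + [
        f"dist_{name}" for name in extra_tracks
    ]
    unknown = [f for f in enabled if f not in available]
    if unknown:
        raise ValueError(
            f"unknown feature(s) {unknown}; available features: {sorted(available)}"
        )

    rows, index, unscored = [], [], []
    for cnv in cnvs:
        envs = cnv_environments(cnv, environments)
        if not envs:
            unscored.append(cnv)
            continue
        genes = [g for env in envs for g in env.genes]
        enhancers = [e for env in envs for e in env.enhancers]
        ctcf = [c for env in envs for c in env.ctcf_sites]
        boundaries = []
        for env in envs:
            for b in env.boundaries:
                if b not in boundaries:
                    boundaries.append(b)
        exons = [ex for g in genes for ex in g.exons]
        gene_ids = {g.gene_id for g in genes}
        gene_loeuf = {g.gene_id: g.loeuf for g in genes}
        env_pchic = [it for it in pchic if it.promoter_gene_id in gene_ids]

        closest_gene, d_gene = closest_element(cnv, genes, key=lambda g: g.interval)
        ddg2p = [g for g in genes if g.is_ddg2p]
        closest_enh, d_enh = closest_element(cnv, enhancers, key=lambda e: e.interval)
        closest_bnd, d_bnd = closest_element(cnv, boundaries, key=lambda b: b.interval)

        nan = float("nan")
        row = {
            "dist_gene": nan if d_gene is None else d_gene,
            "dist_ddg2p_gene": distance_to_closest(cnv, [g.interval for g in ddg2p]),
            "dist_enhancer": nan if d_enh is None else d_enh,
            "dist_ctcf": distance_to_closest(cnv, ctcf),
            "dist_boundary": nan if d_bnd is None else d_bnd,
            "loeuf_closest_gene": nan if closest_gene is None else closest_gene.loeuf,
            "p_hi_closest_gene": nan if closest_gene is None else closest_gene.p_hi,
            "hi_log_odds_closest_gene": nan
            if closest_gene is None
            else closest_gene.hi_log_odds,
            "enh_conservation_closest": nan if closest_enh is None else closest_enh.conservation,
            "boundary_stability_closest": nan if closest_bnd is None else closest_bnd.stability,
            "pchic_score": pchic_score(cnv, env_pchic, gene_loeuf, pchic_aggregation),
            "exon_overlap": exon_overlap(cnv, exons),
        }
        for name, track in extra_tracks.items():
            env_elems = [
                iv
                for iv in track
                if any(env.region.overlaps(iv) for env in envs)
            ]
            row[f"dist_{name}"] = distance_to_closest(cnv, env_elems)
        rows.append({k: (np.nan if row[k] is None else row[k]) for k in enabled})
        index.append(cnv.id)

    table = pd.DataFrame(rows, index=pd.Index(index, name="cnv_id"), columns=enabled, dtype=float)
    return table, unscored


def coding_overlap_flags(
    cnvs: Sequence[CNV], environments: Sequence[TADEnvironment]
) -> pd.Series:
    """True where the CNV overlaps >= 1 exon of a gene in its environment(s)."""
    flags = {}
    for cnv in cnvs:
        exons = [
            ex
            for env in cnv_environments(cnv, environments)
            for g in env.genes
            for ex in g.exons
        ]
        flags[cnv.id] = exon_overlap(cnv, exons) > 0
    return pd.Series(flags, name="coding_overlap")


def coding_penalty_transform(features: pd.DataFrame, coding_overlap: Sequence[bool]) -> pd.DataFrame:
    """Set the gene-constraint features of non-coding rows to their least-important
    fixed values (p(HI)=0, HI log odds=-10, LOEUF=2); coding rows are unchanged.
    Idempotent.
    """
    coding_overlap = np.asarray(coding_overlap, dtype=bool)
    if len(coding_overlap) != len(features):
        raise ValueError("coding_overlap flags must align with feature rows")
    out = features.copy()
    noncoding = ~coding_overlap
    for col, value in CODING_PENALTY_VALUES.items():
        if col in out.columns:
            out.loc[noncoding, col] = value
    return out
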
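"""TAD environments: sort annotation tracks into TADs, stratify TADs and genes,
aggregate conservation, and derive padded tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from tadcnv.variants_io import GenomicInterval


@dataclass(frozen=True)
class GeneRecord:
    interval: GenomicInterval
    gene_id: str
    p_hi: Optional[float] = None
    loeuf: Optional[float] = None
    hi_log_odds: Optional[float] = None
    is_ddg2p: bool = False
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.p_hi is not None and not (0.0 <= self.p_hi <= 1.0):
            raise ValueError(f"p_hi outside [0,1] for {self.gene_id}")
        if self.loeuf is not None and self.loeuf < 0:
            raise ValueError(f"negative LOEUF for {self.gene_id}")
        for e in self.exons:
            if e.chrom != self.interval.chrom:
                raise ValueError(f"exon on wrong chromosome for {self.gene_id}")


@dataclass(frozen=True)
class EnhancerRecord:
    interval: GenomicInterval
    conservation: Optional[float] = None

    def __post_init__(self) -> None:
        if self.conservation is not None and self.conservation < 0:
            raise ValueError("conservation must be >= 0")


@dataclass(frozen=True)
class BoundaryRecord:
    interval: GenomicInterval
    stability: float


@dataclass
class TADEnvironment:
    """A TAD region together with the annotation elements sorted into it."""

    region: GenomicInterval
    genes: List[GeneRecord] = field(default_factory=list)
    enhancers: List[EnhancerRecord] = field(default_factory=list)
    ctcf_sites: List[GenomicInterval] = field(default_factory=list)
    boundaries: List[BoundaryRecord] = field(default_factory=list)
    regulatory_class: Optional[str] = None


@dataclass(frozen=True)
class TADClass:
    base: str  # no_annotation | regulatory_only | coding_only | coding_and_regulatory
    has_plof_intolerant_gene: bool
    has_conserved_enhancer: bool


CLASS_ORDER = ("no_annotation", "regulatory_only", "coding_only", "coding_and_regulatory")


def build_environments(
    tad_regions: Sequence[GenomicInterval],
    boundaries: Sequence[BoundaryRecord] = (),
    genes: Sequence[GeneRecord] = (),
    enhancers: Sequence[EnhancerRecord] = (),
    ctcf: Sequence[GenomicInterval] = (),
) -> List[TADEnvironment]:
    """Attach every annotation element to each TAD region it intersects.

    Elements straddling a TAD border are attached to all intersected TADs.
    The two boundaries closest to each TAD's edges are recorded as flanking.
    Overlapping TAD regions on one chromosome are rejected.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for r in tad_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, regions in by_chrom.items():
        regions.sort(key=lambda r: (r.start, r.end))
        for a, b in zip(regions, regions[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping TAD regions on {chrom}: {a} / {b}")

    envs = [TADEnvironment(region=r) for r in sorted(tad_regions, key=lambda r: (r.chrom, r.start))]
    env_index: Dict[str, list] = {}
    for e in envs:
        env_index.setdefault(e.region.chrom, []).append(e)

    def attach(elements, getter, target_name):
        for el in elements:
            iv = getter(el)
            for env in env_index.get(iv.chrom, ()):
                if env.region.overlaps(iv):
                    getattr(env, target_name).append(el)

    attach(genes, lambda g: g.interval, "genes")
    attach(enhancers, lambda e: e.interval, "enhancers")
    attach(ctcf, lambda c: c, "ctcf_sites")

    bnd_by_chrom: Dict[str, List[BoundaryRecord]] = {}
    for b in boundaries:
        bnd_by_chrom.setdefault(b.interval.chrom, []).append(b)
    for env in envs:
        cands = bnd_by_chrom.get(env.region.chrom, [])
        if not cands:
            continue
        mid = lambda b: (b.interval.start + b.interval.end) / 2
        left = min(cands, key=lambda b: abs(mid(b) - env.region.start))
        right = min(cands, key=lambda b: abs(mid(b) - env.region.end))
        env.boundaries = [left] if left is right else [left, right]
    return envs


def stratify_tads(
    environments: Sequence[TADEnvironment],
    loeuf_intolerant_max: float = 0.1,
    conservation_threshold: Optional[float] = None,
    conservation_q: float = 90.0,
) -> Dict[int, TADClass]:
    """Classify every environment by its coding/regulatory content.

    If ``conservation_threshold`` is None it is computed as the
    ``conservation_q`` percentile of all enhancer conservation scores across
    the supplied environments. Returns a map from environment index to class;
    ``regulatory_class`` is also set on each environment (base class string).
    """
    if conservation_threshold is None:
        scores = [
            e.conservation
            for env in environments
            for e in env.enhancers
            if e.conservation is not None
        ]
        conservation_threshold = (
            conservation_percentile_threshold(scores, conservation_q) if scores else np.inf
        )
    out: Dict[int, TADClass] = {}
    for i, env in enumerate(environments):
        has_coding = len(env.genes) > 0
        has_reg = len(env.enhancers) > 0 or len(env.ctcf_sites) > 0
        if has_coding and has_reg:
            base = "coding_and_regulatory"
        elif has_coding:
            base = "coding_only"
        elif has_reg:
            base = "regulatory_only"
        else:
            base = "no_annotation"
        plof = any(g.loeuf is not None and g.loeuf < loeuf_intolerant_max for g in env.genes)
        conserved = any(
            e.conservation is not None and e.conservation > conservation_threshold
            for e in env.enhancers
        )
        env.regulatory_class = base
        out[i] = TADClass(base, plof, conserved)
    return out


class ConservationTrack:
    """Per-base scores stored as (start, end, value) runs per chromosome."""

    def __init__(self, runs: Iterable[tuple]):
        self._runs: Dict[str, tuple] = {}
        by_chrom: Dict[str, list] = {}
        for chrom, start, end, value in runs:
            if end <= start:
                raise ValueError(f"empty run on {chrom}: [{start},{end})")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        for chrom, rs in by_chrom.items():
            rs.sort()
            for (s1, e1, _), (s2, _, _) in zip(rs, rs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping score runs on {chrom}")
            starts = np.array([r[0] for r in rs])
            ends = np.array([r[1] for r in rs])
            vals = np.array([r[2] for r in rs])
            self._runs[chrom] = (starts, ends, vals)

    def mean_over(self, interval: GenomicInterval) -> Optional[float]:
        if interval.chrom not in self._runs:
            return None
        starts, ends, vals = self._runs[interval.chrom]
        lo = np.maximum(starts, interval.start)
        hi = np.minimum(ends, interval.end)
        w = np.maximum(0, hi - lo)
        total = w.sum()
        if total == 0:
            return None
        return float((w * vals).sum() / total)


def aggregate_conservation(interval: GenomicInterval, track: ConservationTrack) -> Optional[float]:
    """Mean base-wise conservation over ``interval``; None when no base is scored."""
    return track.mean_over(interval)


def conservation_percentile_threshold(scores: Sequence[float], q: float) -> float:
    """Empirical ``q``-th percentile (linear interpolation) of the background
    score distribution; scores strictly above it count as conserved."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    if not (0 < q < 100):
        raise ValueError("q must be in (0, 100)")
    return float(np.percentile(scores, q))


def stratify_genes(
    genes: Sequence[GeneRecord],
    p_hi_high: float = 0.9,
    p_hi_low: float = 0.1,
    loeuf_low: float = 0.1,
    loeuf_high: float = 0.9,
    loeuf_low_is_intolerant: bool = True,
) -> Dict[str, List[GeneRecord]]:
    """Stratify genes by haploinsufficiency and LOEUF constraint.

    Strict inequalities throughout; genes with a missing score belong to no
    stratum on that axis. ``loeuf_low_is_intolerant`` follows standard LOEUF
    semantics (low = intolerant to loss of function); flip it to reproduce the
    transposed assignment.
    """
    strata: Dict[str, List[GeneRecord]] = {
        "HI": [],
        "HS": [],
        "pLoF_intolerant": [],
        "pLoF_tolerant": [],
    }
    low_key = "pLoF_intolerant" if loeuf_low_is_intolerant else "pLoF_tolerant"
    high_key = "pLoF_tolerant" if loeuf_low_is_intolerant else "pLoF_intolerant"
    for g in genes:
        if g.p_hi is not None:
            if g.p_hi > p_hi_high:
                strata["HI"].append(g)
            elif g.p_hi < p_hi_low:
                strata["HS"].append(g)
        if g.loeuf is not None:
            if g.loeuf < loeuf_low:
                strata[low_key].append(g)
            elif g.loeuf > loeuf_high:
                strata[high_key].append(g)
    return strata


def extend_intervals(
    intervals: Sequence[GenomicInterval],
    pad_bp: int,
    chrom_sizes: Dict[str, int],
) -> List[GenomicInterval]:
    """Grow each interval by ``pad_bp`` on both sides, clipped to the chromosome."""
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    out = []
    for iv in intervals:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        size = chrom_sizes[iv.chrom]
        out.append(
            GenomicInterval(iv.chrom, max(0, iv.start - pad_bp), min(size, iv.end + pad_bp))
        )
    return out


# ---------------------------------------------------------------------------
# Track readers (plain-text BED / TSV / bedGraph)
# ---------------------------------------------------------------------------

def _opt_float(s: str) -> Optional[float]:
    return None if s in (".", "", "NA", "nan") else float(s)


def read_tads_bed(path) -> List[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def read_boundaries_bed(path) -> List[BoundaryRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(BoundaryRecord(GenomicInterval(f[0], int(f[1]), int(f[2])), float(f[3])))
    return out


def read_genes_tsv(path) -> List[GeneRecord]:
    """Gene table: chrom start end gene_id p_hi loeuf hi_log_odds ddg2p exons.

    ``exons`` is a comma-separated list of start-end pairs; missing scores are '.'.
    """
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError("gene table must start with a 'chrom ...' header line")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, gene_id = f[0], int(f[1]), int(f[2]), f[3]
            exons = ()
            if len(f) > 8 and f[8] not in (".", ""):
                exons = tuple(
                    GenomicInterval(chrom, int(p.split("-")[0]), int(p.split("-")[1]))
                    for p in f[8].split(",")
                )
            out.append(
                GeneRecord(
                    GenomicInterval(chrom, start, end),
                    gene_id,
                    p_hi=_opt_float(f[4]),
                    loeuf=_opt_float(f[5]),
                    hi_log_odds=_opt_float(f[6]),
                    is_ddg2p=f[7] in ("1", "true", "True"),
                    exons=exons,
                )
            )
    return out


def read_enhancers_bed(path) -> List[EnhancerRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            cons = _opt_float(f[3]) if len(f) > 3 else None
            out.append(EnhancerRecord(GenomicInterval(f[0], int(f[1]), int(f[2])), cons))
    return out


def read_intervals_bed(path) -> List[GenomicInterval]:
    """Plain BED intervals (narrowPeak accepted; extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def read_bedgraph(path) -> List[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return out
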
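"""Reading, validation, filtering, deduplication and size-matching of CNV sets.

Coordinates are 0-based half-open throughout (BED convention). VCF input is
converted on read: POS (1-based) becomes ``start = POS - 1`` and INFO/END is
used directly as the exclusive end.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

SVTYPES = ("DEL", "DUP")
LABELS = ("pathogenic", "nonpathogenic", "unknown")

_AUTOSOME_RE = re.compile(r"^(chr)?([0-9]+)$")


class ParseError(ValueError):
    """Raised when an input line cannot be parsed; names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between the two intervals; 0 if they overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class CNV:
    """A copy-number variant with provenance and (optional) pathogenicity label."""

    interval: GenomicInterval
    svtype: str
    label: str = "unknown"
    af: Optional[float] = None
    source: str = ""
    id: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unsupported svtype {self.svtype!r}")
        if self.label not in LABELS:
            raise ValueError(f"unsupported label {self.label!r}")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"allele frequency outside [0,1]: {self.af}")

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class SizeBinning:
    """ECDF-quantile size bins; ``edges`` are strictly increasing thresholds."""

    edges: tuple

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("edges must contain >= 2 strictly increasing values")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, sizes) -> np.ndarray:
        """Bin index per size; values outside [min, max] clamp to the end bins."""
        e = np.asarray(self.edges, dtype=float)
        idx = np.searchsorted(e, np.asarray(sizes, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def is_autosome(chrom: str) -> bool:
    m = _AUTOSOME_RE.match(chrom)
    return m is not None and 1 <= int(m.group(2)) <= 22


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, default_source: str) -> CNV:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise ParseError(f"line {lineno}: expected >= 4 columns, got {len(fields)}")
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinates") from exc
    svtype = fields[3].upper()
    label = fields[4] if len(fields) > 4 and fields[4] not in (".", "") else "unknown"
    af = None
    if len(fields) > 5 and fields[5] not in (".", ""):
        try:
            af = float(fields[5])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: invalid AF {fields[5]!r}") from exc
    source = fields[6] if len(fields) > 6 else default_source
    cnv_id = fields[7] if len(fields) > 7 else f"{chrom}:{start}-{end}:{svtype}"
    try:
        return CNV(GenomicInterval(chrom, start, end), svtype, label, af, source, cnv_id)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def read_cnvs(path, format: str = "BED", source: str = "") -> list:
    """Read CNVs from a BED (chrom start end svtype [label] [af] [source] [id])
    or VCF (SVTYPE/END in INFO) file.

    Records with an unsupported SVTYPE are skipped; the number skipped is
    reported via a warning. Malformed lines raise :class:`ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.upper()
    if fmt == "BED":
        return _read_bed(path, source)
    if fmt == "VCF":
        return _read_vcf(path, source)
    raise ValueError(f"unsupported format {format!r}")


def _read_bed(path: Path, source: str) -> list:
    cnvs, skipped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 4 and fields[3].upper() not in SVTYPES:
                skipped += 1
                continue
            cnvs.append(_parse_bed_line(line, lineno, source))
    if skipped:
        warnings.warn(f"skipped {skipped} record(s) with unsupported SVTYPE in {path}")
    return cnvs


def _read_vcf(path: Path, source: str) -> list:
    import pysam

    cnvs, skipped = [], 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = str(rec.info.get("SVTYPE", "")).upper()
            if svtype not in SVTYPES:
                skipped += 1
                continue
            af = rec.info.get("AF")
            if isinstance(af, (tuple, list)):
                af = af[0] if af else None
            # pysam: rec.start is 0-based POS-1; rec.stop honours INFO/END.
            interval = GenomicInterval(rec.chrom, rec.start, rec.stop)
            cnvs.append(
                CNV(
                    interval,
                    svtype,
                    "unknown",
                    float(af) if af is not None else None,
                    source,
                    rec.id or f"{rec.chrom}:{rec.start}-{rec.stop}:{svtype}",
                )
            )
    if skipped:
        warnings.warn(f"skipped {skipped} record(s) with unsupported SVTYPE in {path}")
    return cnvs


def write_cnvs_bed(cnvs: Iterable[CNV], path) -> None:
    with open(path, "w") as fh:
        for c in cnvs:
            af = "." if c.af is None else f"{c.af:g}"
            fh.write(
                f"{c.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.svtype}\t"
                f"{c.label}\t{af}\t{c.source}\t{c.id}\n"
            )


def write_cnvs_vcf(cnvs: Iterable[CNV], path, chrom_sizes: dict) -> None:
    """Write a minimal symbolic-allele VCF 4.2 (1-based POS, INFO END/SVTYPE/AF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        for chrom, size in sorted(chrom_sizes.items()):
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in cnvs:
            info = f"SVTYPE={c.svtype};END={c.interval.end}"
            if c.af is not None:
                info += f";AF={c.af:g}"
            fh.write(
                f"{c.chrom}\t{c.interval.start + 1}\t{c.id or '.'}\tN\t<{c.svtype}>\t.\t.\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_cnvs(
    cnvs: Iterable[CNV],
    min_size_bp: int = 50,
    autosomes_only: bool = False,
    allowed_labels: Optional[set] = None,
    af_max: Optional[float] = None,
    af_strict: bool = True,
) -> list:
    """Keep CNVs with length strictly greater than ``min_size_bp`` that satisfy
    the chromosome/label/AF constraints.

    ``af_strict`` selects between ``af < af_max`` (default) and ``af <= af_max``;
    CNVs with missing AF pass the AF filter.
    """
    out = []
    for c in cnvs:
        if c.length <= min_size_bp:
            continue
        if autosomes_only and not is_autosome(c.chrom):
            continue
        if allowed_labels is not None and c.label not in allowed_labels:
            continue
        if af_max is not None and c.af is not None:
            if af_strict and not (c.af < af_max):
                continue
            if not af_strict and not (c.af <= af_max):
                continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Reciprocal-overlap deduplication
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 across chromosomes."""
    ov = a.overlap_len(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_and_deduplicate(
    cnvs: Sequence[CNV],
    threshold: float = 0.9,
    tie_rule: str = "smallest",
    priority: Optional[Sequence[str]] = None,
) -> list:
    """Single-linkage cluster CNVs by reciprocal overlap >= ``threshold`` and
    keep one representative per cluster.

    ``smallest`` keeps the shortest variant (ties: lexicographic
    (chrom, start, end, id)); ``source_priority`` keeps the variant whose
    source appears earliest in ``priority`` (unknown sources sort last, with
    a warning, then fall back to the smallest rule).
    Clustering is restricted to same-chromosome, same-svtype pairs.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if tie_rule not in ("smallest", "source_priority"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    if tie_rule == "source_priority" and priority is None:
        raise ValueError("source_priority requires a priority list")

    cnvs = list(cnvs)
    uf = _UnionFind(len(cnvs))
    by_group: dict = {}
    for i, c in enumerate(cnvs):
        by_group.setdefault((c.chrom, c.svtype), []).append(i)
    for idxs in by_group.values():
        idxs = sorted(idxs, key=lambda i: (cnvs[i].interval.start, cnvs[i].interval.end))
        # sweep: a qualifying pair must overlap, so only compare while intervals intersect
        for k, i in enumerate(idxs):
            a = cnvs[i].interval
            for j in idxs[k + 1 :]:
                b = cnvs[j].interval
                if b.start >= a.end:
                    break
                if reciprocal_overlap(a, b) >= threshold:
                    uf.union(i, j)

    clusters: dict = {}
    for i in range(len(cnvs)):
        clusters.setdefault(uf.find(i), []).append(i)

    unknown_sources: set = set()

    def smallest_key(i: int):
        c = cnvs[i]
        return (c.length, c.chrom, c.interval.start, c.interval.end, c.id)

    def priority_key(i: int):
        c = cnvs[i]
        try:
            rank = priority.index(c.source)
        except ValueError:
            rank = len(priority)
            unknown_sources.add(c.source)
        return (rank,) + smallest_key(i)

    key = smallest_key if tie_rule == "smallest" else priority_key
    kept = [cnvs[min(members, key=key)] for members in clusters.values()]
    if unknown_sources:
        warnings.warn(
            "sources absent from priority list treated as lowest priority: "
            + ", ".join(sorted(repr(s) for s in unknown_sources))
        )
    kept.sort(key=lambda c: (c.chrom, c.interval.start, c.interval.end, c.id))
    return kept


# ---------------------------------------------------------------------------
# ECDF size binning and size matching
# ---------------------------------------------------------------------------

def ecdf_size_bins(sizes: Sequence[int], n_bins: int = 60) -> SizeBinning:
    """Equal-probability (ECDF-quantile) size bins with duplicate edges collapsed."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("sizes must be non-empty")
    edges = np.unique(np.quantile(sizes, np.linspace(0, 1, n_bins + 1)))
    if len(edges) == 1:  # degenerate distribution: one bin containing everything
        edges = np.array([edges[0], edges[0] + 1.0])
    return SizeBinning(tuple(edges))


def size_match(
    pathogenic: Sequence[CNV],
    nonpathogenic: Sequence[CNV],
    n_bins: int = 60,
    seed: int = 0,
):
    """Subsample both classes to per-bin balanced counts.

    Bins are ECDF quantiles of the *non-pathogenic* size distribution; per bin,
    min(#pathogenic, #non-pathogenic) variants of each class are sampled
    without replacement.
    """
    pathogenic, nonpathogenic = list(pathogenic), list(nonpathogenic)
    if not pathogenic or not nonpathogenic:
        raise ValueError("both input sets must be non-empty")
    binning = ecdf_size_bins([c.length for c in nonpathogenic], n_bins=n_bins)
    p_bins = binning.assign([c.length for c in pathogenic])
    n_bins_idx = binning.assign([c.length for c in nonpathogenic])
    rng = np.random.default_rng(seed)
    matched_p, matched_n = [], []
    for b in range(binning.n_bins):
        p_in = [c for c, i in zip(pathogenic, p_bins) if i == b]
        n_in = [c for c, i in zip(nonpathogenic, n_bins_idx) if i == b]
        k = min(len(p_in), len(n_in))
        if k == 0:
            continue
        matched_p.extend(
            p_in[j] for j in sorted(rng.choice(len(p_in), size=k, replace=False))
        )
        matched_n.extend(
            n_in[j] for j in sorted(rng.choice(len(n_in), size=k, replace=False))
        )
    return matched_p, matched_n
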
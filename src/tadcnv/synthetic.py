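"""Toy genomes, annotation tracks and labeled CNV sets with planted,
parameterised signal. Everything is reproducible under a seed and can be
written to (and read back from) the plain-text formats consumed by the
other modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from tadcnv.features import PchicInteraction
from tadcnv.tad_annotation import (
    BoundaryRecord,
    EnhancerRecord,
    GeneRecord,
    TADEnvironment,
    build_environments,
    read_boundaries_bed,
    read_bedgraph,
    read_enhancers_bed,
    read_genes_tsv,
    read_intervals_bed,
    read_tads_bed,
)
from tadcnv.variants_io import CNV, GenomicInterval


@dataclass(frozen=True)
class ToyGenomeConfig:
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_tads: int = 10
    genes_per_tad: int = 3
    enhancers_per_tad: int = 2
    ctcf_per_tad: int = 2
    gc_profile: str = "uniform"  # uniform | blocky
    gc_window_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_tads) <= 0:
            raise ValueError("chromosome/TAD counts and lengths must be positive")
        if min(self.genes_per_tad, self.enhancers_per_tad, self.ctcf_per_tad) < 0:
            raise ValueError("per-TAD element counts must be >= 0")
        if self.gc_profile not in ("uniform", "blocky"):
            raise ValueError(f"unknown gc_profile {self.gc_profile!r}")


@dataclass(frozen=True)
class CnvEffectModel:
    """Generative model planting a haploinsufficiency signal.

    Pathogenic CNVs are forced to overlap a high-p(HI) gene with probability
    ``p_hit_hi_gene``; non-pathogenic CNVs hit one with the (typically much
    lower) ``p_hit_hi_gene_benign``, otherwise they are placed avoiding such
    genes. Setting both probabilities equal yields a null configuration.
    """

    p_hit_hi_gene: float = 0.9
    p_hit_hi_gene_benign: float = 0.1
    size_dist_pathogenic: Tuple[int, int] = (5_000, 50_000)
    size_dist_nonpathogenic: Tuple[int, int] = (5_000, 50_000)
    n_pathogenic: int = 500
    n_nonpathogenic: int = 500
    svtype: str = "DEL"
    p_hi_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_hit_hi_gene, self.p_hit_hi_gene_benign):
            if not (0.0 <= p <= 1.0):
                raise ValueError("hit probabilities must be in [0,1]")
        for lo, hi in (self.size_dist_pathogenic, self.size_dist_nonpathogenic):
            if lo <= 0 or hi < lo:
                raise ValueError("size ranges must be positive and ordered")


@dataclass
class ToyGenome:
    chrom_sizes: Dict[str, int]
    tad_regions: List[GenomicInterval]
    boundaries: List[BoundaryRecord]
    genes: List[GeneRecord]
    enhancers: List[EnhancerRecord]
    ctcf: List[GenomicInterval]
    pchic: List[PchicInteraction]
    gc_track: List[Tuple[str, int, int, float]]
    telomeres: List[GenomicInterval] = field(default_factory=list)

    def environments(self) -> List[TADEnvironment]:
        return build_environments(
            self.tad_regions, self.boundaries, self.genes, self.enhancers, self.ctcf
        )

    @property
    def workspace(self) -> List[GenomicInterval]:
        return [GenomicInterval(c, 0, l) for c, l in sorted(self.chrom_sizes.items())]


def generate_genome(config: ToyGenomeConfig) -> ToyGenome:
    """Build a toy genome: TADs tiling each chromosome, genes with
    p(HI)/LOEUF/HI-log-odds/DDG2P/exons, enhancers with conservation, CTCF
    sites, pcHi-C interactions and a GC track."""
    rng = np.random.default_rng(config.seed)
    tad_len = config.chrom_length_bp // config.n_tads
    min_needed = (config.genes_per_tad + config.enhancers_per_tad + config.ctcf_per_tad) * 50
    if tad_len < max(1000, min_needed):
        raise ValueError("TADs too short to pack the requested elements")

    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chromosomes)
    }
    tads: List[GenomicInterval] = []
    boundaries: List[BoundaryRecord] = []
    genes: List[GeneRecord] = []
    enhancers: List[EnhancerRecord] = []
    ctcf: List[GenomicInterval] = []
    pchic: List[PchicInteraction] = []
    bnd_half = max(1, min(5_000, tad_len // 20))

    gene_counter = 0
    for chrom in sorted(chrom_sizes):
        for t in range(config.n_tads):
            start, end = t * tad_len, (t + 1) * tad_len
            tad = GenomicInterval(chrom, start, end)
            tads.append(tad)
            for edge in ((start,) if t == 0 else ()) + (end,):
                lo = max(0, edge - bnd_half)
                hi = min(config.chrom_length_bp, edge + bnd_half)
                boundaries.append(
                    BoundaryRecord(GenomicInterval(chrom, lo, hi), float(rng.uniform(0, 1)))
                )

            # genes in non-overlapping slots inside the TAD
            if config.genes_per_tad:
                slot = tad_len // config.genes_per_tad
                for g in range(config.genes_per_tad):
                    g_len = int(rng.integers(slot // 8, slot // 3 + 1))
                    g_start = start + g * slot + int(rng.integers(0, max(1, slot - g_len)))
                    g_iv = GenomicInterval(chrom, g_start, g_start + g_len)
                    p_hi = float(rng.beta(0.5, 0.5))
                    logit = math.log(min(max(p_hi, 1e-3), 1 - 1e-3) / (1 - min(max(p_hi, 1e-3), 1 - 1e-3)))
                    loeuf = float(min(rng.gamma(2.0, 0.4), 2.0))
                    n_ex = int(rng.integers(2, 5))
                    ex_bounds = np.sort(rng.choice(np.arange(1, g_len), size=2 * n_ex, replace=False))
                    exons = tuple(
                        GenomicInterval(chrom, g_start + int(ex_bounds[2 * k]), g_start + int(ex_bounds[2 * k + 1]))
                        for k in range(n_ex)
                        if ex_bounds[2 * k + 1] > ex_bounds[2 * k]
                    )
                    gene_id = f"G{gene_counter:05d}"
                    gene_counter += 1
                    genes.append(
                        GeneRecord(
                            g_iv,
                            gene_id,
                            p_hi=p_hi,
                            loeuf=loeuf,
                            hi_log_odds=logit + float(rng.normal(0, 0.3)),
                            is_ddg2p=bool(rng.random() < 0.1),
                            exons=exons,
                        )
                    )
                    for _ in range(int(rng.integers(1, 4))):
                        f_len = int(rng.integers(500, 3_000))
                        f_start = start + int(rng.integers(0, tad_len - f_len))
                        pchic.append(
                            PchicInteraction(
                                gene_id,
                                GenomicInterval(chrom, f_start, f_start + f_len),
                                float(1.0 + rng.exponential(3.0)),
                            )
                        )

            for _ in range(config.enhancers_per_tad):
                e_len = int(rng.integers(500, 2_000))
                e_start = start + int(rng.integers(0, tad_len - e_len))
                enhancers.append(
                    EnhancerRecord(
                        GenomicInterval(chrom, e_start, e_start + e_len),
                        float(rng.beta(2, 2)),
                    )
                )
            for _ in range(config.ctcf_per_tad):
                c_start = start + int(rng.integers(0, tad_len - 200))
                ctcf.append(GenomicInterval(chrom, c_start, c_start + 200))

    gc_track = _make_gc_track(config, chrom_sizes)
    telomeres = [
        iv
        for chrom, size in sorted(chrom_sizes.items())
        for iv in (
            GenomicInterval(chrom, 0, min(10_000, size)),
            GenomicInterval(chrom, max(0, size - 10_000), size),
        )
    ]
    return ToyGenome(
        chrom_sizes=chrom_sizes,
        tad_regions=tads,
        boundaries=boundaries,
        genes=genes,
        enhancers=enhancers,
        ctcf=ctcf,
        pchic=pchic,
        gc_track=gc_track,
        telomeres=telomeres,
    )


def _make_gc_track(config: ToyGenomeConfig, chrom_sizes: Dict[str, int]):
    track = []
    for chrom, size in sorted(chrom_sizes.items()):
        n_windows = size // config.gc_window_bp
        for w in range(n_windows):
            s = w * config.gc_window_bp
            e = min(size, s + config.gc_window_bp)
            if config.gc_profile == "uniform":
                gc = 0.45
            else:  # blocky: alternate low/high GC blocks of 5 windows
                gc = 0.35 if (w // 5) % 2 == 0 else 0.65
            track.append((chrom, s, e, gc))
    return track


def generate_cnvs(genome: ToyGenome, effect_model: CnvEffectModel) -> List[CNV]:
    """Labeled CNVs with a planted haploinsufficiency signal (see
    :class:`CnvEffectModel`)."""
    rng = np.random.default_rng(effect_model.seed)
    hi_genes = [
        g for g in genome.genes if g.p_hi is not None and g.p_hi > effect_model.p_hi_threshold
    ]
    chroms = sorted(genome.chrom_sizes)

    def draw_size(lo: int, hi: int) -> int:
        return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))

    def place_hitting(size: int) -> GenomicInterval:
        for _ in range(100):
            g = hi_genes[int(rng.integers(0, len(hi_genes)))]
            chrom_len = genome.chrom_sizes[g.interval.chrom]
            size_c = min(size, chrom_len)
            lo = max(0, g.interval.start - size_c + 1)
            hi = min(chrom_len - size_c, g.interval.end - 1)
            if hi < lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            iv = GenomicInterval(g.interval.chrom, start, start + size_c)
            if iv.overlaps(g.interval):
                return iv
        raise RuntimeError("could not place a CNV overlapping a high-p(HI) gene")

    def place_avoiding(size: int) -> GenomicInterval:
        iv = None
        for _ in range(1000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            chrom_len = genome.chrom_sizes[chrom]
            size_c = min(size, chrom_len - 1)
            start = int(rng.integers(0, chrom_len - size_c + 1))
            iv = GenomicInterval(chrom, start, start + size_c)
            if not any(iv.overlaps(g.interval) for g in hi_genes if g.interval.chrom == chrom):
                return iv
        return iv  # dense genome: accept the last draw

    cnvs: List[CNV] = []
    specs = [
        ("pathogenic", "P", effect_model.n_pathogenic, effect_model.p_hit_hi_gene,
         effect_model.size_dist_pathogenic),
        ("nonpathogenic", "N", effect_model.n_nonpathogenic, effect_model.p_hit_hi_gene_benign,
         effect_model.size_dist_nonpathogenic),
    ]
    for label, prefix, n, p_hit, (lo, hi) in specs:
        for i in range(n):
            size = draw_size(lo, hi)
            if hi_genes and rng.random() < p_hit:
                iv = place_hitting(size)
            else:
                iv = place_avoiding(size)
            cnvs.append(
                CNV(iv, effect_model.svtype, label, None, "sim", f"{prefix}{i:05d}")
            )
    return cnvs


# ---------------------------------------------------------------------------
# File round-trip (plain-text formats the readers in other modules consume)
# ---------------------------------------------------------------------------

def write_genome(genome: ToyGenome, out_dir) -> Dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("chrom_sizes", "chrom.sizes"),
        ("tads", "tads.bed"),
        ("boundaries", "boundaries.bed"),
        ("genes", "genes.tsv"),
        ("enhancers", "enhancers.bed"),
        ("ctcf", "ctcf.bed"),
        ("pchic", "pchic.tsv"),
        ("gc", "gc.bedgraph"),
        ("telomeres", "telomeres.bed"),
    ]}
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in sorted(genome.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")
    with open(paths["tads"], "w") as fh:
        for t in genome.tad_regions:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")
    with open(paths["boundaries"], "w") as fh:
        for b in genome.boundaries:
            fh.write(f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t{b.stability:.6g}\n")
    with open(paths["genes"], "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\tp_hi\tloeuf\thi_log_odds\tddg2p\texons\n")
        for g in genome.genes:
            exons = ",".join(f"{e.start}-{e.end}" for e in g.exons) or "."
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_id}\t"
                f"{'.' if g.p_hi is None else f'{g.p_hi:.6g}'}\t"
                f"{'.' if g.loeuf is None else f'{g.loeuf:.6g}'}\t"
                f"{'.' if g.hi_log_odds is None else f'{g.hi_log_odds:.6g}'}\t"
                f"{int(g.is_ddg2p)}\t{exons}\n"
            )
    with open(paths["enhancers"], "w") as fh:
        for e in genome.enhancers:
            cons = "." if e.conservation is None else f"{e.conservation:.6g}"
            fh.write(f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}\t{cons}\n")
    with open(paths["ctcf"], "w") as fh:
        for c in genome.ctcf:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\n")
    with open(paths["pchic"], "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tneg_log10_p\n")
        for it in genome.pchic:
            fh.write(
                f"{it.promoter_gene_id}\t{it.fragment.chrom}\t{it.fragment.start}\t"
                f"{it.fragment.end}\t{it.neg_log10_p:.6g}\n"
            )
    with open(paths["gc"], "w") as fh:
        for chrom, s, e, gc in genome.gc_track:
            fh.write(f"{chrom}\t{s}\t{e}\t{gc:.6g}\n")
    with open(paths["telomeres"], "w") as fh:
        for t in genome.telomeres:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")
    return paths


def read_pchic_tsv(path) -> List[PchicInteraction]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError("pchic table must start with a 'gene_id ...' header")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                PchicInteraction(f[0], GenomicInterval(f[1], int(f[2]), int(f[3])), float(f[4]))
            )
    return out


def read_genome(in_dir) -> ToyGenome:
    d = Path(in_dir)
    chrom_sizes = {}
    with open(d / "chrom.sizes") as fh:
        for line in fh:
            chrom, size = line.split("\t")
            chrom_sizes[chrom] = int(size)
    telomeres = read_intervals_bed(d / "telomeres.bed") if (d / "telomeres.bed").exists() else []
    return ToyGenome(
        chrom_sizes=chrom_sizes,
        tad_regions=read_tads_bed(d / "tads.bed"),
        boundaries=read_boundaries_bed(d / "boundaries.bed"),
        genes=read_genes_tsv(d / "genes.tsv"),
        enhancers=read_enhancers_bed(d / "enhancers.bed"),
        ctcf=read_intervals_bed(d / "ctcf.bed"),
        pchic=read_pchic_tsv(d / "pchic.tsv"),
        gc_track=read_bedgraph(d / "gc.bedgraph"),
        telomeres=telomeres,
    )
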
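"""Isochore-constrained bootstrap enrichment tests of CNV sets against
annotation tracks, with log2 fold changes, empirical p-values and BH q-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from tadcnv.variants_io import GenomicInterval


@dataclass(frozen=True)
class Isochore:
    interval: GenomicInterval
    gc_class: int


@dataclass
class EnrichmentResult:
    annotation_name: str
    observed: float
    expected: float
    log2_fc: float
    p_value: float
    q_value: Optional[float]
    n_samples: int
    direction: str  # enriched | depleted
    p_enriched: Optional[float] = None
    p_depleted: Optional[float] = None
    infinite_fc: bool = False
    n_fallback_placements: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("empirical p-value must be in (0, 1]")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals: overlapping or abutting intervals are merged."""
    out: List[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def build_isochores(
    workspace: Sequence[GenomicInterval],
    gc_track: Sequence[Tuple[str, int, int, float]],
    n_gc_classes: int = 4,
    window_bp: Optional[int] = None,
) -> List[Isochore]:
    """Merge runs of consecutive GC-track windows sharing an equal-width GC
    class into isochores. Windows must fall inside the workspace."""
    ws = merge_intervals(workspace)
    ws_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in ws:
        ws_by_chrom.setdefault(iv.chrom, []).append(iv)

    def inside_workspace(chrom: str, start: int, end: int) -> bool:
        return any(iv.start <= start and end <= iv.end for iv in ws_by_chrom.get(chrom, ()))

    windows: Dict[str, list] = {}
    for chrom, start, end, gc in gc_track:
        if not (0.0 <= gc <= 1.0):
            raise ValueError(f"GC fraction outside [0,1]: {gc}")
        if window_bp is not None and end - start != window_bp:
            raise ValueError(f"window [{start},{end}) on {chrom} is not {window_bp} bp")
        if not inside_workspace(chrom, start, end):
            raise ValueError(f"GC window [{start},{end}) on {chrom} outside workspace")
        windows.setdefault(chrom, []).append((start, end, gc))

    isochores: List[Isochore] = []
    for chrom in sorted(windows):
        wins = sorted(windows[chrom])
        run_start = run_end = run_class = None
        for start, end, gc in wins:
            cls = min(int(gc * n_gc_classes), n_gc_classes - 1)
            if run_class == cls and start == run_end:
                run_end = end
            else:
                if run_class is not None:
                    isochores.append(Isochore(GenomicInterval(chrom, run_start, run_end), run_class))
                run_start, run_end, run_class = start, end, cls
        if run_class is not None:
            isochores.append(Isochore(GenomicInterval(chrom, run_start, run_end), run_class))
    return isochores


class _SegmentSampler:
    """Vectorised same-GC-class segment placement across many bootstrap samples."""

    def __init__(self, segments: Sequence[GenomicInterval], isochores: Sequence[Isochore]):
        self.segments = list(segments)
        self.isochores = list(isochores)
        self.n_fallback = 0
        by_class: Dict[int, List[Isochore]] = {}
        for iso in self.isochores:
            by_class.setdefault(iso.gc_class, []).append(iso)

        # per segment: candidate isochores of its own class that can hold it,
        # weighted by the number of valid start positions
        self._candidates: List[Tuple[list, np.ndarray]] = []
        for seg in self.segments:
            cls = self._class_of(seg)
            cands = [
                iso for iso in by_class.get(cls, []) if iso.interval.length >= seg.length
            ]
            if not cands:
                # fallback: anywhere in the workspace-equivalent isochore union
                cands = [iso for iso in self.isochores if iso.interval.length >= seg.length]
                self.n_fallback += 1
                if not cands:
                    raise ValueError(f"no region can hold segment of length {seg.length}")
            weights = np.array(
                [iso.interval.length - seg.length + 1 for iso in cands], dtype=float
            )
            self._candidates.append((cands, weights / weights.sum()))
        if self.n_fallback:
            warnings.warn(
                f"{self.n_fallback} segment(s) exceeded every same-GC-class isochore; "
                "placed anywhere in the workspace"
            )

    def _class_of(self, seg: GenomicInterval) -> Optional[int]:
        best, best_ov = None, 0
        for iso in self.isochores:
            ov = iso.interval.overlap_len(seg)
            if ov > best_ov:
                best, best_ov = iso.gc_class, ov
        return best

    def sample(self, rng: np.random.Generator) -> List[GenomicInterval]:
        placed = []
        for seg, (cands, probs) in zip(self.segments, self._candidates):
            iso = cands[rng.choice(len(cands), p=probs)]
            start = iso.interval.start + int(
                rng.integers(0, iso.interval.length - seg.length + 1)
            )
            placed.append(GenomicInterval(iso.interval.chrom, start, start + seg.length))
        return placed


def sample_segments(
    segments: Sequence[GenomicInterval],
    isochores: Sequence[Isochore],
    seed: int = 0,
) -> List[GenomicInterval]:
    """Place each segment uniformly at random within an isochore of its own GC
    class, preserving its length. Segments too long for every same-class
    isochore fall back to workspace-wide placement (with a warning)."""
    sampler = _SegmentSampler(segments, isochores)
    return sampler.sample(np.random.default_rng(seed))


class _OverlapIndex:
    """O(log n) per-query 'does this segment intersect the annotation' test."""

    def __init__(self, annotation: Sequence[GenomicInterval]):
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        merged = merge_intervals(annotation)
        by_chrom: Dict[str, list] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            starts = np.array([iv.start for iv in ivs])
            cummax_ends = np.maximum.accumulate(np.array([iv.end for iv in ivs]))
            self._by_chrom[chrom] = (starts, cummax_ends)

    def intersects(self, seg: GenomicInterval) -> bool:
        entry = self._by_chrom.get(seg.chrom)
        if entry is None:
            return False
        starts, cummax_ends = entry
        idx = np.searchsorted(starts, seg.end, side="left")
        return idx > 0 and cummax_ends[idx - 1] > seg.start


def segment_overlap_count(
    segments: Sequence[GenomicInterval], annotation: Sequence[GenomicInterval]
) -> int:
    """Number of query segments intersecting the annotation by >= 1 bp
    (each segment counted at most once)."""
    index = _OverlapIndex(annotation)
    return sum(1 for seg in segments if index.intersects(seg))


def enrichment_test(
    segments: Sequence[GenomicInterval],
    annotation: Sequence[GenomicInterval],
    isochores: Sequence[Isochore],
    n_samples: int = 10_000,
    seed: int = 0,
    annotation_name: str = "annotation",
) -> EnrichmentResult:
    """GAT-style bootstrap test of segment-overlap enrichment/depletion.

    Query segments are merged first; ``expected`` is the mean segment-overlap
    count across randomized placements; empirical p-values use the
    add-one pseudocount (k+1)/(n+1) and the smaller one-sided p is reported
    with its direction.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    merged = merge_intervals(segments)
    index = _OverlapIndex(annotation)
    observed = sum(1 for seg in merged if index.intersects(seg))

    sampler = _SegmentSampler(merged, isochores)
    rng = np.random.default_rng(seed)
    sampled = np.empty(n_samples, dtype=float)
    for i in range(n_samples):
        placed = sampler.sample(rng)
        sampled[i] = sum(1 for seg in placed if index.intersects(seg))

    expected = float(sampled.mean())
    p_enriched = (np.sum(sampled >= observed) + 1) / (n_samples + 1)
    p_depleted = (np.sum(sampled <= observed) + 1) / (n_samples + 1)
    if p_enriched <= p_depleted:
        p_value, direction = float(p_enriched), "enriched"
    else:
        p_value, direction = float(p_depleted), "depleted"

    infinite = False
    if observed > 0 and expected == 0:
        log2_fc, infinite = math.inf, True
    elif observed == 0 and expected == 0:
        log2_fc = 0.0
    elif observed == 0:
        log2_fc = -math.inf
        infinite = True
    else:
        log2_fc = math.log2(observed / expected)

    return EnrichmentResult(
        annotation_name=annotation_name,
        observed=float(observed),
        expected=expected,
        log2_fc=log2_fc,
        p_value=p_value,
        q_value=None,
        n_samples=n_samples,
        direction=direction,
        p_enriched=float(p_enriched),
        p_depleted=float(p_depleted),
        infinite_fc=infinite,
        n_fallback_placements=sampler.n_fallback,
    )


def correct_pvalues(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg q-values (``method='bh'``); ``'storey'`` applies the
    Storey pi0 estimate on top of BH."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        pi0 = min(1.0, 2.0 * np.mean(p > 0.5))
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown method {method!r}")


def attach_qvalues(results: Sequence[EnrichmentResult], method: str = "bh") -> List[EnrichmentResult]:
    qs = correct_pvalues([r.p_value for r in results], method=method)
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return list(results)


def compare_fold_changes(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-annotation log2 fold-change difference (a - b) with a joint
    significance flag (both q-values <= threshold)."""
    a = {r.annotation_name: r for r in results_a}
    b = {r.annotation_name: r for r in results_b}
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise ValueError(f"annotation sets differ: {diff}")
    rows = []
    for name in sorted(a):
        ra, rb = a[name], b[name]
        both_sig = (
            ra.q_value is not None
            and rb.q_value is not None
            and ra.q_value <= q_threshold
            and rb.q_value <= q_threshold
        )
        rows.append(
            {
                "annotation": name,
                "log2_fc_a": ra.log2_fc,
                "log2_fc_b": rb.log2_fc,
                "log2_fc_diff": ra.log2_fc - rb.log2_fc,
                "both_significant": both_sig,
            }
        )
    return pd.DataFrame(rows)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "annotation": [r.annotation_name for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "log2_fc": [r.log2_fc for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "direction": [r.direction for r in results],
            "n_samples": [r.n_samples for r in results],
        }
    )
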
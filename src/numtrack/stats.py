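"""Compilation summaries, repeat-content statistics and compilation joins.

All interval arithmetic is on 0-based half-open coordinates; base-pair
overlap statistics are computed on merged interval unions, so no base is
double-counted, while element counts use the >= 1 bp overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import Compilation, GenomicInterval

__all__ = [
    "RESummary",
    "JoinReport",
    "summarize_lengths_identities",
    "re_overlap_stats",
    "correlation_matrix",
    "compare_compilations",
]


@dataclass(frozen=True)
class RESummary:
    """Repeat-element (RE) content of the NumtS loci of one compilation.

    Counts use >= 1 bp element overlap; base-pair fields are merged-union
    intersections.  Flanked figures extend every NumtS interval by the flank
    on both sides (clipped at chromosome ends).
    """

    re_count_in_numts: int
    re_count_with_flanks: int
    re_bp_in_numts: int
    pct_re_bp_of_numts_bp: float
    pct_re_count_of_numts_count: float
    pct_re_bp_of_genome_re_bp: float

    def __post_init__(self) -> None:
        if self.re_count_with_flanks < self.re_count_in_numts:
            raise ValueError("flanked count cannot be below unflanked count")
        for v in (
            self.pct_re_bp_of_numts_bp,
            self.pct_re_count_of_numts_count,
            self.pct_re_bp_of_genome_re_bp,
        ):
            if v < 0:
                raise ValueError("percentages must be non-negative")


def summarize_lengths_identities(comp: Compilation) -> pd.DataFrame:
    """Order statistics (min/q1/median/q3/max) of nuclear span lengths and
    percent identities — the inputs of the per-species box plots."""
    if not comp.records:
        raise ValueError("empty compilation")
    lengths = np.array([len(r.nuclear) for r in comp.records], dtype=float)
    pids = np.array([r.percent_identity for r in comp.records], dtype=float)
    rows = {}
    for name, vals in (("length_bp", lengths), ("percent_identity", pids)):
        rows[name] = {
            "min": float(np.min(vals)),
            "q1": float(np.percentile(vals, 25)),
            "median": float(np.median(vals)),
            "q3": float(np.percentile(vals, 75)),
            "max": float(np.max(vals)),
        }
    return pd.DataFrame(rows).T[["min", "q1", "median", "q3", "max"]]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(x) for x in merged]


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    return sum(hi - lo for lo, hi in _merge(intervals))


def _intersect_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Base pairs in union(a) ∩ union(b) (two-pointer sweep)."""
    a = _merge(a)
    b = _merge(b)
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def re_overlap_stats(
    comp: Compilation,
    repeats: list[GenomicInterval],
    genome_sizes: dict[str, int],
    flank: int = 1000,
) -> RESummary:
    """Repeat-element content of the compilation's nuclear loci.

    ``genome_sizes`` (chromosome -> length) is required to clip flanks at
    chromosome boundaries.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    numts: dict[str, list[tuple[int, int]]] = {}
    flanked: dict[str, list[tuple[int, int]]] = {}
    for rec in comp.records:
        iv = rec.nuclear
        numts.setdefault(iv.chrom, []).append((iv.start, iv.end))
        size = genome_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"no genome size for chromosome {iv.chrom}")
        flanked.setdefault(iv.chrom, []).append(
            (max(0, iv.start - flank), min(size, iv.end + flank))
        )
    reps: dict[str, list[tuple[int, int]]] = {}
    for iv in repeats:
        reps.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def count_overlapping(regions: dict[str, list[tuple[int, int]]]) -> int:
        n = 0
        for chrom, rep_ivs in reps.items():
            merged = _merge(regions.get(chrom, []))
            if not merged:
                continue
            starts = np.array([m[0] for m in merged])
            ends = np.array([m[1] for m in merged])
            for lo, hi in rep_ivs:
                idx = np.searchsorted(starts, hi)
                if idx > 0 and ends[idx - 1] > lo:
                    n += 1
        return n

    re_count = count_overlapping(numts)
    re_count_flanked = count_overlapping(flanked)
    re_bp = sum(
        _intersect_bp(numts.get(chrom, []), reps.get(chrom, []))
        for chrom in set(numts) | set(reps)
    )
    numts_bp = sum(_union_bp(v) for v in numts.values())
    genome_re_bp = sum(_union_bp(v) for v in reps.values())
    n_records = len(comp.records)
    return RESummary(
        re_count_in_numts=re_count,
        re_count_with_flanks=re_count_flanked,
        re_bp_in_numts=re_bp,
        pct_re_bp_of_numts_bp=100.0 * re_bp / numts_bp if numts_bp else 0.0,
        pct_re_count_of_numts_count=(
            100.0 * re_count / n_records if n_records else 0.0
        ),
        pct_re_bp_of_genome_re_bp=(
            100.0 * re_bp / genome_re_bp if genome_re_bp else 0.0
        ),
    )


def correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation across per-species genome/NumtS features.

    Requires at least three rows (species).  Zero-variance columns yield
    missing (NaN) entries rather than zeros.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 species rows")
    numeric = features.select_dtypes(include=[np.number])
    corr = numeric.corr(method="pearson", min_periods=2)
    # unit diagonal wherever the column is non-degenerate
    for col in numeric.columns:
        if numeric[col].std() > 0:
            corr.loc[col, col] = 1.0
    return corr


@dataclass
class JoinReport:
    """Interval join between a compilation and an external interval set."""

    matched: list[tuple[str, GenomicInterval, int]]  # (NumtS ID, b-interval, bp)
    a_only: list[str]
    b_only: list[GenomicInterval]
    overlap_bp: int

    @property
    def matched_fraction(self) -> float:
        total = len(self.matched) + len(self.a_only)
        return len(self.matched) / total if total else 0.0


def compare_compilations(
    a: Compilation,
    b: list[GenomicInterval],
    min_overlap: int = 1,
) -> JoinReport:
    """Join the compilation's nuclear loci against another interval set.

    Both inputs must be on the same genome build.  Pairing is one-to-one,
    deterministic: candidate pairs with >= min_overlap bp are taken in order
    of decreasing overlap, ties to the leftmost intervals.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    pairs = []
    for rec in a.records:
        tree = trees.get(rec.nuclear.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(rec.nuclear.start, rec.nuclear.end):
            ov = min(rec.nuclear.end, hit.end) - max(rec.nuclear.start, hit.begin)
            if ov >= min_overlap:
                pairs.append((ov, rec, hit.data))
    pairs.sort(key=lambda t: (-t[0], t[1].nuclear.start, b[t[2]].start))
    used_a: set[str] = set()
    used_b: set[int] = set()
    matched = []
    overlap_bp = 0
    for ov, rec, bidx in pairs:
        if rec.numts_id in used_a or bidx in used_b:
            continue
        used_a.add(rec.numts_id)
        used_b.add(bidx)
        matched.append((rec.numts_id, b[bidx], ov))
        overlap_bp += ov
    a_only = [r.numts_id for r in a.records if r.numts_id not in used_a]
    b_only = [iv for i, iv in enumerate(b) if i not in used_b]
    return JoinReport(
        matched=matched, a_only=a_only, b_only=b_only, overlap_bp=overlap_bp
    )
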
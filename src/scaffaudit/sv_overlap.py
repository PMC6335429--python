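"""Overlap of structural-difference call sets between assemblies.

Structural differences called from two sources against one reference (for
example a short-read assembly and phased haplotigs, both aligned to a
long-read assembly) are matched by reciprocal overlap to split them into a
Venn partition: differences unique to either set and differences shared by
both. Shared calls between a short-read assembly and haplotigs point to real
heterozygous alleles rather than assembly errors. Calls arrive in
Assemblytics-style BED with six size-difference categories; summaries cover
per-category base totals and size-binned counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructuralDiff", "OverlapPartition", "CATEGORIES", "read_diff_bed",
    "match_diffs", "summarize_bases", "size_partition",
]

CATEGORIES = (
    "deletion", "insertion", "repeat_contraction", "repeat_expansion",
    "tandem_contraction", "tandem_expansion",
)

_CATEGORY_ALIASES = {c.replace("_", " "): c for c in CATEGORIES} | {
    c: c for c in CATEGORIES
}


@dataclass(frozen=True)
class StructuralDiff:
    """One size difference between assemblies, on reference coordinates."""

    ref_seq_id: str
    start: int                 # 0-based half-open
    end: int
    size: int                  # bp of difference (insertions: inserted bases)
    category: str
    in_size_window: bool = True  # within the 50-10,000 bp analysis window

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class OverlapPartition:
    only_a: int
    only_b: int
    shared: int

    @property
    def shared_pct_of_a(self) -> float:
        total = self.only_a + self.shared
        return 100.0 * self.shared / total if total else 0.0


def read_diff_bed(path: str | Path,
                  size_window: tuple[int, int] = (50, 10_000)
                  ) -> list[StructuralDiff]:
    """Parse an Assemblytics-style BED: ref, start, end, name, size, strand?,
    type. Categories are normalized to the six canonical labels; records
    outside the analysis size window are kept but flagged."""
    diffs: list[StructuralDiff] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: need >= 5 columns")
            label = f[-1].strip().lower().replace("-", " ")
            if label not in _CATEGORY_ALIASES:
                raise ValueError(f"{path}:{lineno}: unknown category {f[-1]!r}")
            size = int(f[4])
            lo, hi = size_window
            diffs.append(StructuralDiff(
                ref_seq_id=f[0], start=int(f[1]), end=int(f[2]), size=size,
                category=_CATEGORY_ALIASES[label],
                in_size_window=lo <= size <= hi,
            ))
    return diffs


def _overlap_fraction(a: StructuralDiff, b: StructuralDiff) -> float:
    """Reciprocal overlap fraction (the smaller of the two one-way
    fractions); 0 for different reference sequences."""
    if a.ref_seq_id != b.ref_seq_id:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def _insertion_match(a: StructuralDiff, b: StructuralDiff,
                     max_breakpoint_dist: int = 100,
                     min_size_ratio: float = 0.5) -> float:
    """Match score for zero-width (insertion-like) calls: breakpoint distance
    and size agreement; 0 when they do not qualify."""
    if a.ref_seq_id != b.ref_seq_id:
        return 0.0
    if abs(a.start - b.start) > max_breakpoint_dist:
        return 0.0
    ratio = min(a.size, b.size) / max(a.size, b.size)
    if ratio < min_size_ratio:
        return 0.0
    return ratio


def match_diffs(
    set_a: Sequence[StructuralDiff],
    set_b: Sequence[StructuralDiff],
    min_reciprocal_overlap: float = 0.5,
    same_category: bool = True,
) -> tuple[OverlapPartition, list[tuple[int, int]]]:
    """Greedy one-to-one matching of two structural-difference sets.

    Interval calls match when reciprocal overlap reaches the threshold;
    insertion-like calls (reference span < 2 bp) match by breakpoint distance
    <= 100 bp and size ratio >= 0.5. Pairs are taken greedily by descending
    match score with deterministic coordinate tie-breaks; each record is
    matched at most once. Returns the Venn partition plus (index_a, index_b)
    links.
    """
    candidates: list[tuple[float, int, int]] = []
    for ia, a in enumerate(set_a):
        for ib, b in enumerate(set_b):
            if same_category and a.category != b.category:
                continue
            thin = (a.end - a.start) < 2 or (b.end - b.start) < 2
            score = (_insertion_match(a, b) if thin else _overlap_fraction(a, b))
            if thin:
                if score > 0:
                    candidates.append((score, ia, ib))
            elif score >= min_reciprocal_overlap:
                candidates.append((score, ia, ib))
    candidates.sort(key=lambda t: (-t[0],
                                   set_a[t[1]].ref_seq_id, set_a[t[1]].start,
                                   set_b[t[2]].start))
    used_a: set[int] = set()
    used_b: set[int] = set()
    links: list[tuple[int, int]] = []
    for _score, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        links.append((ia, ib))
    shared = len(links)
    return (
        OverlapPartition(only_a=len(set_a) - shared,
                         only_b=len(set_b) - shared, shared=shared),
        sorted(links),
    )


def summarize_bases(diffs: Sequence[StructuralDiff]) -> dict[str, int]:
    """Total bases of structural difference per category (all six keys)."""
    totals = {c: 0 for c in CATEGORIES}
    for d in diffs:
        totals[d.category] += d.size
    return totals


def size_partition(
    diffs: Sequence[StructuralDiff],
    bin_edges: Sequence[int] = (50, 500, 1000, 5000, 10_000),
) -> pd.DataFrame:
    """Count matrix category x size bin; sizes beyond the last edge fall in
    an overflow bin, sizes below the first edge in an underflow bin."""
    edges = list(bin_edges)
    if any(b >= c for b, c in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    labels = ([f"<{edges[0]}"]
              + [f"{a}-{b}" for a, b in zip(edges, edges[1:])]
              + [f">{edges[-1]}"])
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=labels)
    for d in diffs:
        k = int(np.searchsorted(edges, d.size, side="right"))
        counts.loc[d.category, labels[k]] += 1
    return counts
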
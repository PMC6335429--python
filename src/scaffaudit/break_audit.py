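"""Coverage-based audit of scaffolder-introduced contig breaks.

Proximity-ligation scaffolders break input contigs they believe are
chimeric. Whether a break was warranted shows up in long-read depth of
coverage: a break in a region of expected depth is a false break (typically a
haplotype phase switch confusing the scaffolder), unusually high depth marks
collapsed repeats or segmental duplication, and unusually low depth marks a
weakly supported chimeric join. The audit takes the median depth of a window
centred on each breakpoint (default 50 kb), compares it with the genome-wide
median, classifies the break as expected/high/low, and labels expected-depth
breaks as false breaks to be rejoined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from scaffaudit.assembly import LayoutComponent, ScaffoldLayout

__all__ = [
    "CoverageTrack", "BreakCall", "read_bedgraph", "genome_median",
    "window_stats", "classify_break", "audit_breaks", "summarize_verdicts",
    "split_layout", "rejoin_false_breaks",
]


@dataclass
class CoverageTrack:
    """Fixed-step depth track over one sequence.

    ``depths[i]`` covers bases ``[i*step, (i+1)*step)``; step=1 is per-base.
    """

    seq_id: str
    step: int
    depths: np.ndarray
    genome_median: float | None = None

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def length(self) -> int:
        return self.depths.size * self.step


@dataclass(frozen=True)
class BreakCall:
    scaffold_id: str
    position: int
    source: str                  # 'chicago' or 'hic'
    window: tuple[int, int]
    window_median: float
    window_median_ratio: float
    category: str                # 'expected' | 'high' | 'low'
    verdict: str                 # 'false_break' | 'supported'
    clipped: bool = False
    pair_distance: float | None = None  # annotation only, never used in verdict


def read_bedgraph(path: str | Path, step: int = 1) -> dict[str, CoverageTrack]:
    """Read a bedGraph into fixed-step tracks (intervals must align to step)."""
    per_seq: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph row needs 4 fields")
            per_seq.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    tracks: dict[str, CoverageTrack] = {}
    for sid, rows in per_seq.items():
        rows.sort()
        end = rows[-1][1]
        if end % step:
            raise ValueError(f"{sid}: track end {end} not a multiple of step {step}")
        depths = np.zeros(end // step)
        for s, e, v in rows:
            if s % step or e % step:
                raise ValueError(f"{sid}: interval [{s},{e}) not aligned to step {step}")
            depths[s // step: e // step] = v
        tracks[sid] = CoverageTrack(sid, step, depths)
    return tracks


def genome_median(tracks: Mapping[str, CoverageTrack]) -> float:
    """Median depth pooled over all supplied tracks; stamped onto each track."""
    pooled = np.concatenate([t.depths for t in tracks.values()])
    med = float(np.median(pooled))
    for t in tracks.values():
        t.genome_median = med
    return med


def window_stats(
    track: CoverageTrack, position: int, window_size: int = 50_000
) -> tuple[float, float, bool]:
    """Median depth of a window centred on position, and its genome-median ratio.

    Windows are clipped at sequence ends; the returned flag records clipping.
    """
    if not 0 <= position <= track.length:
        raise ValueError(f"position {position} outside {track.seq_id} "
                         f"(length {track.length})")
    if track.genome_median is None or track.genome_median <= 0:
        raise ValueError("genome median depth is unset or zero")
    half = window_size // 2
    start, end = position - half, position + half
    clipped = start < 0 or end > track.length
    start, end = max(0, start), min(track.length, end)
    lo, hi = start // track.step, -(-end // track.step)
    window = track.depths[lo:hi]
    if window.size == 0:
        raise ValueError("empty coverage window")
    med = float(np.median(window))
    return med, med / track.genome_median, clipped


def classify_break(
    ratio: float, high_threshold: float = 1.75, low_threshold: float = 0.25
) -> str:
    """expected / high / low depth category for a window-to-genome depth ratio."""
    if not 0 < low_threshold < 1 < high_threshold:
        raise ValueError("thresholds must satisfy 0 < low < 1 < high")
    if ratio >= high_threshold:
        return "high"
    if ratio <= low_threshold:
        return "low"
    return "expected"


def audit_breaks(
    breaks: Sequence[tuple],
    tracks: Mapping[str, CoverageTrack],
    window_size: int = 50_000,
    high_threshold: float = 1.75,
    low_threshold: float = 0.25,
) -> list[BreakCall]:
    """Classify each scaffolder break by windowed coverage.

    ``breaks`` rows are (scaffold_id, position, source[, pair_distance]).
    A break at expected depth is a false break; high or low depth supports it.
    """
    if tracks and next(iter(tracks.values())).genome_median is None:
        genome_median(tracks)
    calls: list[BreakCall] = []
    for row in breaks:
        sid, pos, source = row[0], int(row[1]), row[2]
        pair_distance = float(row[3]) if len(row) > 3 and row[3] is not None else None
        if sid not in tracks:
            raise KeyError(f"break on unknown sequence {sid!r}")
        track = tracks[sid]
        med, ratio, clipped = window_stats(track, pos, window_size)
        category = classify_break(ratio, high_threshold, low_threshold)
        half = window_size // 2
        calls.append(BreakCall(
            scaffold_id=sid,
            position=pos,
            source=source,
            window=(max(0, pos - half), min(track.length, pos + half)),
            window_median=med,
            window_median_ratio=ratio,
            category=category,
            verdict="false_break" if category == "expected" else "supported",
            clipped=clipped,
            pair_distance=pair_distance,
        ))
    return calls


def summarize_verdicts(calls: Iterable[BreakCall]) -> dict[str, dict[str, int]]:
    """Counts of false/supported breaks by source (chicago, hic, ...)."""
    out: dict[str, dict[str, int]] = {}
    for call in calls:
        bucket = out.setdefault(call.source, {"false_break": 0, "supported": 0})
        bucket[call.verdict] += 1
    return out


def split_layout(
    layout: ScaffoldLayout, cuts: Sequence[int]
) -> list[ScaffoldLayout]:
    """Break a scaffold layout at the given positions (pre-break coordinates).

    Every cut must fall strictly inside a component; pieces of a split
    component are renamed ``<id>.L`` / ``<id>.R``. The resulting scaffolds
    tile the original and are returned in coordinate order.
    """
    for pos in cuts:
        if not any(c.start < pos < c.end for c in layout.components):
            raise ValueError(f"break at {pos} does not split a component of "
                             f"{layout.scaffold_id!r}")
    bounds = [0, *sorted(set(cuts)), layout.length]
    out: list[ScaffoldLayout] = []
    for k, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
        comps: list[LayoutComponent] = []
        for c in sorted(layout.components, key=lambda c: c.start):
            if c.end <= lo or c.start >= hi:
                continue
            piece = c
            if c.start < lo:
                piece = replace(piece, component_id=f"{piece.component_id}.R",
                                start=lo)
            if c.end > hi:
                piece = replace(piece, component_id=f"{piece.component_id}.L",
                                end=hi)
            comps.append(replace(piece, start=piece.start - lo,
                                 end=piece.end - lo))
        gaps = [(s - lo, e - lo) for s, e in sorted(layout.gaps)
                if lo <= s and e <= hi]
        sid = layout.scaffold_id if len(bounds) == 2 else f"{layout.scaffold_id}.{k}"
        seg = ScaffoldLayout(sid, comps, gaps)
        seg.validate()
        out.append(seg)
    return out


def rejoin_false_breaks(
    layout_before: ScaffoldLayout,
    layouts_after: Sequence[ScaffoldLayout],
    verdicts: Mapping[tuple[str, int], str],
) -> list[ScaffoldLayout]:
    """Undo false breaks, keep supported ones.

    ``layouts_after`` must derive from ``layout_before`` by breaking it at
    all verdict positions (keyed by (scaffold_id, position) in pre-break
    coordinates). The corrected set is the pre-break layout re-split at the
    supported positions only, so components flanking a false break are
    re-merged in their original order and orientation.
    """
    for sid, pos in verdicts:
        if sid != layout_before.scaffold_id:
            raise KeyError(f"verdict for unknown scaffold {sid!r}")
        if not 0 < pos < layout_before.length:
            raise ValueError(f"break position {pos} outside scaffold")
    all_cuts = sorted(pos for _sid, pos in verdicts)
    if len(layouts_after) != len(all_cuts) + 1:
        raise ValueError(
            f"{len(layouts_after)} post-break scaffolds inconsistent with "
            f"{len(all_cuts)} breaks"
        )
    if sum(l.length for l in layouts_after) != layout_before.length:
        raise ValueError("post-break scaffolds do not tile the pre-break layout")
    kept = [pos for (sid, pos), v in verdicts.items() if v == "supported"]
    return split_layout(layout_before, kept)
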
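"""Repeat, centromere and telomere profiling from RepeatMasker annotations.

Chromosome-level assemblies should carry centromeric satellite arrays at
the expected places (at chromosome ends for acrocentric chromosomes, at the
ancestral fusion junction for sub-metacentric ones) and, ideally, telomeric
(TTAGGG)n runs within the terminal windows. This module parses RepeatMasker
``.out`` tables, filters annotations by identity (divergence) and length,
summarizes length distributions of long repeats by family, tests
centromere-proximity rules, scans chromosome ends for tandem telomeric
motifs on both strands, and measures the merged repeat content of unplaced
scaffolds.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from scaffaudit.assembly import SequenceRecord, reverse_complement

__all__ = [
    "RepeatFeature", "parse_repeatmasker_out", "family_length_distribution",
    "centromere_proximity", "find_telomeric", "unplaced_repeat_content",
    "merge_intervals",
]


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker annotation, coordinates converted to 0-based
    half-open."""

    seq_id: str
    start: int
    end: int
    family: str          # e.g. 'L1_BT'
    repeat_class: str    # e.g. 'LINE/L1', 'Satellite/centr'
    pct_divergence: float

    def __post_init__(self):
        if not 0 <= self.pct_divergence <= 100:
            raise ValueError("divergence outside [0, 100]")
        if self.end <= self.start:
            raise ValueError("feature interval must be non-empty")

    @property
    def identity(self) -> float:
        return 100.0 - self.pct_divergence

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    """Parse a RepeatMasker ``.out`` file (3 header lines, whitespace-split
    columns: score div del ins query qbegin qend qleft strand repeat
    class/family ...)."""
    features: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("SW", "score", "There were no")):
                continue
            f = stripped.split()
            if len(f) < 11:
                raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
            try:
                div = float(f[1])
                qbegin, qend = int(f[5]), int(f[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            features.append(RepeatFeature(
                seq_id=f[4], start=qbegin - 1, end=qend,
                family=f[9], repeat_class=f[10], pct_divergence=div,
            ))
    return features


def family_length_distribution(
    features: Sequence[RepeatFeature],
    classes: Sequence[str],
    min_len: int = 2000,
    min_identity: float = 60.0,
) -> dict[str, list[int]]:
    """Lengths of long, well-conserved repeats grouped by repeat class.

    Keeps features with identity strictly above ``min_identity`` and length
    strictly above ``min_len``; a requested class with no survivors yields an
    empty group with a warning.
    """
    out: dict[str, list[int]] = {c: [] for c in classes}
    for feat in features:
        if feat.repeat_class not in out:
            continue
        if feat.identity > min_identity and feat.length > min_len:
            out[feat.repeat_class].append(feat.length)
    for c, lengths in out.items():
        if not lengths:
            warnings.warn(f"no qualifying repeats for class {c!r}", stacklevel=2)
    return out


def centromere_proximity(
    features: Sequence[RepeatFeature],
    chrom_lengths: Mapping[str, int],
    window: int = 100_000,
    min_span: int = 5_000,
    centromere_class: str = "Satellite/centr",
    min_identity: float = 60.0,
    merged: bool = False,
) -> dict[str, dict[str, bool]]:
    """Per-chromosome centromeric-repeat flags.

    ``has_centromeric_gt_min_span``: some centromeric feature spans more than
    ``min_span`` (with ``merged=True``, merged arrays are measured instead of
    single features). ``centromere_near_end``: some centromeric feature
    intersects the first or last ``window`` bp of the chromosome.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for feat in features:
        if feat.repeat_class != centromere_class or feat.identity <= min_identity:
            continue
        if feat.seq_id not in per_chrom:
            raise KeyError(f"no length entry for chromosome {feat.seq_id!r}")
        per_chrom[feat.seq_id].append((feat.start, feat.end))
    out: dict[str, dict[str, bool]] = {}
    for chrom, spans in per_chrom.items():
        length = chrom_lengths[chrom]
        measured = merge_intervals(spans) if merged else spans
        out[chrom] = {
            "has_centromeric_gt_min_span": any(e - s > min_span
                                               for s, e in measured),
            "centromere_near_end": any(s < window or e > length - window
                                       for s, e in spans),
        }
    return out


def find_telomeric(
    record: SequenceRecord,
    motif: str = "TTAGGG",
    end_window: int = 100_000,
    min_copies: int = 10,
) -> dict[str, bool]:
    """Search both chromosome ends for a tandem telomeric-motif run.

    Both strands are scanned (the motif and its reverse complement) within
    the terminal ``end_window`` bp; an end is resolved iff it carries a
    tandem run of at least ``min_copies`` motif copies.
    """
    motifs = {motif.upper(), reverse_complement(motif.upper())}
    pattern = re.compile(
        "|".join(f"(?:{re.escape(m)}){{{min_copies},}}" for m in motifs)
    )
    seq = record.residues
    head = seq[:min(end_window, len(seq))]
    tail = seq[max(0, len(seq) - end_window):]
    return {
        "five_prime": bool(pattern.search(head)),
        "three_prime": bool(pattern.search(tail)),
    }


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; idempotent."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def unplaced_repeat_content(
    features: Sequence[RepeatFeature],
    scaffold_lengths: Mapping[str, int],
    repeat_class: str,
    min_identity: float = 60.0,
) -> float:
    """Fraction of unplaced-scaffold bases covered by one repeat class.

    Overlapping annotations are merged per scaffold so bases count once.
    ``scaffold_lengths`` defines the unplaced universe; features on other
    sequences are ignored.
    """
    total = sum(scaffold_lengths.values())
    if total <= 0:
        raise ValueError("total unplaced length must be positive")
    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    for feat in features:
        if (feat.repeat_class == repeat_class and feat.identity > min_identity
                and feat.seq_id in scaffold_lengths):
            per_scaffold.setdefault(feat.seq_id, []).append((feat.start, feat.end))
    covered = sum(
        e - s
        for spans in per_scaffold.values()
        for s, e in merge_intervals(spans)
    )
    return covered / total
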
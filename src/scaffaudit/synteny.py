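"""Synteny-conservation classification of contig joins.

Every gap in a scaffold is the join of two contigs. If the join is real, the
3 kb sequences flanking the gap should land close together in a related
genome: same chromosome, same strand, within 1 Mb. Flank alignment hits are
consumed as BLAST tabular (outfmt 6) from any aligner; the computation here
is the filtering (e-value < 1e-10, identity > 85%, alignment length >= 1 kb),
best-hit choice, and the four-way conservation test. Against several related
genomes, a join counts as synteny-interrupted only if no genome supports it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from scaffaudit.assembly import GapInterval, SequenceRecord

__all__ = [
    "AlignmentHit", "SyntenyVerdict", "read_blast_tabular", "extract_flanks",
    "filter_hits", "classify_join", "validate_assembly_joins",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One BLAST-tabular hit; minus-strand hits are normalized on read so
    target_start < target_end and strand records the orientation."""

    query_id: str
    target_chrom: str
    target_start: int          # 1-based inclusive, normalized ascending
    target_end: int
    strand: str                # '+' or '-'
    pct_identity: float
    align_len: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("percent identity outside [0, 100]")
        if self.align_len < 1:
            raise ValueError("alignment length must be >= 1")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


@dataclass(frozen=True)
class SyntenyVerdict:
    gap_id: str
    target_genome: str
    status: str                       # conserved | not_conserved | unalignable
    left_hit: AlignmentHit | None = None
    right_hit: AlignmentHit | None = None
    separation: int | None = None     # bp between chosen hits on the target


def read_blast_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse BLAST outfmt 6 (qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore); sstart > send encodes minus."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: outfmt-6 row needs 12 fields")
            sstart, send = int(f[8]), int(f[9])
            strand = "+" if sstart <= send else "-"
            hits.append(AlignmentHit(
                query_id=f[0], target_chrom=f[1],
                target_start=min(sstart, send), target_end=max(sstart, send),
                strand=strand, pct_identity=float(f[2]), align_len=int(f[3]),
                evalue=float(f[10]), bitscore=float(f[11]),
            ))
    return hits


def extract_flanks(
    record: SequenceRecord, gap: GapInterval, flank: int = 3000
) -> tuple[str, str, bool]:
    """The sequences immediately left and right of a gap.

    Left flank is [gap.start - flank, gap.start), right is
    [gap.end, gap.end + flank), both clipped at scaffold ends; the returned
    flag records clipping. An all-N flank comes back empty-equivalent for the
    caller to mark unalignable.
    """
    if not (0 <= gap.start <= gap.end <= record.length):
        raise ValueError(f"gap {gap.start}..{gap.end} outside {record.id}")
    left_start = max(0, gap.start - flank)
    right_end = min(record.length, gap.end + flank)
    clipped = left_start > gap.start - flank or right_end < gap.end + flank
    left = record.residues[left_start:gap.start]
    right = record.residues[gap.end:right_end]
    return left, right, clipped


def filter_hits(
    hits: Sequence[AlignmentHit],
    max_evalue: float = 1e-10,
    min_identity: float = 85.0,
    min_len: int = 1000,
) -> list[AlignmentHit]:
    """Keep hits with e-value < max_evalue, identity > min_identity and
    length >= min_len, ordered by descending bitscore."""
    kept = [
        h for h in hits
        if h.evalue < max_evalue and h.pct_identity > min_identity
        and h.align_len >= min_len
    ]
    return sorted(kept, key=lambda h: (-h.bitscore, h.evalue, -h.align_len))


def _best_hit(hits: Sequence[AlignmentHit],
              ambiguity_margin: float = 0.05) -> tuple[AlignmentHit | None, bool]:
    """Top hit by bitscore (ties: e-value, length); ambiguous when the
    runner-up sits on a different chromosome within the bitscore margin."""
    if not hits:
        return None, False
    ranked = sorted(hits, key=lambda h: (-h.bitscore, h.evalue, -h.align_len))
    top = ranked[0]
    ambiguous = any(
        h.target_chrom != top.target_chrom
        and h.bitscore >= top.bitscore * (1 - ambiguity_margin)
        for h in ranked[1:]
    )
    return top, ambiguous


def _separation(a: AlignmentHit, b: AlignmentHit) -> int:
    """Distance between nearest ends of two hits on the target; 0 if they
    overlap."""
    if a.target_start > b.target_start:
        a, b = b, a
    return max(0, b.target_start - a.target_end)


def classify_join(
    left_hits: Sequence[AlignmentHit],
    right_hits: Sequence[AlignmentHit],
    max_separation: int = 1_000_000,
    gap_id: str = "",
    target_genome: str = "",
) -> SyntenyVerdict:
    """Conservation verdict for one join from its filtered flank hits.

    Conserved iff the best hit of each flank lies on the same target
    chromosome, same strand, within ``max_separation``. A flank with no
    surviving hit makes the join unalignable; a flank whose top hits are
    ambiguous across chromosomes is treated conservatively as not conserved.
    """
    left, left_amb = _best_hit(left_hits)
    right, right_amb = _best_hit(right_hits)
    if left is None or right is None:
        return SyntenyVerdict(gap_id, target_genome, "unalignable", left, right)
    sep = _separation(left, right)
    conserved = (
        not left_amb and not right_amb
        and left.target_chrom == right.target_chrom
        and left.strand == right.strand
        and sep <= max_separation
    )
    return SyntenyVerdict(gap_id, target_genome,
                          "conserved" if conserved else "not_conserved",
                          left, right, sep)


def validate_assembly_joins(
    gaps: Mapping[str, Sequence[GapInterval]],
    hit_tables: Mapping[str, Sequence[AlignmentHit]],
    max_separation: int = 1_000_000,
    max_evalue: float = 1e-10,
    min_identity: float = 85.0,
    min_len: int = 1000,
) -> pd.DataFrame:
    """Verdicts for every (gap, target genome) pair plus the overall call.

    ``gaps`` maps scaffold id to its gap intervals; ``hit_tables`` maps a
    target genome name to flank hits whose query ids follow
    ``<scaffold>:gap<k>:L`` / ``:R``. A join is synteny-interrupted overall
    only when no target genome conserves it (any single genome's support
    suffices).
    """
    if not hit_tables:
        raise ValueError("at least one hit table is required")
    indexed: dict[str, dict[str, list[AlignmentHit]]] = {}
    for genome, hits in hit_tables.items():
        by_query: dict[str, list[AlignmentHit]] = {}
        for h in filter_hits(hits, max_evalue, min_identity, min_len):
            by_query.setdefault(h.query_id, []).append(h)
        indexed[genome] = by_query
    rows = []
    for scaffold_id, gap_list in gaps.items():
        for k, _gap in enumerate(gap_list, start=1):
            gap_id = f"{scaffold_id}:gap{k}"
            statuses = {}
            for genome in hit_tables:
                v = classify_join(
                    indexed[genome].get(f"{gap_id}:L", []),
                    indexed[genome].get(f"{gap_id}:R", []),
                    max_separation, gap_id, genome,
                )
                statuses[genome] = v
            overall = ("conserved"
                       if any(v.status == "conserved" for v in statuses.values())
                       else "not_conserved"
                       if any(v.status == "not_conserved" for v in statuses.values())
                       else "unalignable")
            row = {"gap_id": gap_id, "scaffold": scaffold_id, "overall": overall}
            for genome, v in statuses.items():
                row[f"status_{genome}"] = v.status
                row[f"separation_{genome}"] = v.separation
            rows.append(row)
    return pd.DataFrame(rows)
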
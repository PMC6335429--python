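"""Sequence and scaffold-layout backbone.

Sequences are plain uppercase IUPAC DNA strings; assembly gaps are maximal
runs of ``N`` of a minimum length (default 3), and un-gapped contigs are the
complement of those runs. Scaffold layouts are ordered, oriented component
intervals plus gap intervals that tile the scaffold exactly; they round-trip
through AGP v2.1.

All coordinates are 0-based half-open internally; 1-based inclusive
coordinates appear only on the AGP boundary. Ambiguity codes other than N
(R, Y, ...) are treated as ordinary bases for gap calling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord", "GapInterval", "UngappedContig", "LayoutComponent",
    "ScaffoldLayout", "read_fasta", "write_fasta", "find_gaps",
    "split_ungapped", "filter_chromosomes", "apply_layout",
    "decompose_record", "read_agp", "write_agp", "write_bed",
    "reverse_complement",
]

_RC = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                    "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One assembly sequence: a scaffold, contig or chromosome."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"sequence record {self.id!r} is empty")


@dataclass(frozen=True)
class GapInterval:
    """A maximal N run of qualifying length, 0-based half-open."""

    seq_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class UngappedContig:
    """A maximal gap-free stretch of a sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LayoutComponent:
    """One oriented component placement within a scaffold."""

    component_id: str
    orientation: str  # '+' or '-'
    start: int        # scaffold coordinates, 0-based half-open
    end: int

    def __post_init__(self):
        if self.orientation not in "+-":
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")
        if self.end <= self.start:
            raise ValueError("component interval must be non-empty")


@dataclass
class ScaffoldLayout:
    """Ordered, oriented components plus gaps tiling [0, scaffold_length)."""

    scaffold_id: str
    components: list[LayoutComponent] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        ends = [c.end for c in self.components] + [g[1] for g in self.gaps]
        return max(ends) if ends else 0

    def validate(self) -> None:
        """Check that components and gaps tile [0, length) without overlap."""
        rows = sorted(
            [(c.start, c.end, "W") for c in self.components]
            + [(s, e, "N") for s, e in self.gaps]
        )
        if not rows:
            raise ValueError(f"layout {self.scaffold_id!r} is empty")
        if rows[0][0] != 0:
            raise ValueError(f"layout {self.scaffold_id!r} does not start at 0")
        for (s0, e0, _), (s1, e1, _) in zip(rows, rows[1:]):
            if s1 != e0:
                raise ValueError(
                    f"layout {self.scaffold_id!r} has a hole or overlap at {e0}..{s1}"
                )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, residues uppercased.

    Empty files yield an empty list; a header with no sequence raises.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i:i + width] + "\n")


def find_gaps(record: SequenceRecord, min_run: int = 3) -> list[GapInterval]:
    """All maximal N runs of length >= min_run, sorted by start."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    return [
        GapInterval(record.id, m.start(), m.end())
        for m in re.finditer("N+", record.residues)
        if m.end() - m.start() >= min_run
    ]


def split_ungapped(record: SequenceRecord, min_run: int = 3) -> list[UngappedContig]:
    """Un-gapped contigs: the complement of qualifying N runs in the record."""
    contigs: list[UngappedContig] = []
    prev = 0
    for gap in find_gaps(record, min_run):
        if gap.start > prev:
            contigs.append(UngappedContig(record.id, prev, gap.start))
        prev = gap.end
    if prev < record.length:
        contigs.append(UngappedContig(record.id, prev, record.length))
    return contigs


# Default chromosome-name convention: chr1/chr22/chrX, or bare 1..n / X.
_AUTOSOME_X = re.compile(r"^(chr)?(\d+|X)$", re.IGNORECASE)


def filter_chromosomes(
    records: Sequence[SequenceRecord],
    keep: Iterable[str] | None = None,
) -> list[SequenceRecord]:
    """Retain autosome and X records; drop unplaced, Y and mitochondrial ones.

    With ``keep`` given, it is an explicit list of ids to retain; otherwise a
    name convention (``chrN``/``N``/``chrX``/``X``) selects autosomes + X.
    Relative order is preserved. An empty result warns rather than raises.
    """
    if keep is not None:
        keep_set = set(keep)
        kept = [r for r in records if r.id in keep_set]
    else:
        kept = [r for r in records if _AUTOSOME_X.match(r.id)]
    if not kept:
        warnings.warn("chromosome filter retained no sequences", stacklevel=2)
    return kept


def apply_layout(
    layout: ScaffoldLayout,
    component_sequences: dict[str, str],
    gap_fill_char: str = "N",
) -> SequenceRecord:
    """Reconstruct a scaffold sequence from its layout and component sequences.

    Minus-oriented components are reverse complemented into place. The
    resulting record decomposes back to the same layout (round trip).
    """
    layout.validate()
    parts: list[tuple[int, str]] = []
    for comp in layout.components:
        try:
            seq = component_sequences[comp.component_id]
        except KeyError:
            raise KeyError(f"missing component sequence {comp.component_id!r}")
        if len(seq) != comp.end - comp.start:
            raise ValueError(
                f"component {comp.component_id!r} length {len(seq)} does not "
                f"match layout span {comp.end - comp.start}"
            )
        if comp.orientation == "-":
            seq = reverse_complement(seq)
        parts.append((comp.start, seq.upper()))
    for s, e in layout.gaps:
        parts.append((s, gap_fill_char * (e - s)))
    parts.sort()
    return SequenceRecord(layout.scaffold_id, "".join(p[1] for p in parts))


def decompose_record(
    record: SequenceRecord, min_run: int = 3
) -> tuple[ScaffoldLayout, dict[str, str]]:
    """Split a scaffold at its gaps into a layout plus component sequences.

    Components are named ``<scaffold_id>.<k>`` in order; all plus-oriented.
    Inverse of :func:`apply_layout` up to component naming.
    """
    layout = ScaffoldLayout(record.id)
    seqs: dict[str, str] = {}
    for k, contig in enumerate(split_ungapped(record, min_run), start=1):
        cid = f"{record.id}.{k}"
        layout.components.append(LayoutComponent(cid, "+", contig.start, contig.end))
        seqs[cid] = record.residues[contig.start:contig.end]
    layout.gaps = [(g.start, g.end) for g in find_gaps(record, min_run)]
    return layout, seqs


def write_agp(layouts: Iterable[ScaffoldLayout], path: str | Path) -> None:
    """Write layouts as AGP v2.1 (W rows for components, N rows for gaps)."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for layout in layouts:
            rows = sorted(
                [(c.start, c.end, c) for c in layout.components]
                + [(s, e, None) for s, e in layout.gaps]
            , key=lambda r: (r[0], r[1]))
            for part, (s, e, comp) in enumerate(rows, start=1):
                if comp is None:
                    fh.write(
                        f"{layout.scaffold_id}\t{s + 1}\t{e}\t{part}\tN\t{e - s}"
                        f"\tscaffold\tyes\tproximity_ligation\n"
                    )
                else:
                    fh.write(
                        f"{layout.scaffold_id}\t{s + 1}\t{e}\t{part}\tW\t"
                        f"{comp.component_id}\t1\t{e - s}\t{comp.orientation}\n"
                    )


def read_agp(path: str | Path) -> list[ScaffoldLayout]:
    """Read AGP v2.1 into ScaffoldLayouts (W/N/U rows; others rejected)."""
    layouts: dict[str, ScaffoldLayout] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: truncated AGP row")
            sid, start1, end1, _part, kind = f[0], int(f[1]), int(f[2]), f[3], f[4]
            layout = layouts.setdefault(sid, ScaffoldLayout(sid))
            start, end = start1 - 1, end1
            if kind == "W":
                layout.components.append(
                    LayoutComponent(f[5], f[8] if len(f) > 8 else "+", start, end)
                )
            elif kind in ("N", "U"):
                layout.gaps.append((start, end))
            else:
                raise ValueError(f"{path}:{lineno}: unsupported AGP row type {kind!r}")
    for layout in layouts.values():
        layout.validate()
    return list(layouts.values())


def write_bed(
    intervals: Iterable[GapInterval | UngappedContig], path: str | Path
) -> None:
    """Write gap or contig intervals as BED3."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")
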
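"""Seeded synthetic genomes, populations and assembly defects.

Every validation stage in this package needs inputs that are expensive to
obtain for a real genome: long-read coverage, a genotyped population, flank
alignments against a related species, structural-difference calls and repeat
annotations. This module fabricates all of them at desk scale (a few
chromosomes of 0.2-0.3 Mb) with a known truth set, so the whole pipeline can
be exercised closed-loop:

* a base genome with planted LINE-like arrays, centromeric satellite arrays
  (at the fusion junction for "sub-metacentric" chromosomes, near one end
  for acrocentric ones) and optional telomeric (TTAGGG)n ends;
* a related genome derived from it by inter-chromosomal translocations and
  inversions plus base divergence, with an ideal BLAST-tabular flank-hit
  table computed from the rearrangement block map (no aligner needed);
* a diploid population whose haplotypes descend from a small set of founder
  haplotypes: founder alleles are clades of one per-chromosome tree, so
  unrecombined stretches show complete LD, LD decays across block
  boundaries via a Markov founder-switch process, and chromosomes are
  independent;
* scaffolds with true contig joins, injected cross-chromosome mis-joins,
  false breaks at flat-coverage sites, true breaks over collapsed repeats
  with doubled depth, and paired structural-difference call sets with a
  planted shared fraction.

All randomness flows from ``SimulationConfig.seed`` through per-stage
``numpy`` generators; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from scaffaudit.assembly import (
    LayoutComponent,
    ScaffoldLayout,
    SequenceRecord,
    write_agp,
    write_fasta,
)
from scaffaudit.ldmap import GenotypeMatrix
from scaffaudit.repeats import RepeatFeature
from scaffaudit.sv_overlap import CATEGORIES, StructuralDiff

__all__ = [
    "SimulationConfig", "TruthSet", "Genome", "RelatedGenome", "SimScaffold",
    "Simulation", "simulate_genome", "simulate_population", "inject_defects",
    "simulate", "write_repeatmasker_out",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the desk-scale conditions
    every test and report in this package runs under."""

    seed: int = 1
    # genome
    n_chromosomes: int = 4
    chromosome_lengths: tuple[int, ...] = (300_000, 250_000, 250_000, 200_000)
    submetacentric_chromosomes: int = 1
    line_arrays_per_chromosome: int = 2
    line_array_length: int = 4000
    centromere_array_length: int = 8000
    centromere_monomer_length: int = 169
    telomere_copies: int = 0          # (TTAGGG)n copies planted per end; 0 = none
    # scaffolds
    gaps_per_scaffold: int = 4
    gap_length: int = 100
    flank: int = 3000
    # related genome
    related_divergence: float = 0.05
    n_translocations: int = 1
    n_inversions: int = 1
    rearrangement_margin: int = 20_000
    # population
    snp_density_per_kb: float = 0.2
    ld_block_length: int = 15_000
    recombination_between_blocks: float = 0.3
    n_founders: int = 4
    n_individuals: int = 200
    missing_rate: float = 0.02
    # defects
    n_misjoins: int = 2
    n_false_breaks: int = 10
    n_true_breaks: int = 5
    collapsed_length: int = 36_000
    # coverage
    base_depth: float = 40.0
    collapsed_multiplier: float = 2.0
    coverage_noise_sd: float = 3.0
    coverage_step: int = 100
    # structural differences
    sv_counts: dict[str, int] = field(default_factory=lambda: {
        "deletion": 12, "insertion": 10, "repeat_contraction": 8,
        "repeat_expansion": 8, "tandem_contraction": 5, "tandem_expansion": 5,
    })
    sv_shared_fraction: float = 0.125

    def __post_init__(self):
        self.chromosome_lengths = tuple(self.chromosome_lengths)
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("need one length per chromosome")
        for rate in (self.recombination_between_blocks, self.missing_rate,
                     self.related_divergence, self.sv_shared_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_misjoins * 2 > self.n_chromosomes:
            raise ValueError("mis-joins need two chromosomes each")
        unknown = set(self.sv_counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown SV categories {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["chromosome_lengths"] = list(self.chromosome_lengths)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class RelatedGenome:
    """Rearranged, diverged copy of the base genome with its block map."""

    records: list[SequenceRecord]
    # per related chromosome: (rel_start, rel_end, src_chrom, src_start,
    # src_end, strand); blocks tile the related chromosome
    blocks: dict[str, list[tuple[int, int, str, int, int, str]]]
    divergence: float

    def project(self, chrom: str, start: int, end: int
                ) -> list[tuple[str, int, int, str]]:
        """Map a source-genome interval into related-genome pieces
        (related_chrom, start, end, strand), 0-based half-open."""
        pieces = []
        for rchrom, blocks in self.blocks.items():
            for rs, _re, src, s0, e0, strand in blocks:
                lo, hi = max(start, s0), min(end, e0)
                if lo >= hi or src != chrom:
                    continue
                if strand == "+":
                    pieces.append((rchrom, rs + (lo - s0), rs + (hi - s0), "+"))
                else:
                    pieces.append((rchrom, rs + (e0 - hi), rs + (e0 - lo), "-"))
        return sorted(pieces)


@dataclass
class Genome:
    chromosomes: list[SequenceRecord]
    repeat_ledger: list[RepeatFeature]
    related: RelatedGenome
    gap_positions: dict[str, list[int]]   # planned per-chromosome join points

    def chromosome(self, chrom: str) -> SequenceRecord:
        return next(r for r in self.chromosomes if r.id == chrom)


@dataclass
class SimScaffold:
    """A simulated scaffold: source pieces joined by gaps, plus truth."""

    id: str
    record: SequenceRecord
    layout: ScaffoldLayout
    # per component k: (chrom, src_start, src_end), all plus strand
    sources: list[tuple[str, int, int]]
    join_truth: list[str]                 # per gap: 'true' | 'misjoin'

    def gap_ids(self) -> list[str]:
        return [f"{self.id}:gap{k}" for k in range(1, len(self.layout.gaps) + 1)]


@dataclass
class TruthSet:
    misjoins: list[dict]
    false_breaks: list[tuple[str, int]]
    true_breaks: list[tuple[str, int]]
    collapsed_intervals: list[tuple[str, int, int]]
    sv_shared: int
    ld_block_boundaries: dict[str, list[int]]
    join_truth: dict[str, str]            # gap_id -> 'true' | 'misjoin'


@dataclass
class Simulation:
    """Everything one seeded run of the simulator produces."""

    config: SimulationConfig
    genome: Genome
    genotypes: GenotypeMatrix             # placed on source chromosomes
    clean_scaffolds: list[SimScaffold]
    defective_scaffolds: list[SimScaffold]
    coverage: dict[str, np.ndarray]       # clean scaffold id -> stepped depths
    break_report: list[tuple[str, int, str]]
    flank_hits: list[str]                 # outfmt-6 rows for all scaffolds
    sv_set_a: list[StructuralDiff]
    sv_set_b: list[StructuralDiff]
    truth: TruthSet

    def genotypes_on(self, scaffolds: Sequence[SimScaffold]) -> GenotypeMatrix:
        """Re-place SNPs from source-chromosome onto scaffold coordinates."""
        cols, sids, pos = [], [], []
        for j in range(self.genotypes.n_snps):
            chrom = self.genotypes.scaffolds[j]
            p = int(self.genotypes.positions[j])
            for scaf in scaffolds:
                hit = _scaffold_position(scaf, chrom, p)
                if hit is not None:
                    cols.append(j)
                    sids.append(scaf.id)
                    pos.append(hit)
                    break
        return GenotypeMatrix(
            self.genotypes.genotypes[:, cols],
            [self.genotypes.snp_ids[j] for j in cols],
            np.array(sids, dtype=object), np.array(pos),
        )

    def scaffold_gaps(self, scaffolds: Sequence[SimScaffold]):
        """Gap intervals keyed by scaffold id, for synteny validation."""
        from scaffaudit.assembly import GapInterval
        return {
            s.id: [GapInterval(s.id, a, b) for a, b in s.layout.gaps]
            for s in scaffolds
        }

    def write_outputs(self, outdir: str | Path) -> None:
        """Write the standard-format views of this simulation."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.chromosomes, out / "genome.fa")
        write_fasta(self.genome.related.records, out / "related.fa")
        write_fasta([s.record for s in self.clean_scaffolds],
                    out / "scaffolds.fa")
        write_fasta([s.record for s in self.defective_scaffolds],
                    out / "defective_scaffolds.fa")
        write_agp([s.layout for s in self.clean_scaffolds], out / "scaffolds.agp")
        write_agp([s.layout for s in self.defective_scaffolds],
                  out / "defective_scaffolds.agp")
        step = self.config.coverage_step
        with open(out / "coverage.bedgraph", "w") as fh:
            for sid, depths in self.coverage.items():
                for i, v in enumerate(depths):
                    fh.write(f"{sid}\t{i * step}\t{(i + 1) * step}\t{v:.2f}\n")
        with open(out / "breaks.tsv", "w") as fh:
            fh.write("scaffold\tposition\tsource\n")
            for sid, p, src in self.break_report:
                fh.write(f"{sid}\t{p}\t{src}\n")
        with open(out / "flank_hits.tsv", "w") as fh:
            fh.write("\n".join(self.flank_hits) + "\n")
        for name, diffs in (("sv_a.bed", self.sv_set_a), ("sv_b.bed", self.sv_set_b)):
            with open(out / name, "w") as fh:
                for k, d in enumerate(diffs):
                    fh.write(f"{d.ref_seq_id}\t{d.start}\t{d.end}\tdiff{k}\t"
                             f"{d.size}\t+\t{d.category.replace('_', ' ')}\n")
        write_repeatmasker_out(self.genome.repeat_ledger, out / "repeats.out")
        self.genotypes.to_tsv(out / "genotypes.tsv", out / "snp_map.tsv")
        self.config.to_yaml(out / "config.yaml")


def _scaffold_position(scaf: SimScaffold, chrom: str, pos: int) -> int | None:
    for comp, (src, s0, e0) in zip(scaf.layout.components, scaf.sources):
        if src == chrom and s0 <= pos < e0:
            return comp.start + (pos - s0)
    return None


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    hit = rng.random(seq.size) < rate
    if hit.any():
        seq = seq.copy()
        shift = rng.integers(1, 4, size=int(hit.sum()))
        codes = np.searchsorted(_BASES, seq[hit])
        seq[hit] = _BASES[(codes + shift) % 4]
    return seq


def simulate_genome(config: SimulationConfig) -> Genome:
    """Base genome with planted repeats, planned join points, and the
    rearranged/diverged related genome with its block map."""
    rng = config._rng(0)
    ledger: list[RepeatFeature] = []
    chrom_arrays: dict[str, np.ndarray] = {}
    for i, length in enumerate(config.chromosome_lengths):
        cid = f"chr{i + 1}"
        seq = _random_seq(rng, length)
        # centromeric satellite: mid-chromosome for sub-metacentric
        # chromosomes (the ancestral fusion junction), near the 5' end for
        # acrocentric ones
        monomer = _random_seq(rng, config.centromere_monomer_length)
        n_copies = -(-config.centromere_array_length // monomer.size)
        array = np.concatenate([
            _mutate(rng, monomer, rng.uniform(0.02, 0.10))
            for _ in range(n_copies)
        ])[:config.centromere_array_length]
        cen_start = (length // 2 - array.size // 2
                     if i < config.submetacentric_chromosomes else 10_000)
        seq[cen_start:cen_start + array.size] = array
        ledger.append(RepeatFeature(cid, cen_start, cen_start + array.size,
                                    "SAT_SIM", "Satellite/centr",
                                    round(rng.uniform(5, 15), 1)))
        # LINE-like arrays, two families
        for k in range(config.line_arrays_per_chromosome):
            family, rclass = (("L1_SIM", "LINE/L1") if k % 2 == 0
                              else ("BOVB_SIM", "LINE/RTE-BovB"))
            alen = config.line_array_length
            for _ in range(200):
                start = int(rng.integers(20_000, length - 20_000 - alen))
                if abs(start - cen_start) > array.size + 5000:
                    break
            unit = _mutate(rng, _random_seq(rng, alen), rng.uniform(0.05, 0.30))
            seq[start:start + alen] = unit
            ledger.append(RepeatFeature(cid, start, start + alen, family,
                                        rclass, round(rng.uniform(5, 35), 1)))
        if config.telomere_copies > 0:
            telo = np.array(list("TTAGGG" * config.telomere_copies))
            seq[:telo.size] = telo
            seq[-telo.size:] = np.array(list("CCCTAA" * config.telomere_copies))
            ledger.append(RepeatFeature(cid, 0, telo.size, "(TTAGGG)n",
                                        "Simple_repeat", 0.0))
            ledger.append(RepeatFeature(cid, length - telo.size, length,
                                        "(TTAGGG)n", "Simple_repeat", 0.0))
        chrom_arrays[cid] = seq

    # planned contig-join points, away from ends and from each other
    gap_positions: dict[str, list[int]] = {}
    for cid, seq in chrom_arrays.items():
        length = seq.size
        spacing = length // (config.gaps_per_scaffold + 1)
        gap_positions[cid] = [
            spacing * (k + 1) + int(rng.integers(-spacing // 4, spacing // 4))
            for k in range(config.gaps_per_scaffold)
        ]

    related = _build_related(config, rng, chrom_arrays, gap_positions)
    chromosomes = [SequenceRecord(cid, "".join(arr))
                   for cid, arr in chrom_arrays.items()]
    return Genome(chromosomes, ledger, related, gap_positions)


def _build_related(config, rng, chrom_arrays, gap_positions) -> RelatedGenome:
    cids = list(chrom_arrays)
    margin = config.rearrangement_margin

    def safe_breakpoint(cid: str) -> int:
        length = chrom_arrays[cid].size
        for _ in range(500):
            p = int(rng.integers(margin, length - margin))
            if all(abs(p - g) >= margin for g in gap_positions[cid]):
                return p
        raise RuntimeError("could not place a rearrangement breakpoint")

    # start from identity blocks in source coordinates
    plan: dict[str, list[tuple[str, int, int, str]]] = {
        cid: [(cid, 0, chrom_arrays[cid].size, "+")] for cid in cids
    }
    # reciprocal translocations: swap chromosome tails; the pairing is
    # offset by one so it never coincides with a mis-join pairing (which
    # joins chromosomes 2t and 2t+1) — a translocation between the same two
    # chromosomes would make their mis-join look syntenic
    for t in range(config.n_translocations):
        a, b = cids[(2 * t + 1) % len(cids)], cids[(2 * t + 2) % len(cids)]
        pa, pb = safe_breakpoint(a), safe_breakpoint(b)
        plan[a] = [(a, 0, pa, "+"), (b, pb, chrom_arrays[b].size, "+")]
        plan[b] = [(b, 0, pb, "+"), (a, pa, chrom_arrays[a].size, "+")]
    # inversions: flip a window wholly inside one plus-strand block
    for v in range(config.n_inversions):
        cid = cids[v % len(cids)]
        for _ in range(200):
            k = int(rng.integers(len(plan[cid])))
            src, s, e, st = plan[cid][k]
            if st != "+" or e - s < 4 * margin:
                continue
            p1, p2 = sorted((safe_breakpoint(src), safe_breakpoint(src)))
            if p1 <= s + margin or p2 >= e - margin or p2 - p1 < margin:
                continue
            plan[cid][k:k + 1] = [(src, s, p1, "+"), (src, p1, p2, "-"),
                                  (src, p2, e, "+")]
            break

    records: list[SequenceRecord] = []
    blocks: dict[str, list[tuple[int, int, str, int, int, str]]] = {}
    comp = str.maketrans("ACGT", "TGCA")
    for cid in cids:
        rid = f"r{cid}"
        parts: list[str] = []
        rblocks: list[tuple[int, int, str, int, int, str]] = []
        offset = 0
        for src, s, e, st in plan[cid]:
            piece = _mutate(rng, chrom_arrays[src][s:e],
                            config.related_divergence)
            text = "".join(piece)
            if st == "-":
                text = text.translate(comp)[::-1]
            rblocks.append((offset, offset + (e - s), src, s, e, st))
            parts.append(text)
            offset += e - s
        records.append(SequenceRecord(rid, "".join(parts)))
        blocks[rid] = rblocks
    return RelatedGenome(records, blocks, config.related_divergence)


def _founder_clades(rng: np.random.Generator, k: int) -> list[np.ndarray]:
    """Clades of a random binary tree over k founders, as boolean masks.

    Restricting SNP allele vectors to clades keeps every pair of SNPs on an
    unrecombined background free of all four gametes, i.e. |D'| = 1 within
    blocks — the perfect-phylogeny property of haplotypes without
    recombination.
    """
    groups = [np.array([i]) for i in range(k)]
    clades = [g for g in groups]
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        merged = np.concatenate([groups[i], groups[j]])
        groups = [g for t, g in enumerate(groups) if t not in (i, j)] + [merged]
        if merged.size < k:
            clades.append(merged)
    masks = []
    for clade in clades:
        mask = np.zeros(k, dtype=bool)
        mask[clade] = True
        masks.append(mask)
    return masks


def simulate_population(config: SimulationConfig, genome: Genome
                        ) -> tuple[GenotypeMatrix, dict[str, list[int]]]:
    """Diploid genotypes with block-wise LD, placed on source chromosomes.

    Returns the genotype matrix and the true LD-block boundary positions per
    chromosome.
    """
    rng = config._rng(1)
    n, k = config.n_individuals, config.n_founders
    r = config.recombination_between_blocks
    all_geno: list[np.ndarray] = []
    ids: list[str] = []
    scaffolds: list[str] = []
    positions: list[int] = []
    boundaries: dict[str, list[int]] = {}
    for record in genome.chromosomes:
        cid, length = record.id, record.length
        m = max(3, int(round(length / 1000 * config.snp_density_per_kb)))
        pos = np.sort(rng.choice(np.arange(1000, length - 1000, 250),
                                 size=m, replace=False)) * 1
        block_of = pos // config.ld_block_length
        boundaries[cid] = [int(b * config.ld_block_length)
                           for b in range(1, int(block_of.max()) + 1)]
        clades = _founder_clades(rng, k)
        alleles = np.stack([
            clades[rng.integers(len(clades))] for _ in range(m)
        ], axis=1)  # (k founders, m snps) boolean: carries reference allele
        # founder index per gamete per block (Markov switch between blocks)
        n_blocks = int(block_of.max()) + 1
        idx = np.empty((2 * n, n_blocks), dtype=int)
        idx[:, 0] = rng.integers(k, size=2 * n)
        for b in range(1, n_blocks):
            switch = rng.random(2 * n) < r
            idx[:, b] = np.where(switch, rng.integers(k, size=2 * n),
                                 idx[:, b - 1])
        gam = alleles[idx[:, block_of], np.arange(m)]  # (2n, m) boolean
        geno = gam[0::2].astype(float) + gam[1::2].astype(float)
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = np.nan
        all_geno.append(geno)
        ids.extend(f"{cid}_snp{t + 1}" for t in range(m))
        scaffolds.extend([cid] * m)
        positions.extend(int(p) for p in pos)
    gm = GenotypeMatrix(np.concatenate(all_geno, axis=1), ids,
                        np.array(scaffolds, dtype=object),
                        np.array(positions))
    return gm, boundaries


def _build_scaffold(sid: str, pieces: list[tuple[str, int, int]],
                    join_truth: list[str], genome: Genome,
                    gap_length: int) -> SimScaffold:
    assert len(join_truth) == len(pieces) - 1
    seqs = {r.id: r.residues for r in genome.chromosomes}
    parts: list[str] = []
    comps: list[LayoutComponent] = []
    gaps: list[tuple[int, int]] = []
    offset = 0
    for k, (chrom, s, e) in enumerate(pieces):
        if k:
            gaps.append((offset, offset + gap_length))
            parts.append("N" * gap_length)
            offset += gap_length
        comps.append(LayoutComponent(f"{sid}_ctg{k + 1}", "+", offset,
                                     offset + (e - s)))
        parts.append(seqs[chrom][s:e])
        offset += e - s
    layout = ScaffoldLayout(sid, comps, gaps)
    layout.validate()
    return SimScaffold(sid, SequenceRecord(sid, "".join(parts)), layout,
                       pieces, join_truth)


def _chromosome_pieces(genome: Genome, chrom: str, start: int, end: int
                       ) -> list[tuple[str, int, int]]:
    cuts = [start] + [p for p in genome.gap_positions[chrom]
                      if start < p < end] + [end]
    return [(chrom, a, b) for a, b in zip(cuts, cuts[1:])]


def _flank_hit_rows(sim_scaffolds: Sequence[SimScaffold], genome: Genome,
                    flank: int) -> list[str]:
    """Ideal outfmt-6 rows for every gap flank, from the block map."""
    rows: list[str] = []
    pident = 100 * (1 - genome.related.divergence)
    for scaf in sim_scaffolds:
        for k in range(1, len(scaf.layout.gaps) + 1):
            left_src = scaf.sources[k - 1]
            right_src = scaf.sources[k]
            for tag, (chrom, s, e) in (("L", left_src), ("R", right_src)):
                if tag == "L":
                    lo, hi = max(s, e - flank), e
                else:
                    lo, hi = s, min(e, s + flank)
                qpos = 1
                for rchrom, rs, re_, strand in genome.related.project(chrom, lo, hi):
                    plen = re_ - rs
                    sstart, send = ((rs + 1, re_) if strand == "+"
                                    else (re_, rs + 1))
                    rows.append("\t".join(map(str, (
                        f"{scaf.id}:gap{k}:{tag}", rchrom,
                        f"{pident:.2f}", plen,
                        int(plen * genome.related.divergence), 0,
                        qpos, qpos + plen - 1, sstart, send,
                        "1e-100", int(round(1.9 * plen)),
                    ))))
                    qpos += plen
    return rows


def inject_defects(config: SimulationConfig, genome: Genome
                   ) -> tuple[list[SimScaffold], list[SimScaffold],
                              dict[str, np.ndarray],
                              list[tuple[str, int, str]], TruthSet]:
    """Clean and defective scaffold sets, coverage, break report and truth.

    The clean assembly has one scaffold per chromosome with true joins at
    the planned gap points. The defective assembly replaces pairs of
    chromosomes with cross-chromosome mis-joined scaffolds (left half of one
    joined to the right half of another, leftovers as separate scaffolds).
    Coverage over the clean scaffolds carries doubled depth across collapsed
    intervals; the break report mixes false breaks at flat-coverage sites
    with true breaks centred on collapsed intervals.
    """
    rng = config._rng(2)
    cids = [r.id for r in genome.chromosomes]

    clean = [
        _build_scaffold(
            f"scaf_{cid}", _chromosome_pieces(genome, cid, 0, len_),
            ["true"] * len([p for p in genome.gap_positions[cid]]),
            genome, config.gap_length)
        for cid, len_ in zip(cids, config.chromosome_lengths)
    ]

    defective: list[SimScaffold] = []
    misjoins: list[dict] = []
    used: set[str] = set()
    for t in range(config.n_misjoins):
        a, b = cids[2 * t], cids[2 * t + 1]
        used.update((a, b))
        mid_a = config.chromosome_lengths[2 * t] // 2
        mid_b = config.chromosome_lengths[2 * t + 1] // 2
        left = _chromosome_pieces(genome, a, 0, mid_a)
        right = _chromosome_pieces(genome, b, mid_b,
                                   config.chromosome_lengths[2 * t + 1])
        sid = f"mis_{t + 1}"
        truth = ["true"] * (len(left) - 1) + ["misjoin"] + ["true"] * (len(right) - 1)
        defective.append(_build_scaffold(sid, left + right, truth, genome,
                                         config.gap_length))
        misjoins.append({
            "scaffold": sid,
            "gap_id": f"{sid}:gap{len(left)}",
            "left_chrom": a, "right_chrom": b,
            "junction_gap_index": len(left),
        })
        # leftovers stay as clean scaffolds of the defective assembly
        defective.append(_build_scaffold(
            f"rest_{a}", _chromosome_pieces(genome, a, mid_a,
                                            config.chromosome_lengths[2 * t]),
            ["true"] * len([p for p in genome.gap_positions[a] if p > mid_a]),
            genome, config.gap_length))
        defective.append(_build_scaffold(
            f"rest_{b}", _chromosome_pieces(genome, b, 0, mid_b),
            ["true"] * len([p for p in genome.gap_positions[b] if p < mid_b]),
            genome, config.gap_length))
    for cid, len_ in zip(cids, config.chromosome_lengths):
        if cid not in used:
            defective.append(_build_scaffold(
                f"scaf_{cid}", _chromosome_pieces(genome, cid, 0, len_),
                ["true"] * len(genome.gap_positions[cid]),
                genome, config.gap_length))

    coverage, breaks, truth = _coverage_and_breaks(config, rng, clean)
    truth_set = TruthSet(
        misjoins=misjoins,
        false_breaks=truth["false"],
        true_breaks=truth["true"],
        collapsed_intervals=truth["collapsed"],
        sv_shared=0,
        ld_block_boundaries={},
        join_truth={
            gid: status
            for scaf in clean + defective
            for gid, status in zip(scaf.gap_ids(), scaf.join_truth)
        },
    )
    return clean, defective, coverage, breaks, truth_set


def _coverage_and_breaks(config, rng, scaffolds):
    step = config.coverage_step
    half_window = 25_000
    collapsed: list[tuple[str, int, int]] = []
    false_breaks: list[tuple[str, int]] = []
    true_breaks: list[tuple[str, int]] = []

    true_sites: dict[str, list[int]] = {s.id: [] for s in scaffolds}
    false_sites: dict[str, list[int]] = {s.id: [] for s in scaffolds}
    # a break window must not straddle a collapsed interval it does not own,
    # and collapsed intervals must stay clear of every false-break window
    clear_of_collapsed = config.collapsed_length // 2 + half_window + 5_000

    def place(scaf: SimScaffold, min_true_sep: int, min_false_sep: int
              ) -> int | None:
        length = scaf.record.length
        for _ in range(2000):
            p = int(rng.integers(half_window + 1000, length - half_window - 1000))
            if any(abs(p - q) < min_true_sep for q in true_sites[scaf.id]):
                continue
            if any(abs(p - q) < min_false_sep for q in false_sites[scaf.id]):
                continue
            if not any(c.start + 1000 < p < c.end - 1000
                       for c in scaf.layout.components):
                continue
            return p
        return None

    order = list(range(len(scaffolds)))
    for t in range(config.n_true_breaks):
        scaf = scaffolds[order[t % len(order)]]
        p = place(scaf, min_true_sep=2 * clear_of_collapsed,
                  min_false_sep=clear_of_collapsed)
        if p is None:
            continue
        true_sites[scaf.id].append(p)
        half = config.collapsed_length // 2
        collapsed.append((scaf.id, p - half, p + half))
        true_breaks.append((scaf.id, p))
    for t in range(config.n_false_breaks):
        scaf = scaffolds[order[t % len(order)]]
        p = place(scaf, min_true_sep=clear_of_collapsed, min_false_sep=5_000)
        if p is None:
            continue
        false_sites[scaf.id].append(p)
        false_breaks.append((scaf.id, p))

    coverage: dict[str, np.ndarray] = {}
    for scaf in scaffolds:
        n_bins = -(-scaf.record.length // step)
        depths = config.base_depth + rng.normal(0, config.coverage_noise_sd,
                                                n_bins)
        for sid, s, e in collapsed:
            if sid == scaf.id:
                depths[s // step: e // step] *= config.collapsed_multiplier
        coverage[scaf.id] = np.clip(depths, 0, None).round(2)

    breaks = [(sid, p, "chicago") for sid, p in false_breaks + true_breaks]
    if breaks:
        breaks[-1] = (*breaks[-1][:2], "hic")
    rng.shuffle(breaks)
    return coverage, breaks, {
        "false": false_breaks, "true": true_breaks, "collapsed": collapsed,
    }


def _simulate_svs(config: SimulationConfig, genome: Genome
                  ) -> tuple[list[StructuralDiff], list[StructuralDiff], int]:
    """Two structural-difference call sets with a planted shared fraction.

    Records are packed sequentially along the chromosomes so non-shared
    records never overlap; shared records appear in both sets with a small
    coordinate jitter.
    """
    rng = config._rng(3)
    n_a = sum(config.sv_counts.values())
    n_shared = int(round(config.sv_shared_fraction * n_a))
    cats_a = [c for c in CATEGORIES for _ in range(config.sv_counts.get(c, 0))]
    rng.shuffle(cats_a)
    shared_idx = set(rng.choice(n_a, size=n_shared, replace=False).tolist())
    cats_b_only = [str(c) for c in rng.choice(
        [c for c in CATEGORIES if config.sv_counts.get(c, 0)],
        size=n_a - n_shared)]

    plan: list[tuple[str, str]] = (
        [("a", c) for c in cats_a] + [("b", c) for c in cats_b_only]
    )
    rng.shuffle(plan)
    set_a: list[StructuralDiff] = []
    set_b: list[StructuralDiff] = []
    chrom_iter = iter([(r.id, r.length) for r in genome.chromosomes])
    chrom, chrom_len = next(chrom_iter)
    cursor = 2000
    a_seen = 0
    for who, cat in plan:
        size = int(round(np.exp(rng.uniform(np.log(50), np.log(10_000)))))
        span = 1 if cat == "insertion" else size
        if cursor + span + 2000 > chrom_len:
            chrom, chrom_len = next(chrom_iter)
            cursor = 2000
        start = cursor
        cursor += span + int(rng.integers(300, 800))
        rec = StructuralDiff(chrom, start, start + span, size, cat)
        if who == "a":
            set_a.append(rec)
            if a_seen in shared_idx:
                jitter = int(rng.integers(-10, 11))
                b_start = max(0, start + jitter)
                set_b.append(StructuralDiff(chrom, b_start, b_start + span,
                                            size, cat))
            a_seen += 1
        else:
            set_b.append(rec)
    return set_a, set_b, n_shared


def simulate(config: SimulationConfig | None = None) -> Simulation:
    """Run every stage of the simulator and bundle the results."""
    config = config or SimulationConfig()
    genome = simulate_genome(config)
    genotypes, boundaries = simulate_population(config, genome)
    clean, defective, coverage, breaks, truth = inject_defects(config, genome)
    set_a, set_b, n_shared = _simulate_svs(config, genome)
    truth.sv_shared = n_shared
    truth.ld_block_boundaries = boundaries
    hits = _flank_hit_rows(clean + defective, genome, config.flank)
    return Simulation(config, genome, genotypes, clean, defective, coverage,
                      breaks, hits, set_a, set_b, truth)


def write_repeatmasker_out(features: Sequence[RepeatFeature],
                           path: str | Path) -> None:
    """Write features as a RepeatMasker ``.out`` table (synthetic
    annotations; scores are nominal)."""
    header = (
        "   SW   perc perc perc  query     position in query    matching"
        "  repeat       position in repeat\n"
        "score   div. del. ins.  sequence  begin end   (left)   repeat"
        "  class/family  begin end (left) ID\n\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for k, feat in enumerate(features, start=1):
            fh.write(
                f"{1000:>5} {feat.pct_divergence:>5.1f}  0.0  0.0  "
                f"{feat.seq_id}  {feat.start + 1} {feat.end} "
                f"(0) + {feat.family} {feat.repeat_class} 1 "
                f"{feat.end - feat.start} (0) {k}\n"
            )
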
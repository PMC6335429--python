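# scaffaudit

Validation and curation computations for chromosome-level genome
assemblies.

Long-read contig assemblies scaffolded with proximity-ligation data
(Chicago / Hi-C) inherit two characteristic classes of error: the
scaffolder breaks contigs it wrongly believes are chimeric (often at
haplotype phase switches), and it occasionally joins sequence that does not
belong together. `scaffaudit` implements the downstream audit a curation
team runs to find and fix both, plus the contiguity, structural-difference
and repeat profiling used to benchmark the result. It is a library first
(importable API plus `examples/`), with a thin `scaffaudit` command-line
front end over the same functions.

## What it computes

* **Coverage audit of scaffolder breaks.** For each reported breakpoint,
  the median long-read depth of a 50 kb window centred on the break is
  compared with the genome-wide median. Ratio ≈ 1 → the break is *false*
  (expected coverage; typically a phase switch) and is rejoined;
  ratio ≥ 1.75 → collapsed repeat / segmental duplication; ratio ≤ 0.25 →
  weakly supported chimeric join. `rejoin_false_breaks` restores the
  pre-break layout at exactly the false breaks.
* **LD-jump mis-join detection.** From unphased population genotypes, a
  linkage-disequilibrium-unit (LDU) map assigns each SNP a cumulative
  coordinate under the Malecot association model
  ρ(d) = (1 − L)·M·e^(−εd) + L, with one LDU increment per inter-SNP
  interval fitted jointly over windowed SNP pairs. Intervals whose
  increment exceeds an outlier threshold θ (Tukey upper fence over
  trusted-scaffold increments; constant override available, e.g. the
  published 0.275) are *LD jumps* — candidate mis-joins. The same score
  tests synthetic joins of scaffold pairs in all four orientations.
* **Synteny validation of contig joins.** The 3 kb flanks of every gap are
  checked against one or more related genomes (BLAST outfmt-6 input,
  filters: e-value < 1e−10, identity > 85 %, alignment ≥ 1 kb). A join is
  conserved iff both flanks hit the same chromosome, same strand, within
  1 Mb. Joins failing *both* LD and synteny become mis-assembly
  candidates.
* **Contiguity statistics.** Gap calling (N runs ≥ 3), un-gapped contig
  decomposition, N50, and a one-sided Wilcoxon rank-sum comparison of
  un-gapped contig lengths (R's W convention, continuity-corrected,
  Bonferroni-adjusted).
* **Structural-difference overlap.** Assemblytics-style call sets are
  matched by 50 % reciprocal overlap (insertions by breakpoint distance)
  into a Venn partition, with per-category base totals and size-binned
  counts.
* **Repeat profiling.** RepeatMasker `.out` parsing, >60 % identity and
  >2 kb filters for LINE/L1, LINE/RTE-BovB and centromeric satellite
  length distributions, centromere-placement rules (arrays > 5 kb; within
  100 kb of chromosome ends), and a (TTAGGG)n telomere search on both
  strands of the terminal 100 kb.
* **Synthetic data.** A fully seeded simulator builds toy diploid genomes
  with planted repeat arrays, a rearranged related genome with an ideal
  flank-hit table, populations with block-wise LD, coverage tracks,
  injected mis-joins/false breaks, and paired SV call sets — every defect
  with a truth record, so the whole pipeline closes the loop offline.

## Worked example

`examples/03_ld_misjoin_check.py` simulates an assembly with two injected
cross-chromosome mis-joins and runs the LD audit:

```
outlier threshold from standard scaffolds: theta = 0.548 LDU
mis_1: map length 685.92 LDU, 5 flagged jumps; junction interval 27 has
delta 679.29 (scaffold max 679.29)
rest_chr1 + rest_chr3 junction deltas: {'++': 64.56, '+-': 2.1,
'-+': 35.04, '--': 4.15} -> not supported
```

The injected junction carries the largest LDU increment on its scaffold
(679 LDU against a 0.55 LDU outlier fence — SNPs across the junction are
unlinked in the population), and a synthetic join of two scaffolds from
different chromosomes exceeds θ in every orientation, so no false join is
made. `examples/04_synteny_check.py` then crosses these flags with synteny
verdicts and reports exactly the injected mis-joins as candidates:

```
mis-join candidates (LD jump AND broken synteny): ['mis_1:gap3', 'mis_2:gap3']
injected mis-joins: ['mis_1:gap3', 'mis_2:gap3']
```

The other examples cover gap/contiguity statistics, the coverage break
audit, structural-difference overlap and repeat/telomere profiling.

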
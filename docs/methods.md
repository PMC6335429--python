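# Methods

This note records the models, parameter choices and numerical decisions
behind `scaffaudit`, and what the synthetic-data generator does and does
not emulate.

## Coverage-based break audit

A scaffolder break is audited by the median long-read depth of a window
centred on the breakpoint (default 50 kb), divided by the genome-wide
median depth pooled over all supplied tracks. The median, not the mean, is
used so isolated depth spikes cannot move a verdict. Windows are clipped at
sequence ends and the call carries a `clipped` flag rather than being
dropped, to preserve auditability near termini.

The category thresholds are ratios, not absolute depths, making the audit
invariant under uniform scaling of coverage: `high` at ratio ≥ 1.75 and
`low` at ratio ≤ 0.25 by default, both configurable. The rationale: a
collapsed haplotype or segmental duplication roughly doubles apparent
depth, so a cut-off placed below 2 but well above normal fluctuation
separates the two regimes, while near-zero depth indicates the join was
never supported by reads. A break at expected depth is a false break — the
dominant mechanism being a haplotype phase switch in the input contigs —
and `rejoin_false_breaks` re-merges the flanking components in their
original order and orientation; supported breaks keep the scaffold split.
Chicago read-pair distance is accepted as an annotation column and
reported, but never used in the verdict: no defensible decision rule for
it is established, and coverage alone separates the simulated regimes.

## LDU maps and LD jumps

Association between two SNPs is estimated from unphased genotypes by an EM
fit of the four two-locus haplotype frequencies (the standard
double-heterozygote decomposition), reported as |D′| by default or as the
signed correlation r. Monomorphic pairs return NaN and the affected
interval is flagged rather than failing.

The LDU map itself treats the Malecot exponential decay model

    rho(d) = (1 − L) · M · exp(−ε d) + L

as a model of association *through the map*: writing D_i for the
cumulative LDU coordinate of SNP i, a pair (j, k) is modelled as
rho_jk = (1 − L)·M·exp(−(D_k − D_j)) + L, and all interval increments
Δ_i = D_{i+1} − D_i of a scaffold are fitted jointly (bounded least
squares: L, M ∈ [0, 1], Δ_i ≥ 0) to the associations of all SNP pairs
within a 10-SNP window. The joint formulation matters: an interval is
identified by the pairs that span it *and* by its neighbours' same-side
pairs, whereas a per-interval fit using only spanning pairs cannot
distinguish a long junction from a flat low-association background. The
fast `r2decay` surrogate sets Δ_i = −ln(max(|assoc| of the flanking pair,
0.05)) and is used for initialisation; intervals with no usable pairs keep
the surrogate and carry a `skipped` flag. SNPs with more than 20 %
missingness or minor-allele frequency below 0.05 are dropped before
mapping — association estimates are unstable below that.

An interval whose increment exceeds the outlier threshold θ is an LD jump.
θ defaults to the Tukey upper fence (Q3 + 1.5·IQR) over increments from
trusted scaffolds supplied as calibration; a constant override (for
example a previously published genome-wide calibration of 0.275) is
available. Raising θ can only shrink the flagged set.

Synthetic joins evaluate all four orientation configurations of a scaffold
pair by building the combined map with a 10 kb junction gap and reading
the junction interval's increment; the join is supported iff the minimum
junction increment falls below θ, ties broken toward the smaller increment
and then lexicographic orientation. Scaffolds with fewer than two usable
SNPs are reported untestable rather than erroring. Mis-assembly
*candidates* require two independent lines of evidence — a flagged LD jump
attributed to the join (within one interval, absorbing SNP-placement
discretisation) *and* synteny not conserved against any related genome;
joins with a single line of evidence go to a watch list.

Exactness note: reversing a scaffold reverses the increment sequence
exactly in `r2decay` mode (the computation is symmetric); the joint fit
reproduces it to ~1e-6, limited by finite least-squares tolerances.

## Synteny classification

The 3 kb flanks of each gap are looked up in BLAST outfmt-6 hit tables
(any aligner; `blastn` works directly). Filters follow the strict
inequalities e-value < 1e−10 and identity > 85 %, with alignment length
≥ 1 kb. Per flank the best hit is chosen by bitscore, ties by e-value then
length; if a runner-up within 5 % bitscore sits on a different chromosome
the flank is ambiguous and the join is conservatively not conserved.
Separation is measured between the nearest ends of the two chosen hits
(0 if overlapping) and must be ≤ 1 Mb; strand is compared on the raw hit
strands (the right flank is not reverse complemented before search, so
conserved joins show equal strands). Against several related genomes a
join is interrupted overall only if no genome conserves it.

## Contiguity statistics

Gaps are maximal N runs of length ≥ 3 (other ambiguity codes are ordinary
bases); un-gapped contigs are their complement, and terminal N runs count
as gaps. N50 is the smallest length L such that sequences ≥ L hold at
least half the total. The rank-sum comparison uses the first-sample
rank-sum minus n1(n1+1)/2 convention (identical to R's `wilcox.test` W),
exact for tie-free samples up to n = 50 per side and the
continuity-corrected normal approximation otherwise; two identical
all-tied samples take the degenerate p = 1 path. Bonferroni adjustment
multiplies by the number of comparisons in the invocation, capped at 1.
Percentages are rounded half-up at the report layer only.

## Structural-difference overlap

Interval calls match at ≥ 50 % reciprocal overlap within the same
category; insertion-like calls (reference span < 2 bp) match by breakpoint
distance ≤ 100 bp and size ratio ≥ 0.5. Matching is greedy by descending
score with deterministic coordinate tie-breaks and each record used at
most once, so the Venn partition conserves |A| = only_a + shared and
|B| = only_b + shared. Records outside the 50–10,000 bp analysis window
are parsed and flagged, not dropped. Both knobs (reciprocal fraction,
category awareness) are configurable because published comparisons rarely
state their matching rule; 50 % reciprocal overlap with category agreement
is the community default for SV set comparison.

## Repeat, centromere and telomere profiling

RepeatMasker `.out` rows are converted to 0-based half-open coordinates
and identity = 100 − divergence; the >60 % identity filter is strict, as
is the >2 kb length filter for family length distributions. Centromere
rules are evaluated per chromosome: some Satellite/centr feature spanning
more than 5 kb (single-feature span by default; a merged-array mode exists
because annotations often fragment one array), and any centromeric feature
intersecting the terminal 100 kb. The telomere search scans both strands
(TTAGGG and CCCTAA) in the terminal 100 kb and calls an end resolved only
for a tandem run of ≥ 10 motif copies — the motif alone appears by chance
in any megabase of sequence, a tandem run does not. Base-fraction
computations merge overlapping annotations per class so bases count once.

## The synthetic-data generator

Defaults are the study conditions for every test and report in the
package, at desk scale so the whole suite runs in minutes on one CPU: four
chromosomes of 0.2–0.3 Mb (1 Mb genome), 200 diploid individuals, 0.2
SNPs/kb, four founder haplotypes, 15 kb LD blocks with 0.3 recombination
probability between blocks, four contig joins per scaffold, two injected
cross-chromosome mis-joins, ten false and five true breaks, base depth 40×
with Gaussian noise (sd 3) and 2× depth over collapsed intervals, 5 %
divergence plus one translocation and one inversion in the related genome,
and 48-call SV sets with a 12.5 % planted shared fraction.

Design points worth recording:

* **Founder haplotypes are clades of one per-chromosome tree.** Allele
  vectors drawn as arbitrary founder splits would create SNP pairs with
  all four gametes — zero LD *inside* an unrecombined block, which real
  haplotypes (absent recurrent mutation) do not show. Restricting allele
  vectors to clades of a single random tree per chromosome gives the
  perfect-phylogeny property: |D′| = 1 on unrecombined backgrounds, decay
  only through the Markov founder-switch process at block boundaries, and
  independence across chromosomes.
* **LD blocks are 15 kb against ~5 kb SNP spacing**, so boundary-crossing
  intervals are a routine part of every scaffold's increment distribution.
  Calibration of θ by the Tukey fence then reflects ordinary decay, and a
  junction between unlinked scaffolds stands far outside it.
* **Collapsed intervals span 36 kb of the 50 kb audit window.** The window
  *median* only reflects a collapse that covers most of the window; a
  collapse much smaller than the window is a different phenomenon (and
  would rightly be missed by a median-based audit).
* **The related genome is a block map first.** Translocations swap
  chromosome tails (pairing deliberately offset from the mis-join pairing,
  since a translocation between the same two chromosomes would make their
  mis-join genuinely syntenic), inversions flip an internal window, and
  all rearrangement breakpoints keep a 20 kb margin from planned contig
  joins. The ideal flank-hit table is computed exactly from this block
  map, so synteny tests need no aligner; the same FASTA can be fed to a
  real aligner for end-to-end runs.
* **Determinism.** All randomness flows from one seed through per-stage
  `numpy` generators; identical configs give byte-identical output files.

What the generator does not emulate — and hence what passing tests do not
show about real data: read-level error models (no FASTQ), mapping
ambiguity in coverage tracks, gene conversion and recurrent mutation,
realistic repeat family structure or nested/divergent arrays, population
structure and relatedness beyond the founder-block model, reference bias
in SNP placement, and aligner-specific artifacts in flank hits. Recovery
rates measured here characterise the pipeline's logic under clean signals,
not its field performance.

## Numerical choices

EM for haplotype frequencies iterates to 1e−10 (max 200 rounds) on
pairwise-complete observations. The joint LDU fit runs bounded trust-region
least squares with xtol = ftol = 1e−10, initialised from the surrogate
increments; increments of intervals spanned by no retained pair are left
at the surrogate and flagged. The association floor for the surrogate is
0.05 (capping one increment at −ln 0.05 ≈ 3). Coverage windows at ends
are truncated, never padded. All internal coordinates are 0-based
half-open; AGP and BLAST coordinates are converted at the boundary.
Greedy SV matching breaks score ties by reference id and coordinate, so
results are order-independent.

## Limitations

The LDU estimator is a deliberately compact re-implementation of the
additive-map idea, not a port of any specific mapping package; absolute
LDU values are therefore comparable only within a run (the jump logic uses
calibrated thresholds, never absolute map lengths). Synthetic-join testing
scales quadratically in the number of scaffold pairs and is meant for a
handful of major scaffolds. The external-genome gap benchmarks
(chromosome-level human/goat comparisons) require downloading those
assemblies and are not bundled; the gap-calling and rank-sum machinery
they need is fully covered by the offline suite.
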
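"""Contiguity statistics and report arithmetic.

N50 and gap summaries per assembly, a one-sided Wilcoxon rank-sum comparison
of un-gapped contig length distributions between assemblies (the statistic is
reported in the first-sample rank-sum minus n1(n1+1)/2 convention, as R's
``wilcox.test`` W), and the small arithmetic helpers behind headline assembly
numbers: sequencing coverage folds, percentages, phred QV error-rate folds
and fold improvements.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from scaffaudit.assembly import SequenceRecord, find_gaps, split_ungapped

__all__ = [
    "ContiguitySummary", "RankTestResult", "n50", "compare_ungapped_lengths",
    "coverage_fold", "fraction_pct", "qv_error_fold", "fold_improvement",
    "summarize_assembly",
]


@dataclass(frozen=True)
class ContiguitySummary:
    n_sequences: int
    n_gaps: int
    N50: int
    total_length: int
    per_chromosome_gap_counts: Mapping[str, int]


@dataclass(frozen=True)
class RankTestResult:
    """One-sided rank-sum comparison with Bonferroni-adjusted p value."""

    W: float
    p_raw: float
    p_adjusted: float
    n1: int
    n2: int
    alternative: str


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that sequences of length >= L hold half the bases."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths))[::-1]
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2))
    return int(arr[idx])


def compare_ungapped_lengths(
    lengths_a: Sequence[int],
    lengths_b: Sequence[int],
    alternative: str = "greater",
    n_tests: int = 1,
) -> RankTestResult:
    """Wilcoxon rank-sum test of contig length distributions A vs B.

    Exact null distribution for small tie-free samples, otherwise the normal
    approximation with continuity correction; ``alternative='greater'`` asks
    whether A's contigs tend to be longer. The raw p value is Bonferroni
    multiplied by ``n_tests`` and capped at 1.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if max(a.size, b.size) <= 50 and not ties:
        method = "exact"
    else:
        method = "asymptotic"  # scipy applies the continuity correction here
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    p_raw = float(res.pvalue)
    return RankTestResult(
        W=float(res.statistic),
        p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * n_tests),
        n1=a.size,
        n2=b.size,
        alternative=alternative,
    )


def coverage_fold(total_bases: float, genome_size: float) -> float:
    """Sequencing depth: total bases over genome size (same units)."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return total_bases / genome_size


def fraction_pct(part: float, whole: float, ndigits: int = 1) -> float:
    """``100*part/whole`` rounded half-up to ndigits (report-layer rounding)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if part < 0:
        raise ValueError("part must be non-negative")
    pct = decimal.Decimal(100 * part / whole)
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(q, rounding=decimal.ROUND_HALF_UP))


def qv_error_fold(qv_low: float, qv_high: float) -> float:
    """Fold fewer substitution errors implied by a phred QV gain.

    QV is -10*log10(error rate), so the fold is 10^((qv_high - qv_low)/10).
    """
    return 10 ** ((qv_high - qv_low) / 10)


def fold_improvement(new_value: float, old_value: float) -> float:
    if old_value <= 0:
        raise ValueError("old value must be positive")
    return new_value / old_value


def summarize_assembly(
    records: Sequence[SequenceRecord], min_run: int = 3
) -> ContiguitySummary:
    """Gap counts, N50 and total length over a set of assembly sequences."""
    gap_counts = {r.id: len(find_gaps(r, min_run)) for r in records}
    return ContiguitySummary(
        n_sequences=len(records),
        n_gaps=sum(gap_counts.values()),
        N50=n50([r.length for r in records]),
        total_length=sum(r.length for r in records),
        per_chromosome_gap_counts=gap_counts,
    )


def ungapped_lengths(records: Sequence[SequenceRecord], min_run: int = 3) -> list[int]:
    """Lengths of un-gapped contigs pooled over all records."""
    return [c.length for r in records for c in split_ungapped(r, min_run)]
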
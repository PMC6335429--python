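"""Contiguity statistics: N50, rank-sum comparison, report arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scaffaudit.contiguity import (
    compare_ungapped_lengths,
    coverage_fold,
    fold_improvement,
    fraction_pct,
    n50,
    qv_error_fold,
    summarize_assembly,
)


def n50_oracle(lengths):
    """Brute force: walk lengths in decreasing order to half the total."""
    total = sum(lengths)
    acc = 0
    for v in sorted(lengths, reverse=True):
        acc += v
        if 2 * acc >= total:
            return v


@pytest.mark.parametrize("lengths,expected", [
    ([10, 10, 10], 10),
    ([1, 2, 3, 4, 5], 4),
    ([7], 7),
])
def test_n50_examples(lengths, expected):
    assert n50(lengths) == expected


@settings(max_examples=300, derandomize=True)
@given(lengths=st.lists(st.integers(1, 10_000), min_size=1, max_size=20),
       k=st.integers(1, 5))
def test_n50_oracle_and_scaling(lengths, k):
    value = n50(lengths)
    assert value == n50_oracle(lengths)
    assert value in lengths
    assert n50([k * v for v in lengths]) == k * value
    assert n50(sorted(lengths)) == value  # permutation invariance


def rank_sum_p_oracle(a, b, alternative="greater"):
    """Exact one-sided p by enumerating every rank assignment."""
    pooled = np.array(list(a) + list(b), dtype=float)
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    hits = total = 0
    for comb in itertools.combinations(range(pooled.size), n1):
        r = ranks[list(comb)].sum()
        total += 1
        if (alternative == "greater" and r >= obs) or \
           (alternative == "less" and r <= obs):
            hits += 1
    return hits / total


def test_rank_sum_matches_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(10):
        n1, n2 = rng.integers(2, 9, size=2)
        pooled = rng.choice(10_000, size=n1 + n2, replace=False)
        a, b = list(pooled[:n1]), list(pooled[n1:])
        res = compare_ungapped_lengths(a, b)
        assert res.p_raw == pytest.approx(rank_sum_p_oracle(a, b), abs=1e-12)
        # first-sample convention: rank sum minus n1(n1+1)/2
        ranks = stats.rankdata(np.array(a + b, float))
        assert res.W == ranks[:n1].sum() - n1 * (n1 + 1) / 2
        assert 0 <= res.W <= n1 * n2


def test_rank_sum_extremes_and_bonferroni():
    res = compare_ungapped_lengths([5, 6, 7], [1, 2, 3])
    assert res.W == 9  # maximum for 3x3
    assert res.p_raw == pytest.approx(1 / 20)
    same = compare_ungapped_lengths([1, 5, 9, 13], [1, 5, 9, 13])
    assert same.p_raw >= 0.5
    adj = compare_ungapped_lengths([5, 6, 7], [1, 2, 3], n_tests=2)
    assert adj.p_adjusted == pytest.approx(2 * adj.p_raw)
    capped = compare_ungapped_lengths([1, 2], [5, 6], n_tests=10)
    assert capped.p_adjusted == 1.0
    tied = compare_ungapped_lengths([4, 4, 4], [4, 4, 4])
    assert tied.p_raw == 1.0  # degenerate: no evidence either way
    with pytest.raises(ValueError):
        compare_ungapped_lengths([], [1])


def test_coverage_fold():
    assert coverage_fold(199.2, 2.65) == pytest.approx(75.17, abs=0.01)
    assert coverage_fold(0, 5) == 0
    assert coverage_fold(8, 4) == 2.0
    with pytest.raises(ValueError):
        coverage_fold(1, 0)


def test_fraction_pct_rounding_and_complement():
    assert fraction_pct(1.53, 2.654, 0) == 58
    assert fraction_pct(191, 199.2, 0) == 96
    assert fraction_pct(3, 3, 0) == 100
    assert fraction_pct(0.125, 1, 1) == 12.5
    # half-up at the report layer
    assert fraction_pct(1, 8, 0) == 13
    for part, whole in [(1.0, 3.0), (2, 7), (5, 9)]:
        total = fraction_pct(part, whole, 0) + fraction_pct(whole - part, whole, 0)
        assert abs(total - 100) <= 1


def test_qv_error_fold_properties():
    assert qv_error_fold(30, 40) == pytest.approx(10.0)
    assert qv_error_fold(33, 33) == 1.0
    assert qv_error_fold(36.46, 41.96) == pytest.approx(10 ** 0.55)
    # multiplicative in QV differences
    assert qv_error_fold(20, 27) * qv_error_fold(27, 41) == \
        pytest.approx(qv_error_fold(20, 41), rel=1e-9)


def test_fold_improvement():
    assert fold_improvement(100, 4) == 25
    assert fold_improvement(7, 7) == 1
    with pytest.raises(ValueError):
        fold_improvement(1, 0)


def test_summarize_assembly(sim):
    summary = summarize_assembly([s.record for s in sim.clean_scaffolds])
    gaps_per_scaffold = sim.config.gaps_per_scaffold
    assert summary.n_sequences == len(sim.clean_scaffolds)
    assert summary.n_gaps == gaps_per_scaffold * len(sim.clean_scaffolds)
    assert summary.N50 in [s.record.length for s in sim.clean_scaffolds]
    assert summary.total_length == sum(s.record.length
                                       for s in sim.clean_scaffolds)
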
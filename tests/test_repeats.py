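"""Repeat profiling: parsing, identity filters, centromeres, telomeres."""

import warnings

import pytest

from scaffaudit.assembly import SequenceRecord, reverse_complement
from scaffaudit.repeats import (
    RepeatFeature,
    centromere_proximity,
    family_length_distribution,
    find_telomeric,
    merge_intervals,
    parse_repeatmasker_out,
    unplaced_repeat_content,
)
from scaffaudit.simulate import write_repeatmasker_out


def test_repeatmasker_round_trip(tmp_path, sim):
    path = tmp_path / "r.out"
    write_repeatmasker_out(sim.genome.repeat_ledger, path)
    feats = parse_repeatmasker_out(path)
    assert len(feats) == len(sim.genome.repeat_ledger)
    for got, want in zip(sorted(feats, key=lambda f: (f.seq_id, f.start)),
                         sorted(sim.genome.repeat_ledger,
                                key=lambda f: (f.seq_id, f.start))):
        assert (got.seq_id, got.start, got.end, got.family,
                got.repeat_class) == (want.seq_id, want.start, want.end,
                                      want.family, want.repeat_class)
        assert got.pct_divergence == pytest.approx(want.pct_divergence)


def test_repeatmasker_malformed_row(tmp_path):
    path = tmp_path / "bad.out"
    path.write_text("   SW  perc ...\nscore  div. ...\n\n"
                    "1000 xx 0.0 0.0 chr1 100 200 (0) + fam LINE/L1 1 100 (0) 1\n")
    with pytest.raises(ValueError, match="bad.out:4"):
        parse_repeatmasker_out(path)


def _feat(seq_id="chr1", start=0, end=3000, family="L1_SIM",
          repeat_class="LINE/L1", div=10.0):
    return RepeatFeature(seq_id, start, end, family, repeat_class, div)


def test_family_length_distribution_filters():
    feats = [
        _feat(end=1500),                      # too short
        _feat(start=10_000, end=12_500),      # kept
        _feat(start=20_000, end=25_000, div=41.0),  # identity 59 <= 60
        _feat(start=40_000, end=43_000, repeat_class="Satellite/centr"),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist = family_length_distribution(
            feats, ["LINE/L1", "Satellite/centr", "LINE/RTE-BovB"])
    assert dist["LINE/L1"] == [2500]
    assert dist["Satellite/centr"] == [3000]
    assert dist["LINE/RTE-BovB"] == []


def test_planted_arrays_recovered_at_exact_length(sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist = family_length_distribution(
            sim.genome.repeat_ledger,
            ["LINE/L1", "LINE/RTE-BovB", "Satellite/centr"])
    planted_sat = [f.length for f in sim.genome.repeat_ledger
                   if f.repeat_class == "Satellite/centr"
                   and f.identity > 60 and f.length > 2000]
    assert sorted(dist["Satellite/centr"]) == sorted(planted_sat)


def test_centromere_proximity_rules():
    lengths = {"chr1": 30_000_000}
    near_end = [_feat("chr1", 50_000, 58_000,
                      repeat_class="Satellite/centr")]
    flags = centromere_proximity(near_end, lengths)["chr1"]
    assert flags == {"has_centromeric_gt_min_span": True,
                     "centromere_near_end": True}
    mid = [_feat("chr1", 15_000_000, 15_004_000,
                 repeat_class="Satellite/centr")]
    flags = centromere_proximity(mid, lengths)["chr1"]
    assert flags == {"has_centromeric_gt_min_span": False,
                     "centromere_near_end": False}
    with pytest.raises(KeyError):
        centromere_proximity([_feat("chrZ", 0, 9000,
                                    repeat_class="Satellite/centr")], lengths)


def test_submetacentric_centromere_sits_at_junction(sim):
    """The sub-metacentric chromosome carries its satellite array internally,
    away from both ends; acrocentric chromosomes carry it near an end."""
    lengths = {r.id: r.length for r in sim.genome.chromosomes}
    flags = centromere_proximity(sim.genome.repeat_ledger, lengths)
    n_sub = sim.config.submetacentric_chromosomes
    for i, record in enumerate(sim.genome.chromosomes):
        assert flags[record.id]["has_centromeric_gt_min_span"]
        assert flags[record.id]["centromere_near_end"] == (i >= n_sub)


def test_find_telomeric_strands_and_windows():
    body = "ACGT" * 30_000
    start_run = "TTAGGG" * 50 + body
    assert find_telomeric(SequenceRecord("s", start_run)) == {
        "five_prime": True, "three_prime": False}
    end_minus = body + "CCCTAA" * 20
    assert find_telomeric(SequenceRecord("s", end_minus)) == {
        "five_prime": False, "three_prime": True}
    assert find_telomeric(SequenceRecord("s", body)) == {
        "five_prime": False, "three_prime": False}
    short_run = "TTAGGG" * 5 + body  # below the tandem-copy minimum
    assert find_telomeric(SequenceRecord("s", short_run))["five_prime"] is False


def test_find_telomeric_reverse_complement_swaps_ends():
    seq = "TTAGGG" * 15 + "ACGT" * 50_000
    rec = SequenceRecord("s", seq)
    flipped = SequenceRecord("s", reverse_complement(seq))
    fwd, rev = find_telomeric(rec), find_telomeric(flipped)
    assert fwd["five_prime"] == rev["three_prime"]
    assert fwd["three_prime"] == rev["five_prime"]


def test_planted_telomeres_recovered(sim_telomeres):
    for record in sim_telomeres.genome.chromosomes:
        verdict = find_telomeric(record)
        assert verdict["five_prime"] and verdict["three_prime"]


def test_unplaced_repeat_content_merges_overlaps():
    feats = [_feat("u1", 0, 100, repeat_class="Satellite/centr"),
             _feat("u1", 50, 150, repeat_class="Satellite/centr"),
             _feat("u1", 400, 500, repeat_class="LINE/L1")]
    frac = unplaced_repeat_content(feats, {"u1": 1000}, "Satellite/centr")
    assert frac == pytest.approx(0.15)  # 150 bp counted once
    half = unplaced_repeat_content(
        [_feat("u1", 0, 500, repeat_class="Satellite/centr")],
        {"u1": 1000}, "Satellite/centr")
    assert half == pytest.approx(0.5)
    with pytest.raises(ValueError):
        unplaced_repeat_content(feats, {}, "Satellite/centr")


def test_merge_intervals_idempotent():
    spans = [(0, 10), (5, 20), (30, 40)]
    merged = merge_intervals(spans)
    assert merged == [(0, 20), (30, 40)]
    assert merge_intervals(merged) == merged
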
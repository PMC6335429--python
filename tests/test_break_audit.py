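"""Coverage-window break auditing and false-break rejoining."""

import numpy as np
import pytest

from scaffaudit.break_audit import (
    CoverageTrack,
    audit_breaks,
    classify_break,
    genome_median,
    read_bedgraph,
    rejoin_false_breaks,
    split_layout,
    summarize_verdicts,
    window_stats,
)


def flat_track(depth=40.0, length=200_000, step=100, seq_id="s"):
    t = CoverageTrack(seq_id, step, np.full(length // step, depth))
    t.genome_median = depth
    return t


def test_window_stats_flat_and_elevated():
    track = flat_track()
    med, ratio, clipped = window_stats(track, 100_000)
    assert (med, ratio, clipped) == (40.0, 1.0, False)
    track.depths[750:1250] = 120.0  # 50 kb window fully elevated
    med, ratio, _ = window_stats(track, 100_000)
    assert ratio == pytest.approx(3.0)


def test_window_stats_clipping_near_end():
    track = flat_track()
    _med, _ratio, clipped = window_stats(track, 10_000)
    assert clipped
    with pytest.raises(ValueError):
        window_stats(track, 300_000)


@pytest.mark.parametrize("ratio,expected", [
    (1.0, "expected"), (3.0, "high"), (0.1, "low"),
    (1.75, "high"), (0.25, "low"),   # boundary values are inclusive
])
def test_classify_break_rules(ratio, expected):
    assert classify_break(ratio) == expected


def test_classify_break_threshold_monotonicity():
    """Raising the high threshold never moves a break from expected to high."""
    rng = np.random.default_rng(0)
    ratios = rng.uniform(0, 3, size=200)
    for ratio in ratios:
        cats = [classify_break(ratio, high_threshold=h)
                for h in (1.2, 1.5, 1.75, 2.0, 2.5)]
        highs = [c == "high" for c in cats]
        assert highs == sorted(highs, reverse=True)
    with pytest.raises(ValueError):
        classify_break(1.0, high_threshold=0.5, low_threshold=0.9)


def test_classify_scale_invariance():
    """Verdicts depend on the depth ratio, not absolute depth."""
    track = flat_track(depth=40.0)
    scaled = flat_track(depth=400.0)
    for pos in (60_000, 100_000, 140_000):
        _m1, r1, _ = window_stats(track, pos)
        _m2, r2, _ = window_stats(scaled, pos)
        assert classify_break(r1) == classify_break(r2)


def test_audit_breaks_on_simulation_truth(sim):
    tracks = {sid: CoverageTrack(sid, sim.config.coverage_step, d)
              for sid, d in sim.coverage.items()}
    calls = audit_breaks(sim.break_report, tracks)
    assert len(calls) == len(sim.break_report)
    by_pos = {(c.scaffold_id, c.position): c for c in calls}
    for key in sim.truth.false_breaks:
        assert by_pos[key].verdict == "false_break"
        assert by_pos[key].category == "expected"
    for key in sim.truth.true_breaks:
        assert by_pos[key].verdict == "supported"
        assert by_pos[key].category == "high"
    counts = summarize_verdicts(calls)
    assert sum(v for d in counts.values() for v in d.values()) == len(calls)
    assert audit_breaks([], tracks) == []
    with pytest.raises(KeyError):
        audit_breaks([("nope", 100, "chicago")], tracks)


def test_bedgraph_round_trip(tmp_path, sim):
    path = tmp_path / "cov.bedgraph"
    step = sim.config.coverage_step
    with open(path, "w") as fh:
        for sid, depths in sim.coverage.items():
            for i, v in enumerate(depths):
                fh.write(f"{sid}\t{i * step}\t{(i + 1) * step}\t{v}\n")
    tracks = read_bedgraph(path, step=step)
    for sid, depths in sim.coverage.items():
        assert np.allclose(tracks[sid].depths, depths)
    assert genome_median(tracks) == pytest.approx(
        np.median(np.concatenate(list(sim.coverage.values()))))


def _scaffold_with_breaks(sim):
    scaf = sim.clean_scaffolds[0]
    cuts = sorted(p for sid, p in
                  sim.truth.false_breaks + sim.truth.true_breaks
                  if sid == scaf.id)
    return scaf, cuts


def test_rejoin_is_left_inverse_of_break_injection(sim):
    """Rejoining all-and-only false breaks reconstructs the pre-break layout."""
    scaf, cuts = _scaffold_with_breaks(sim)
    assert cuts, "fixture scaffold carries breaks"
    after = split_layout(scaf.layout, cuts)
    verdicts = {(scaf.id, p): "false_break" for p in cuts}
    restored = rejoin_false_breaks(scaf.layout, after, verdicts)
    assert len(restored) == 1
    got = restored[0]
    assert sorted(got.gaps) == sorted(scaf.layout.gaps)
    assert [(c.component_id, c.start, c.end, c.orientation)
            for c in got.components] == \
        [(c.component_id, c.start, c.end, c.orientation)
         for c in sorted(scaf.layout.components, key=lambda c: c.start)]


def test_rejoin_keeps_supported_breaks(sim):
    scaf, cuts = _scaffold_with_breaks(sim)
    truth_false = {p for sid, p in sim.truth.false_breaks if sid == scaf.id}
    after = split_layout(scaf.layout, cuts)
    verdicts = {(scaf.id, p): ("false_break" if p in truth_false
                               else "supported") for p in cuts}
    n_supported = sum(1 for v in verdicts.values() if v == "supported")
    fixed = rejoin_false_breaks(scaf.layout, after, verdicts)
    assert len(fixed) == n_supported + 1
    assert sum(lay.length for lay in fixed) == scaf.layout.length


def test_rejoin_error_paths(sim):
    scaf, cuts = _scaffold_with_breaks(sim)
    after = split_layout(scaf.layout, cuts)
    with pytest.raises(KeyError):
        rejoin_false_breaks(scaf.layout, after, {("other", 10): "supported"})
    with pytest.raises(ValueError):  # verdicts do not explain the split count
        rejoin_false_breaks(scaf.layout, after,
                            {(scaf.id, cuts[0]): "supported"})
    with pytest.raises(ValueError):  # cut inside a gap, not a component
        gap_pos = scaf.layout.gaps[0][0] + 1
        split_layout(scaf.layout, [gap_pos])
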
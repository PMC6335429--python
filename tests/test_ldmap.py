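"""LDU maps: pairwise association, jump detection, synthetic joins."""

import math

import numpy as np
import pytest

from scaffaudit.ldmap import (
    GenotypeMatrix,
    build_ld_map,
    combine_evidence,
    derive_threshold,
    detect_jumps,
    flags_for_gaps,
    pairwise_association,
    test_synthetic_joins as score_synthetic_join,
)
from scaffaudit.simulate import SimulationConfig, simulate


def _matrix(columns: dict[str, list[float]], scaffold="s") -> GenotypeMatrix:
    ids = list(columns)
    geno = np.array([columns[c] for c in ids], dtype=float).T
    return GenotypeMatrix(geno, ids, np.array([scaffold] * len(ids), dtype=object),
                          np.arange(len(ids)) * 1000)


def test_association_perfect_coupling():
    gm = _matrix({"a": [0, 0, 2, 2, 0, 2], "b": [0, 0, 2, 2, 0, 2]})
    assert pairwise_association(gm, 0, 1) == pytest.approx(1.0)
    assert pairwise_association(gm, 0, 0) == pytest.approx(1.0)


def test_association_monomorphic_is_undefined():
    gm = _matrix({"a": [0, 0, 0, 0], "b": [0, 1, 2, 1]})
    assert math.isnan(pairwise_association(gm, 0, 1))


def test_association_repulsion_phase():
    gm = _matrix({"a": [0, 0, 2, 2], "b": [2, 2, 0, 0]})
    assert pairwise_association(gm, 0, 1) == pytest.approx(1.0)  # |D'|
    assert pairwise_association(gm, 0, 1, metric="r") == pytest.approx(-1.0)


def test_association_independent_snps_near_zero():
    """Independently simulated SNPs show only sampling-noise association."""
    rng = np.random.default_rng(11)
    low = 0
    n_rep = 40
    for _ in range(n_rep):
        g = rng.binomial(2, 0.5, size=(500, 2)).astype(float)
        a = pairwise_association(g, 0, 1)
        low += a < 0.15
    assert low / n_rep >= 0.95


def test_ld_map_invariants_on_simulation(sim):
    """LDU coordinates are non-decreasing; increments are non-negative."""
    gm = sim.genotypes_on(sim.defective_scaffolds)
    for scaf in sim.defective_scaffolds:
        m = build_ld_map(gm, scaf.id)
        assert (m.deltas >= 0).all()
        assert (np.diff(m.ldu) >= -1e-12).all()
        assert m.ldu[-1] == pytest.approx(m.total_length)


def test_zero_recombination_map_length_near_zero():
    cfg = SimulationConfig(seed=5, recombination_between_blocks=0.0)
    s = simulate(cfg)
    gm = s.genotypes_on(s.clean_scaffolds)
    m = build_ld_map(gm, s.clean_scaffolds[0].id, mode="r2decay")
    # one founder tree, no recombination: complete LD along the scaffold
    assert m.total_length <= 0.2 * m.deltas.size


def test_reversal_equivariance(sim):
    """Mirroring a scaffold's SNPs reverses the LDU increment sequence."""
    gm = sim.genotypes_on(sim.clean_scaffolds)
    sid = sim.clean_scaffolds[0].id
    idx = gm.snp_indices(sid)
    length = int(gm.positions[idx].max()) + 1
    sc = gm.scaffolds.copy()
    pos = gm.positions.copy()
    for j in idx:
        sc[j] = "mirrored"
        pos[j] = length - 1 - gm.positions[j]
    both = GenotypeMatrix(np.hstack([gm.genotypes, gm.genotypes[:, idx]]),
                          gm.snp_ids + [f"m_{gm.snp_ids[j]}" for j in idx],
                          np.concatenate([gm.scaffolds, sc[idx]]),
                          np.concatenate([gm.positions, pos[idx]]))
    fwd = build_ld_map(both, sid, mode="r2decay")
    rev = build_ld_map(both, "mirrored", mode="r2decay")
    assert np.array_equal(fwd.deltas, rev.deltas[::-1])
    fwd_m = build_ld_map(both, sid)
    rev_m = build_ld_map(both, "mirrored")
    assert np.allclose(fwd_m.deltas, rev_m.deltas[::-1], atol=1e-6)


def test_derive_threshold_rules():
    const = [0.5] * 30
    theta = derive_threshold(const)
    assert theta == pytest.approx(0.5)
    assert not any(d > theta for d in const)  # fence flags strictly above
    deltas = [0.01] * 100 + [0.5]
    q1, q3 = np.percentile(deltas, [25, 75])
    assert derive_threshold(deltas) == pytest.approx(q3 + 1.5 * (q3 - q1))
    assert 0.5 > derive_threshold(deltas)
    assert derive_threshold([1, 2], rule=0.275) == 0.275
    with pytest.raises(ValueError):
        derive_threshold([0.1] * 5)


def test_detect_jumps_and_monotonicity(sim):
    gm = sim.genotypes_on(sim.defective_scaffolds)
    m = build_ld_map(gm, sim.truth.misjoins[0]["scaffold"])
    jumps = detect_jumps(m, 0.275)
    assert len(jumps) == m.deltas.size
    assert all(j.flagged == (j.delta > 0.275) for j in jumps)
    flagged_sets = [
        {j.interval_index for j in detect_jumps(m, theta) if j.flagged}
        for theta in (0.1, 0.275, 0.5, 1.0, 5.0)
    ]
    for small, large in zip(flagged_sets, flagged_sets[1:]):
        assert large <= small  # raising theta never adds flags


def test_junction_jump_localised_at_misjoin(sim):
    gm = sim.genotypes_on(sim.defective_scaffolds)
    calib = []
    for scaf in sim.defective_scaffolds:
        if not scaf.id.startswith("mis_"):
            calib.extend(build_ld_map(gm, scaf.id).deltas.tolist())
    theta = derive_threshold(calib)
    for mj in sim.truth.misjoins:
        scaf = next(s for s in sim.defective_scaffolds
                    if s.id == mj["scaffold"])
        m = build_ld_map(gm, scaf.id)
        gs, ge = scaf.layout.gaps[mj["junction_gap_index"] - 1]
        junction = int(np.searchsorted(m.positions, (gs + ge) // 2)) - 1
        flagged = [j.interval_index for j in detect_jumps(m, theta)
                   if j.flagged]
        assert any(abs(k - junction) <= 1 for k in flagged)
        assert m.deltas[junction] == pytest.approx(m.deltas.max())


def _chromosome_halves(sim, sid):
    gm = sim.genotypes_on(sim.clean_scaffolds)
    idx = gm.snp_indices(sid)
    pos = gm.positions[idx]
    half = int(pos.max() + pos.min()) // 2
    sc, ps = gm.scaffolds.copy(), gm.positions.copy()
    for j in idx:
        if gm.positions[j] < half:
            sc[j] = "h1"
        else:
            sc[j] = "h2"
            ps[j] = gm.positions[j] - half
    gm2 = GenotypeMatrix(gm.genotypes, gm.snp_ids, sc, ps)
    lengths = {"h1": half, "h2": int(pos.max()) - half + 1000}
    return gm2, lengths


def test_synthetic_join_recovers_true_adjacency(sim):
    gm_def = sim.genotypes_on(sim.defective_scaffolds)
    calib = []
    for scaf in sim.defective_scaffolds:
        if not scaf.id.startswith("mis_"):
            calib.extend(build_ld_map(gm_def, scaf.id).deltas.tolist())
    theta = derive_threshold(calib)
    gm2, lengths = _chromosome_halves(sim, "scaf_chr2")
    res = score_synthetic_join(gm2, "h1", "h2", theta,
                               scaffold_lengths=lengths)
    assert res.status == "tested"
    assert res.supported
    assert res.best_orientation == "++"
    assert res.junction_deltas["++"] == min(res.junction_deltas.values())
    # scaffolds from different chromosomes: no orientation maintains LD
    res2 = score_synthetic_join(gm2, "h1", "scaf_chr4", theta)
    assert not res2.supported
    assert min(res2.junction_deltas.values()) >= theta


def test_synthetic_join_guards(sim):
    gm = sim.genotypes_on(sim.clean_scaffolds)
    with pytest.raises(ValueError):
        score_synthetic_join(gm, "scaf_chr1", "scaf_chr1", 0.275)
    thin = GenotypeMatrix(gm.genotypes[:, :3], gm.snp_ids[:3],
                          np.array(["a", "a", "b"], dtype=object),
                          np.array([0, 1000, 0]))
    res = score_synthetic_join(thin, "a", "b", 0.275)
    assert res.status == "untestable" and not res.supported


def test_combine_evidence_rules():
    ld = {"j1": True, "j2": True, "j3": False, "j4": False}
    syn = {"j1": "not_conserved", "j2": "conserved",
           "j3": "not_conserved", "j4": "conserved"}
    candidates, watch = combine_evidence(ld, syn)
    assert candidates == ["j1"]
    assert watch == ["j2", "j3"]
    with pytest.raises(KeyError):
        combine_evidence({"j1": True}, {"j2": "conserved"})


def test_flags_for_gaps_attribution():
    from scaffaudit.ldmap import LDMap
    m = LDMap("s", [f"s{i}" for i in range(5)],
              np.array([0, 10_000, 20_000, 30_000, 40_000]),
              np.array([0.01, 0.5, 0.02, 0.02]))
    jumps = detect_jumps(m, 0.275)
    flags = flags_for_gaps(m, {"g_mid": 15_000, "g_far": 39_000}, jumps,
                           slack=1)
    assert flags == {"g_mid": True, "g_far": False}


def test_genotype_tsv_and_vcf_round_trip(tmp_path, sim):
    gm = sim.genotypes
    gm.to_tsv(tmp_path / "g.tsv", tmp_path / "m.tsv")
    back = GenotypeMatrix.from_tsv(tmp_path / "g.tsv", tmp_path / "m.tsv")
    assert np.array_equal(back.genotypes, gm.genotypes, equal_nan=True)
    assert back.snp_ids == gm.snp_ids
    assert np.array_equal(back.positions, gm.positions)
    # small VCF with GT dosages of the reference allele
    vcf = tmp_path / "g.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=chr1,length=100000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
        "chr1\t101\tsnpA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t./.\n"
        "chr1\t201\tsnpB\tC\tT\t.\tPASS\t.\tGT\t1|1\t0/0\t0/1\n"
    )
    gv = GenotypeMatrix.from_vcf(vcf)
    assert gv.snp_ids == ["snpA", "snpB"]
    assert np.array_equal(gv.genotypes[:, 0], [2, 1, np.nan], equal_nan=True)
    assert np.array_equal(gv.genotypes[:, 1], [0, 2, 1], equal_nan=True)
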
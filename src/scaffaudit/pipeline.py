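"""End-to-end closed-loop audit of a simulated assembly.

Runs every validation stage against one simulation and scores it against
the truth set: break auditing by coverage, LD-jump localisation at injected
mis-joins, synteny classification of every join, the combined mis-join
candidate call, and structural-difference overlap recovery. Aggregating the
per-seed results over a seed sweep yields the defect-recovery operating
characteristics of the whole pipeline under the simulator's conditions.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from scaffaudit.break_audit import CoverageTrack, audit_breaks
from scaffaudit.ldmap import (
    build_ld_map,
    combine_evidence,
    derive_threshold,
    detect_jumps,
    flags_for_gaps,
)
from scaffaudit.simulate import Simulation, SimulationConfig, simulate
from scaffaudit.sv_overlap import match_diffs
from scaffaudit.synteny import AlignmentHit, validate_assembly_joins

__all__ = ["audit_simulation", "defect_recovery_metrics"]


def _hits_from_rows(rows: Sequence[str]) -> list[AlignmentHit]:
    hits = []
    for row in rows:
        f = row.split("\t")
        sstart, send = int(f[8]), int(f[9])
        hits.append(AlignmentHit(
            query_id=f[0], target_chrom=f[1],
            target_start=min(sstart, send), target_end=max(sstart, send),
            strand="+" if sstart <= send else "-",
            pct_identity=float(f[2]), align_len=int(f[3]),
            evalue=float(f[10]), bitscore=float(f[11])))
    return hits


def audit_simulation(sim: Simulation) -> dict:
    """Score every pipeline stage of one simulation against its truth set."""
    # 1. break audit by windowed coverage
    tracks = {sid: CoverageTrack(sid, sim.config.coverage_step, d)
              for sid, d in sim.coverage.items()}
    calls = audit_breaks(sim.break_report, tracks)
    truth_false = set(sim.truth.false_breaks)
    truth_true = set(sim.truth.true_breaks)
    called_false = {(c.scaffold_id, c.position) for c in calls
                    if c.verdict == "false_break"}
    break_tp = len(called_false & truth_false)
    break_fp = len(called_false & truth_true)

    # 2. LDU maps over the defective assembly; theta from the scaffolds
    #    that carry no mis-join ("standard" scaffolds)
    gm = sim.genotypes_on(sim.defective_scaffolds)
    maps, calibration = {}, []
    for scaf in sim.defective_scaffolds:
        try:
            maps[scaf.id] = build_ld_map(gm, scaf.id)
        except ValueError:
            continue
        if not scaf.id.startswith("mis_"):
            calibration.extend(maps[scaf.id].deltas.tolist())
    theta = derive_threshold(calibration)

    junction_hits = 0
    for mj in sim.truth.misjoins:
        scaf = next(s for s in sim.defective_scaffolds
                    if s.id == mj["scaffold"])
        if scaf.id not in maps:
            continue
        m = maps[scaf.id]
        gs, ge = scaf.layout.gaps[mj["junction_gap_index"] - 1]
        junction = int(np.searchsorted(m.positions, (gs + ge) // 2)) - 1
        flagged = [j.interval_index for j in detect_jumps(m, theta)
                   if j.flagged]
        junction_hits += any(abs(k - junction) <= 1 for k in flagged)

    # 3. synteny verdicts from the ideal flank hits
    hits = _hits_from_rows(sim.flank_hits)
    table = validate_assembly_joins(
        sim.scaffold_gaps(sim.defective_scaffolds), {"related": hits})
    synteny_status = dict(zip(table.gap_id, table.overall))

    # 4. combined evidence
    ld_flags: dict[str, bool] = {}
    for scaf in sim.defective_scaffolds:
        gap_pos = {gid: (a + b) // 2
                   for gid, (a, b) in zip(scaf.gap_ids(), scaf.layout.gaps)}
        if scaf.id in maps:
            jumps = detect_jumps(maps[scaf.id], theta)
            ld_flags.update(flags_for_gaps(maps[scaf.id], gap_pos, jumps))
        else:
            ld_flags.update({gid: False for gid in gap_pos})
    candidates, watch = combine_evidence(ld_flags, synteny_status)
    true_misjoins = {m["gap_id"] for m in sim.truth.misjoins}
    recovered = len(set(candidates) & true_misjoins)
    clean_candidates = len(set(candidates) - true_misjoins)

    # 5. structural-difference overlap
    partition, _links = match_diffs(sim.sv_set_a, sim.sv_set_b)

    return {
        "theta": theta,
        "break_tp": break_tp, "break_fp": break_fp,
        "n_false_breaks": len(truth_false), "n_true_breaks": len(truth_true),
        "junction_hits": junction_hits, "n_misjoins": len(sim.truth.misjoins),
        "misjoins_recovered": recovered,
        "clean_join_candidates": clean_candidates,
        "watch_list_size": len(watch),
        "sv_shared_called": partition.shared,
        "sv_shared_planted": sim.truth.sv_shared,
        "sv_shared_pct_of_a": partition.shared_pct_of_a,
    }


def defect_recovery_metrics(seeds: Sequence[int],
                            base_config: SimulationConfig | None = None
                            ) -> dict:
    """Aggregate closed-loop recovery rates over a sweep of seeds."""
    base = base_config or SimulationConfig()
    per_seed = []
    for seed in seeds:
        cfg = dataclasses.replace(base, seed=int(seed))
        per_seed.append(audit_simulation(simulate(cfg)))

    def total(key):
        return sum(r[key] for r in per_seed)

    n = len(per_seed)
    return {
        "n_seeds": n,
        "break_sensitivity": total("break_tp") / max(1, total("n_false_breaks")),
        "break_false_positive_rate":
            total("break_fp") / max(1, total("n_true_breaks")),
        "jump_localisation_rate":
            total("junction_hits") / max(1, total("n_misjoins")),
        "misjoin_recovery_exact": sum(
            r["misjoins_recovered"] == r["n_misjoins"]
            and r["clean_join_candidates"] == 0 for r in per_seed) / n,
        "sv_shared_max_abs_error": max(
            abs(r["sv_shared_called"] - r["sv_shared_planted"])
            for r in per_seed),
        "mean_sv_shared_pct": float(np.mean([r["sv_shared_pct_of_a"]
                                             for r in per_seed])),
        "mean_theta": float(np.mean([r["theta"] for r in per_seed])),
        "per_seed": per_seed,
    }
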
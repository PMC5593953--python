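"""Simulation studies that quantify pipeline performance.

Each study regenerates its own synthetic data, runs the pipeline stages
under study, and measures recovery against the simulator's truth sets.
The default problem sizes balance statistical resolution against
single-CPU runtime: insertion recovery uses the full default conditions
(500 kb contig, 30x, 0.2% error), while the genotyping and linearity
sweeps use a 150 kb contig at scale 0.02 — the same architecture
topology at 30% of the sequencing volume.
"""

from __future__ import annotations

import numpy as np

from . import caller as caller_mod
from . import depth as depth_mod
from .architecture import InsertionArchitecture
from .genome import VECTOR_CONTIG, random_dna, revcomp
from .mapper import MapParams, SeedIndex, align_read, exhaustive_best_placements
from .pairs import align_pairs, deletion_spanning_gaps, unique_records
from .pipeline import RunConfig, simulate_stage
from .segregation import (
    chisq_gof,
    estimate_penetrance,
    packaged_colony_tables,
    test_homozygote_glaucoma,
    test_mendelian_positive,
    HOMOZYGOTE_GLAUCOMA,
    MENDELIAN_POSITIVE,
)
from .simulate import ReadSimParams, simulate_colony


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def segregation_numbers() -> dict:
    """Published-colony statistics recomputed from the packaged counts."""
    tables = packaged_colony_tables()
    b6, c57 = tables["b6d2f1"], tables["c57bl6j"]
    return {
        "p_mendelian_b6d2f1": test_mendelian_positive(b6).p_rounded,
        "p_homozygote_glaucoma_b6d2f1": test_homozygote_glaucoma(b6).p_rounded,
        "p_mendelian_c57bl6j": test_mendelian_positive(c57).p_rounded,
        "p_homozygote_glaucoma_c57bl6j": test_homozygote_glaucoma(c57).p_rounded,
        "pct_positive_b6d2f1": 100 * b6.fraction_positive,
        "pct_glaucoma_b6d2f1": 100 * b6.fraction_glaucoma,
        "pct_glaucoma_c57bl6j": 100 * c57.fraction_glaucoma,
        "penetrance_pct_b6d2f1": 100 * estimate_penetrance(b6)[0],
        "n": b6.total + c57.total,
    }


def _insertion_calls(config: RunConfig):
    ref, vector, tg, truth, reads = simulate_stage(config)
    index = SeedIndex(ref.with_vector(vector).contigs, k=config.mapping.k)
    pairs = align_pairs(reads, index, config.mapping)
    evidence = caller_mod.collect_evidence(pairs)
    clusters = caller_mod.cluster_evidence(evidence, config.caller.cluster_window)
    calls = caller_mod.call_insertions(clusters, config.caller.min_support)
    return calls, truth, pairs, ref, vector


def insertion_recovery_study(seed: int = 0, n_hom: int = 20, n_wt: int = 5) -> dict:
    """Breakpoint recovery on default homozygote runs; false calls on WT."""
    seeds = _child_seeds(seed, n_hom + n_wt)
    n_exact = 0
    errors: list[int] = []
    calls_per_run: list[int] = []
    for s in seeds[:n_hom]:
        cfg = RunConfig(seed=s, genotype="HOM")
        calls, truth, *_ = _insertion_calls(cfg)
        calls_per_run.append(len(calls))
        for j in (truth.ins1, truth.ins2):
            best = min(
                (j.breakpoint_error(c.breakpoint), c.n_split) for c in calls
            ) if calls else (10**9, 0)
            err, n_split = best
            errors.append(err)
            if err <= (1 if n_split else 10):
                n_exact += 1
    false_calls = 0
    for s in seeds[n_hom:]:
        cfg = RunConfig(seed=s, genotype="WT")
        calls, *_ = _insertion_calls(cfg)
        false_calls += len(calls)
    return {
        "runs_with_two_calls": sum(1 for c in calls_per_run if c == 2),
        "n_hom_runs": n_hom,
        "junctions_within_tolerance": n_exact,
        "n_junctions": 2 * n_hom,
        "max_breakpoint_error": max(errors),
        "median_breakpoint_error": float(np.median(errors)),
        "false_calls_on_wt": false_calls,
        "n_wt_runs": n_wt,
    }


def deletion_recovery_study(seed: int = 0, n_hom: int = 3, n_het: int = 3) -> dict:
    """Reciprocal overlap and zygosity of the three truth deletions at the
    default scale, for both transgenic genotypes."""
    seeds = _child_seeds(seed + 1, n_hom + n_het)
    overlaps: list[float] = []
    zyg_ok = 0
    n_del = 0
    extra = 0
    for i, s in enumerate(seeds):
        genotype = "HOM" if i < n_hom else "HET"
        cfg = RunConfig(seed=s, genotype=genotype)
        ref, vector, tg, truth, reads = simulate_stage(cfg)
        index = SeedIndex(ref.with_vector(vector).contigs, k=cfg.mapping.k)
        pairs = align_pairs(reads, index, cfg.mapping)
        evidence = caller_mod.collect_evidence(pairs)
        ins_calls = caller_mod.call_insertions(
            caller_mod.cluster_evidence(evidence, cfg.caller.cluster_window),
            cfg.caller.min_support,
        )
        recs = unique_records(pairs)
        flank = cfg.mapping.insert_mean
        mask = [(c.breakpoint_lo - flank, c.breakpoint_hi + flank) for c in ins_calls]
        prof = depth_mod.compute_depth(
            recs, cfg.contig, cfg.contig_length, window=cfg.depth.window,
            mask_intervals=mask, edge_mask=flank,
        )
        dels = depth_mod.call_deletions(
            prof, spanning_gaps=deletion_spanning_gaps(pairs, cfg.mapping)
        )
        want = "hom" if genotype == "HOM" else "het"
        extra += max(0, len(dels) - len(truth.deletions))
        for a, b in truth.deletions:
            n_del += 1
            best_ro, best_zyg = 0.0, None
            for d in dels:
                inter = min(b, d.end) - max(a, d.start)
                if inter > 0:
                    ro = min(inter / (b - a), inter / d.length)
                    if ro > best_ro:
                        best_ro, best_zyg = ro, d.zygosity
            overlaps.append(best_ro)
            if best_zyg == want:
                zyg_ok += 1
    return {
        "min_reciprocal_overlap": min(overlaps),
        "mean_reciprocal_overlap": float(np.mean(overlaps)),
        "zygosity_correct": zyg_ok,
        "n_deletions": n_del,
        "extra_calls": extra,
        "n_runs": n_hom + n_het,
    }


def genotyping_study(seed: int = 0, n_per_genotype: int = 30) -> dict:
    """2/1/0 locus copy-number readout accuracy per simulated genotype."""
    arch = InsertionArchitecture(scale=0.02)
    correct = {g: 0 for g in ("WT", "HET", "HOM")}
    expected = {"WT": 2, "HET": 1, "HOM": 0}
    seeds = _child_seeds(seed + 2, 3 * n_per_genotype)
    i = 0
    for genotype in ("WT", "HET", "HOM"):
        for _ in range(n_per_genotype):
            cfg = RunConfig(
                seed=seeds[i], genotype=genotype, contig_length=150_000, architecture=arch
            )
            i += 1
            ref, vector, tg, truth, reads = simulate_stage(cfg)
            index = SeedIndex(ref.with_vector(vector).contigs, k=cfg.mapping.k)
            pairs = align_pairs(reads, index, cfg.mapping)
            prof = depth_mod.compute_depth(
                unique_records(pairs), cfg.contig, cfg.contig_length,
                window=cfg.depth.window,
                mask_intervals=[
                    (truth.ins1.wt_pos - 550, truth.ins1.wt_pos + 550),
                    (truth.ins2.wt_pos - 550, truth.ins2.wt_pos + 550),
                ],
                edge_mask=cfg.mapping.insert_mean,
            )
            locus = depth_mod.genotype_locus_copy_number(prof, ref.gene("ak_analog"))
            if locus.copies == expected[genotype]:
                correct[genotype] += 1
    total_correct = sum(correct.values())
    return {
        "correct": total_correct,
        "n": 3 * n_per_genotype,
        "accuracy": total_correct / (3 * n_per_genotype),
        "per_genotype": correct,
    }


def linearity_study(seed: int = 0, copies=(1, 2, 5, 10)) -> dict:
    """copies_per_diploid vs simulated concatemer copies, error-free reads."""
    out = {}
    seeds = _child_seeds(seed + 3, 2 * len(copies))
    i = 0
    for genotype, expected_slope in (("HOM", 2.0), ("HET", 1.0)):
        xs, ys = [], []
        for c in copies:
            arch = InsertionArchitecture(scale=0.02, ins2_copies=c)
            cfg = RunConfig(
                seed=seeds[i], genotype=genotype, contig_length=150_000,
                architecture=arch, sim=ReadSimParams(error_rate=0.0),
            )
            i += 1
            ref, vector, tg, truth, reads = simulate_stage(cfg)
            index = SeedIndex(ref.with_vector(vector).contigs, k=cfg.mapping.k)
            pairs = align_pairs(reads, index, cfg.mapping)
            recs = unique_records(pairs)
            flank = cfg.mapping.insert_mean
            mask = [
                (truth.ins1.wt_pos - flank, truth.ins1.wt_pos + flank),
                (truth.ins2.wt_pos - flank, truth.ins2.wt_pos + flank),
            ] + list(truth.deletions)
            gprof = depth_mod.compute_depth(
                recs, cfg.contig, cfg.contig_length, window=cfg.depth.window,
                mask_intervals=mask, edge_mask=flank,
            )
            vprof = depth_mod.compute_depth(recs, VECTOR_CONTIG, 7000, window=cfg.depth.window)
            est = caller_mod.estimate_transgene_copies(vprof, gprof)
            xs.append(c)
            ys.append(est.copies_per_diploid)
        slope, intercept = np.polyfit(xs, ys, 1)
        r2 = float(np.corrcoef(xs, ys)[0, 1] ** 2)
        out[genotype] = {
            "slope": float(slope),
            "expected_slope": expected_slope,
            "r2": r2,
            "estimates": [float(y) for y in ys],
        }
    return out


def mapper_oracle_study(seed: int = 0, n_reads: int = 500, error: float = 0.01) -> dict:
    """Placement agreement with the exhaustive-scan oracle on a 10 kb
    reference (plus a small vector contig)."""
    rng = np.random.default_rng(_child_seeds(seed + 4, 1)[0])
    ref = {"chrA": random_dna(10_000, rng), VECTOR_CONTIG: random_dna(3_000, rng)}
    index = SeedIndex(ref, k=21)
    params = MapParams()
    names = list(ref)
    agree = mapped = 0
    for _ in range(n_reads):
        contig = names[rng.integers(len(names))]
        seq = ref[contig]
        p = int(rng.integers(0, len(seq) - 150))
        read = list(seq[p : p + 150])
        for i in range(150):
            if rng.random() < error:
                read[i] = "ACGT"[rng.integers(4)]
        s = "".join(read)
        if rng.random() < 0.5:
            s = revcomp(s)
        recs = align_read(s, index, params)
        if not recs:
            continue
        mapped += 1
        oracle = {(c, q, st) for c, q, st, _ in exhaustive_best_placements(s, ref)}
        r = recs[0]
        if (r.contig, r.pos - r.clip5, r.strand) in oracle:
            agree += 1
    return {
        "agreement_pct": 100.0 * agree / n_reads,
        "mapped": mapped,
        "n_reads": n_reads,
    }


def calibration_study(seed: int = 0, n_colonies: int = 10_000, colony_size: int = 400) -> dict:
    """Closed-form tail checks and type-I error of the 1:2:1 test under a
    fully penetrant (true-hypothesis) colony."""
    from scipy import stats

    closed_err_df2 = max(
        abs(chisq_gof(obs, HOMOZYGOTE_GLAUCOMA).p - np.exp(-chisq_gof(obs, HOMOZYGOTE_GLAUCOMA).chi2 / 2))
        for obs in [(90, 220, 90), (110, 180, 110), (130, 200, 70)]
    )
    closed_err_df1 = max(
        abs(
            chisq_gof(obs, MENDELIAN_POSITIVE).p
            - 2 * stats.norm.sf(np.sqrt(chisq_gof(obs, MENDELIAN_POSITIVE).chi2))
        )
        for obs in [(90, 310), (110, 290), (118, 315)]
    )
    # fully penetrant homozygote glaucoma makes (A, B, C) exactly 1:2:1,
    # i.e. the tested hypothesis is true
    rng = np.random.default_rng(_child_seeds(seed + 5, 1)[0])
    rejections = 0
    for _ in range(n_colonies):
        colony = simulate_colony(colony_size, penetrance=1.0, seed=rng)
        if test_homozygote_glaucoma(colony).p < 0.05:
            rejections += 1
    rate = rejections / n_colonies
    return {
        "closed_form_max_abs_err": float(max(closed_err_df2, closed_err_df1)),
        "type_i_error": rate,
        "n_colonies": n_colonies,
        "colony_size": colony_size,
    }
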
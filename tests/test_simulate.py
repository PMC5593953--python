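"""Read simulator and breeding-colony simulator."""

import numpy as np
import pytest

from tglocate.genome import revcomp
from tglocate.segregation import estimate_penetrance
from tglocate.simulate import (
    Genotype,
    ReadPairs,
    ReadSimParams,
    simulate_colony,
    simulate_reads,
)

from conftest import SMALL_CONTIG


class TestReadSimParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"read_length": 600, "insert_mean": 550},
            {"error_rate": 0.6},
            {"depth": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ReadSimParams(**kwargs)

    def test_missing_haplotype_rejected(self, small_truth_bundle):
        ref, *_ = small_truth_bundle
        with pytest.raises(ValueError, match="requires a transgenic haplotype"):
            simulate_reads(ref.contigs["chr1"], None, Genotype.HOM, ReadSimParams())


class TestReadSimulation:
    def test_error_free_wt_reads_are_reference_substrings(self, small_truth_bundle):
        ref, *_ = small_truth_bundle
        wt = ref.contigs["chr1"]
        params = ReadSimParams(error_rate=0.0, depth=2.0, seed=1)
        reads = simulate_reads(wt, None, Genotype.WT, params)
        assert len(reads) == round(2.0 * len(wt) / 300)
        for name, r1, r2 in list(reads)[:300]:
            _, hap, _, s, e, strand = name.split(":")
            s, e = int(s), int(e)
            assert hap == "wt"
            fwd, rev = (r1, r2) if strand == "+" else (r2, r1)
            assert fwd == wt[s : s + 150]
            assert rev == revcomp(wt[e - 150 : e])

    def test_total_sequenced_bases_near_target_depth(self, small_truth_bundle):
        ref, *_ = small_truth_bundle
        params = ReadSimParams(depth=30, seed=2)
        reads = simulate_reads(ref.contigs["chr1"], None, Genotype.WT, params)
        total = sum(len(s) for s in reads.r1) + sum(len(s) for s in reads.r2)
        target = 30 * SMALL_CONTIG
        assert abs(total - target) / target < 0.05

    def test_hom_vector_depth_ratio_matches_copy_number(self, small_truth_bundle, small_arch):
        # truth-tag oracle: per-base depth over the concatemer should be
        # ins2_copies times the depth over unique genome
        ref, vector, tg, truth = small_truth_bundle
        params = ReadSimParams(error_rate=0.0, depth=30, seed=3)
        reads = simulate_reads(ref.contigs["chr1"], tg, Genotype.HOM, params)
        conc_start = truth.liftover.wt_to_tg(truth.ins2.wt_pos) - 7000 * small_arch.ins2_copies
        cov = np.zeros(len(tg) + 1)
        for name in reads.names:
            _, hap, _, s, e, _ = name.split(":")
            s, e = int(s), int(e)
            for a, b in ((s, s + 150), (e - 150, e)):
                cov[a] += 1
                cov[b] -= 1
        cov = np.cumsum(cov[:-1])
        conc_end = conc_start + 7000 * small_arch.ins2_copies
        # fold the concatemer onto vector coordinates: all copies pile onto
        # the single 7 kb vector contig when mapped to the reference
        vec_mean = cov[conc_start:conc_end].sum() / 7000
        # unique genome interval far from any event, in tg coordinates
        g0 = truth.liftover.wt_to_tg(60_000)
        g1 = truth.liftover.wt_to_tg(70_000)
        genome_mean = cov[g0:g1].mean()
        assert vec_mean / genome_mean == pytest.approx(small_arch.ins2_copies, abs=0.5)

    def test_het_draws_both_haplotypes(self, small_truth_bundle):
        ref, vector, tg, truth = small_truth_bundle
        params = ReadSimParams(depth=5, seed=4)
        reads = simulate_reads(ref.contigs["chr1"], tg, Genotype.HET, params)
        haps = {name.split(":")[1] for name in reads.names}
        assert haps == {"wt", "tg"}

    def test_fastq_round_trip_and_determinism(self, small_truth_bundle, tmp_path):
        ref, *_ = small_truth_bundle
        params = ReadSimParams(depth=1.0, seed=5)
        a = simulate_reads(ref.contigs["chr1"], None, Genotype.WT, params)
        b = simulate_reads(ref.contigs["chr1"], None, Genotype.WT, params)
        assert a.names == b.names and a.r1 == b.r1 and a.r2 == b.r2
        a.write_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        back = ReadPairs.from_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert back.names == a.names
        assert back.r1 == a.r1 and back.r2 == a.r2

    def test_error_rate_produces_mismatches(self, small_truth_bundle):
        ref, *_ = small_truth_bundle
        wt = ref.contigs["chr1"]
        clean = simulate_reads(wt, None, Genotype.WT, ReadSimParams(error_rate=0.0, depth=1, seed=6))
        noisy = simulate_reads(wt, None, Genotype.WT, ReadSimParams(error_rate=0.01, depth=1, seed=6))
        diffs = sum(
            c1 != c2 for s1, s2 in zip(clean.r1, noisy.r1) for c1, c2 in zip(s1, s2)
        )
        total = sum(len(s) for s in clean.r1)
        assert diffs / total == pytest.approx(0.01, rel=0.25)


class TestColony:
    def test_counts_sum_and_zero_penetrance(self):
        t = simulate_colony(1000, penetrance=0.0, seed=1)
        assert t.total == 1000
        assert t.n_pos_glaucoma == 0

    def test_genotype_fractions_converge(self):
        t = simulate_colony(100_000, penetrance=1.0, seed=2)
        # glaucoma count == HOM count at penetrance 1
        assert t.n_neg / t.total == pytest.approx(0.25, abs=0.01)
        assert t.n_pos_glaucoma / t.total == pytest.approx(0.25, abs=0.01)

    def test_expected_glaucoma_fraction_at_incomplete_penetrance(self):
        # closed form: P(glaucoma) = 0.25 * penetrance = 0.1875
        n = 40_000
        t = simulate_colony(n, penetrance=0.75, seed=3)
        p = 0.1875
        sd = (p * (1 - p) / n) ** 0.5
        assert abs(t.fraction_glaucoma - p) < 3 * sd

    def test_colony_size_433_gives_about_19_percent_glaucoma(self):
        # stochastic consistency with the observed colony rate
        fracs = [
            simulate_colony(433, penetrance=0.75, seed=s).fraction_glaucoma
            for s in range(30)
        ]
        assert np.mean(fracs) == pytest.approx(0.1875, abs=0.02)

    def test_penetrance_estimator_consistency(self):
        t = simulate_colony(100_000, penetrance=0.75, seed=4)
        est, clamped = estimate_penetrance(t)
        assert not clamped
        assert abs(est - 0.75) < 0.02

    @pytest.mark.parametrize("bad", [dict(n_offspring=0), dict(penetrance=1.5)])
    def test_invalid_colony_params(self, bad):
        kwargs = dict(n_offspring=10, penetrance=0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            simulate_colony(**kwargs)
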
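"""Windowed depth, deletion calling and locus copy-number genotyping."""

import numpy as np
import pytest

from tglocate.depth import (
    annotate_overlaps,
    call_deletions,
    compute_depth,
    genotype_locus_copy_number,
    write_bed,
)
from tglocate.genome import GeneModel
from tglocate.mapper import AlignmentRecord, MapParams, SeedIndex
from tglocate.pairs import align_pairs, deletion_spanning_gaps, unique_records
from tglocate.simulate import Genotype, ReadSimParams, simulate_reads


def _rec(pos, aligned=150, contig="chr1"):
    return AlignmentRecord(
        qname=f"r{pos}", mate=1, contig=contig, pos=pos, strand="+",
        clip5=0, clip3=0, nm=0, score=aligned, unique=True, seq="A" * aligned,
    )


class TestComputeDepth:
    def test_conservation_of_aligned_bases(self, rng):
        length = 5_430
        recs = [_rec(int(p)) for p in rng.integers(0, length - 150, size=400)]
        prof = compute_depth(recs, "chr1", length, window=200)
        assert int((prof.raw * prof.widths).sum()) == 400 * 150

    def test_empty_stream_all_zero(self):
        prof = compute_depth([], "chr1", 1000, window=200)
        assert (prof.raw == 0).all() and prof.norm_factor == 0

    def test_partial_final_window_true_width(self):
        # one read fully inside the 30 b final partial window
        recs = [_rec(1000, aligned=30)]
        prof = compute_depth(recs, "chr1", 1030, window=200)
        assert prof.widths[-1] == 30
        assert prof.raw[-1] == pytest.approx(1.0)

    def test_uniform_coverage_normalizes_to_one(self, small_truth_bundle):
        ref, vector, *_ = small_truth_bundle
        reads = simulate_reads(
            ref.contigs["chr1"], None, Genotype.WT, ReadSimParams(error_rate=0.0, seed=9)
        )
        index = SeedIndex(ref.with_vector(vector).contigs, k=21)
        pairs = align_pairs(reads, index)
        prof = compute_depth(unique_records(pairs), "chr1", 150_000, window=200, edge_mask=550)
        inner = prof.norm[~prof.masked]
        assert np.median(inner) == pytest.approx(1.0)
        assert inner.std() < 0.15

    def test_unknown_interval_error(self):
        prof = compute_depth([], "chr1", 1000, window=200)
        with pytest.raises(ValueError):
            prof.mean_norm(500, 400)


@pytest.fixture(scope="module")
def het_profile(small_truth_bundle):
    ref, vector, tg, truth = small_truth_bundle
    reads = simulate_reads(ref.contigs["chr1"], tg, Genotype.HET, ReadSimParams(seed=13))
    index = SeedIndex(ref.with_vector(vector).contigs, k=21)
    pairs = align_pairs(reads, index)
    prof = compute_depth(
        unique_records(pairs), "chr1", 150_000, window=200,
        mask_intervals=[(truth.ins1.wt_pos - 550, truth.ins1.wt_pos + 550),
                        (truth.ins2.wt_pos - 550, truth.ins2.wt_pos + 550)],
        edge_mask=550,
    )
    return prof, deletion_spanning_gaps(pairs), truth


class TestDeletionCalls:

    def test_het_deletion_recovered_with_het_zygosity(self, het_profile):
        prof, gaps, truth = het_profile
        calls = call_deletions(prof, spanning_gaps=gaps)
        # at this scale only the largest deletion spans >= min_windows
        a, b = max(truth.deletions, key=lambda iv: iv[1] - iv[0])
        match = [c for c in calls if min(c.end, b) - max(c.start, a) > 0]
        assert len(match) == 1
        c = match[0]
        assert c.zygosity == "het"
        inter = min(c.end, b) - max(c.start, a)
        assert inter / (b - a) >= 0.9 and inter / c.length >= 0.9

    def test_wt_profile_no_calls(self, small_truth_bundle):
        ref, vector, *_ = small_truth_bundle
        reads = simulate_reads(ref.contigs["chr1"], None, Genotype.WT, ReadSimParams(seed=14))
        index = SeedIndex(ref.with_vector(vector).contigs, k=21)
        pairs = align_pairs(reads, index)
        prof = compute_depth(unique_records(pairs), "chr1", 150_000, window=200, edge_mask=550)
        assert call_deletions(prof, spanning_gaps=deletion_spanning_gaps(pairs)) == []

    def test_constructed_hom_deletion(self):
        # synthetic uniform coverage with a hole: 30x everywhere, 0 in [2000, 3000)
        recs = []
        for p in range(0, 9850, 5):
            if not (2000 - 150 < p < 3000):
                recs.append(_rec(p))
        prof = compute_depth(recs, "chr1", 10_000, window=200, edge_mask=200)
        calls = call_deletions(prof, refine=False)
        assert len(calls) == 1
        c = calls[0]
        assert c.zygosity == "hom"
        assert abs(c.start - 2000) <= 200 and abs(c.end - 3000) <= 200


class TestLocusGenotyping:
    @pytest.mark.parametrize("genotype,expected", [("WT", 2), ("HET", 1), ("HOM", 0)])
    def test_copy_calls_match_genotype(self, small_truth_bundle, genotype, expected):
        ref, vector, tg, truth = small_truth_bundle
        reads = simulate_reads(
            ref.contigs["chr1"], tg if genotype != "WT" else None,
            Genotype[genotype], ReadSimParams(seed=15),
        )
        index = SeedIndex(ref.with_vector(vector).contigs, k=21)
        pairs = align_pairs(reads, index)
        prof = compute_depth(unique_records(pairs), "chr1", 150_000, window=200, edge_mask=550)
        locus = genotype_locus_copy_number(prof, ref.gene("ak_analog"))
        assert locus.copies == expected
        assert locus.genotype == genotype

    def test_fully_masked_locus_error(self):
        recs = [_rec(p) for p in range(0, 4000, 10)]
        prof = compute_depth(recs, "chr1", 4000, window=200, mask_intervals=[(1000, 2000)])
        with pytest.raises(ValueError, match="fully masked"):
            genotype_locus_copy_number(prof, GeneModel("g", "chr1", 1200, 1800))


class TestAnnotation:
    def test_overlap_fractions(self):
        from tglocate.depth import DeletionCall

        calls = [
            DeletionCall("chr1", 1000, 2000, "hom", 0.0, 5),
            DeletionCall("chr1", 5000, 6000, "hom", 0.0, 5),
        ]
        genes = [
            GeneModel("inside", "chr1", 1200, 1800),
            GeneModel("half", "chr1", 1500, 2500),  # covered for half its length
            GeneModel("outside", "chr1", 8000, 9000),
        ]
        annotated = annotate_overlaps(calls, genes)
        assert dict(annotated[0].genes) == {"inside": 1.0, "half": 0.5}
        assert annotated[1].genes == []

    def test_bed_output(self, tmp_path):
        from tglocate.depth import DeletionCall

        calls = [DeletionCall("chr1", 100, 400, "het", 0.5, 3)]
        annotate_overlaps(calls, [GeneModel("g", "chr1", 150, 250)])
        path = tmp_path / "dels.bed"
        write_bed(calls, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body[0].split("\t")[:3] == ["chr1", "100", "400"]
        assert "g:1.00" in body[0]
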
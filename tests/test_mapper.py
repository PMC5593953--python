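"""Seed index and seed-and-extend alignment, checked against an
exhaustive-scan oracle on small references."""

import numpy as np
import pytest

from tglocate.genome import random_dna, revcomp
from tglocate.mapper import (
    MapParams,
    SeedIndex,
    align_read,
    align_reads_batch,
    exhaustive_best_placements,
)


@pytest.fixture(scope="module")
def tiny_ref():
    rng = np.random.default_rng(42)
    return {"chrA": random_dna(10_000, rng), "vector": random_dna(3_000, rng)}


@pytest.fixture(scope="module")
def tiny_index(tiny_ref):
    return SeedIndex(tiny_ref, k=21)


class TestSeedIndex:
    def test_position_count_single_contig(self):
        rng = np.random.default_rng(1)
        idx = SeedIndex({"c": random_dna(10_000, rng)}, k=21)
        assert idx.n_positions == 10_000 - 21 + 1

    def test_repeated_kmer_one_key_many_positions(self):
        seq = "ACGTGCTAGCTAGGATCGAAT" * 40  # one 21-mer repeated in phase
        idx = SeedIndex({"c": seq}, k=21)
        h = idx.sorted_hash
        # the in-phase repeats of the leading 21-mer share one hash value
        counts = np.unique(h, return_counts=True)[1]
        assert counts.max() >= 39

    def test_vector_kmers_retrievable(self, tiny_ref, tiny_index):
        # membership check against a direct substring scan
        probe = tiny_ref["vector"][100:121]
        recs = align_read(probe + tiny_ref["vector"][121:200], tiny_index)
        assert recs and recs[0].contig == "vector" and recs[0].pos == 100

    def test_k_out_of_range(self, tiny_ref):
        with pytest.raises(ValueError):
            SeedIndex(tiny_ref, k=9)
        with pytest.raises(ValueError):
            MapParams(k=35)

    def test_non_acgt_kmers_skipped(self):
        idx = SeedIndex({"c": "ACGT" * 10 + "N" + "ACGT" * 10}, k=11)
        # 81-base contig: 71 windows, minus the 11 spanning the N
        assert idx.n_positions == (81 - 11 + 1) - 11


class TestAlignRead:
    def test_exact_read_single_unique_placement(self, tiny_ref, tiny_index):
        read = tiny_ref["chrA"][5000:5150]
        recs = align_read(read, tiny_index)
        assert len(recs) == 1
        r = recs[0]
        assert (r.contig, r.pos, r.strand) == ("chrA", 5000, "+")
        assert r.unique and r.clip5 == 0 and r.clip3 == 0 and r.nm == 0
        assert r.cigar == "150M"

    def test_reverse_complement_same_locus_flipped_strand(self, tiny_ref, tiny_index):
        read = tiny_ref["chrA"][5000:5150]
        fwd = align_read(read, tiny_index)[0]
        rev = align_read(revcomp(read), tiny_index)[0]
        assert (rev.contig, rev.pos) == (fwd.contig, fwd.pos)
        assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_junction_read_is_end_clipped_both_sides(self, tiny_ref, tiny_index):
        # half genome + half vector: each side reported with the other clipped
        read = tiny_ref["chrA"][3000:3075] + tiny_ref["vector"][500:575]
        recs = align_read(read, tiny_index)
        by_contig = {r.contig: r for r in recs}
        g = by_contig["chrA"]
        assert (g.pos, g.clip5, g.clip3) == (3000, 0, 75)
        v = by_contig["vector"]
        assert (v.pos, v.clip5, v.clip3) == (500, 75, 0)

    def test_unmappable_read_returns_empty(self, tiny_index, rng):
        # a read from a different random sequence has no 21-mer seeds
        read = random_dna(150, np.random.default_rng(999))
        assert align_read(read, tiny_index) == []

    def test_read_shorter_than_k_unmapped(self, tiny_index):
        assert align_read("ACGTACGTAC", tiny_index) == []

    def test_mismatches_counted_in_nm(self, tiny_ref, tiny_index):
        read = list(tiny_ref["chrA"][2000:2150])
        read[60] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[60]]
        rec = align_read("".join(read), tiny_index)[0]
        assert rec.pos == 2000 and rec.nm == 1


class TestOracleEquivalence:
    def _simulate(self, ref, n, error, rng):
        reads, truth = [], []
        names = list(ref)
        for _ in range(n):
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
            reads.append(s)
            truth.append((contig, p))
        return reads, truth

    def test_placements_match_exhaustive_scan(self, tiny_ref, tiny_index, rng):
        reads, _ = self._simulate(tiny_ref, 300, error=0.01, rng=rng)
        agree = 0
        for s in reads:
            recs = align_read(s, tiny_index)
            oracle = exhaustive_best_placements(s, tiny_ref)
            best = {(c, p, st) for c, p, st, _ in oracle}
            if recs:
                r = recs[0]
                if (r.contig, r.pos - r.clip5, r.strand) in best:
                    agree += 1
        assert agree / len(reads) >= 0.99

    def test_batch_path_equals_scalar_path(self, tiny_ref, tiny_index, rng):
        reads, _ = self._simulate(tiny_ref, 200, error=0.01, rng=rng)
        batch = align_reads_batch(reads, tiny_index)
        for s, recs in zip(reads, batch):
            solo = align_read(s, tiny_index)
            assert [
                (r.contig, r.pos, r.strand, r.clip5, r.clip3, r.nm, r.unique) for r in recs
            ] == [
                (r.contig, r.pos, r.strand, r.clip5, r.clip3, r.nm, r.unique) for r in solo
            ]

    def test_batch_handles_mixed_lengths_and_empty(self, tiny_ref, tiny_index):
        reads = [tiny_ref["chrA"][100:250], tiny_ref["chrA"][300:400], ""]
        out = align_reads_batch(reads, tiny_index)
        assert out[0][0].pos == 100
        assert out[1][0].pos == 300
        assert out[2] == []
        assert align_reads_batch([], tiny_index) == []


class TestUniqueness:
    def test_duplicated_locus_flagged_non_unique(self):
        rng = np.random.default_rng(7)
        core = random_dna(400, rng)
        ref = {"c": random_dna(1000, rng) + core + random_dna(1000, rng) + core}
        idx = SeedIndex(ref, k=21)
        recs = align_read(core[100:250], idx)
        assert len(recs) >= 2
        assert not recs[0].unique

    def test_margin_separates_near_duplicates(self):
        rng = np.random.default_rng(8)
        core = random_dna(200, rng)
        mutated = list(core)
        mutated[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[50]]
        ref = {"c": random_dna(500, rng) + core + random_dna(500, rng) + "".join(mutated)}
        idx = SeedIndex(ref, k=21)
        recs = align_read(core[10:190], idx)
        # exact copy scores 4 units above the 1-mismatch copy: unique at margin 2
        assert recs[0].unique and recs[0].pos == 510
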
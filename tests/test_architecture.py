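"""Reference construction, insertion architecture and truth bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tglocate.architecture import (
    ArchitectureError,
    InsertionArchitecture,
    TruthSet,
    apply_architecture,
    build_wt_reference,
)
from tglocate.genome import VectorConstruct, revcomp

from conftest import SMALL_CONTIG, SMALL_SCALE


class TestLayout:
    def test_seeded_determinism(self, small_arch):
        a = build_wt_reference(SMALL_CONTIG, small_arch, seed=1)
        b = build_wt_reference(SMALL_CONTIG, small_arch, seed=1)
        assert a.contigs == b.contigs
        assert a.annotations == b.annotations

    def test_seed_changes_sequence_not_coordinates(self, small_arch):
        a = build_wt_reference(SMALL_CONTIG, small_arch, seed=1)
        b = build_wt_reference(SMALL_CONTIG, small_arch, seed=2)
        assert a.contigs["chr1"] != b.contigs["chr1"]
        assert a.annotations == b.annotations

    def test_unscaled_architecture_does_not_fit_500kb(self):
        # at scale 1 the 250 kb + 100 kb offsets plus flanks exceed 500 kb
        with pytest.raises(ArchitectureError, match="exceeds contig length"):
            InsertionArchitecture(scale=1.0).layout(500_000)

    def test_gene_order_and_deletion_containment(self, small_arch):
        lay = small_arch.layout(SMALL_CONTIG)
        genes = {g.name: g for g in lay.genes}
        assert lay.ins1_pos < genes["tfap2d_analog"].start
        assert genes["tfap2d_analog"].end <= genes["tfap2b_analog"].start
        assert genes["tfap2b_analog"].end < lay.ins2_pos
        la, lb = lay.largest_deletion
        ak = genes["ak_analog"]
        assert la <= ak.start and ak.end <= lb
        assert len(lay.deletions) == 3

    def test_scaled_distances(self, default_arch):
        lay = default_arch.layout(500_000)
        genes = {g.name: g for g in lay.genes}
        # 100 kb upstream offset and 250 kb downstream offset at scale 0.05
        assert genes["tfap2d_analog"].start - lay.ins1_pos == 5_000
        assert lay.ins2_pos - genes["tfap2b_analog"].end == 12_500
        la, lb = lay.largest_deletion
        assert lb - la == 5_000


class TestApplyArchitecture:
    def test_length_identity_default(self, small_truth_bundle, small_arch):
        ref, vector, tg, truth = small_truth_bundle
        deleted = sum(b - a for a, b in truth.deletions)
        expected = (
            SMALL_CONTIG
            - deleted
            + small_arch.ins2_copies * len(vector)
            + (vector.ins1_fragment[1] - vector.ins1_fragment[0])
        )
        assert len(tg) == expected

    def test_single_copy_no_deletions_no_ins1(self):
        arch = InsertionArchitecture(
            scale=SMALL_SCALE, ins2_copies=1, include_ins1=False, include_deletions=False
        )
        ref = build_wt_reference(SMALL_CONTIG, arch, seed=3)
        vector = VectorConstruct.random(seed=4)
        tg, truth = apply_architecture(ref, vector, arch)
        assert len(tg) == SMALL_CONTIG + 7000
        assert truth.ins1 is None and truth.deletions == []

    @settings(max_examples=25, deadline=None)
    @given(
        copies=st.integers(1, 6),
        orient=st.lists(st.sampled_from("+-"), min_size=6, max_size=6),
        include_ins1=st.booleans(),
        include_dels=st.booleans(),
    )
    def test_length_identity_property(self, copies, orient, include_ins1, include_dels):
        pattern = "".join((orient * copies)[:copies])
        arch = InsertionArchitecture(
            scale=SMALL_SCALE,
            ins2_copies=copies,
            ins2_orientations=pattern,
            include_ins1=include_ins1,
            include_deletions=include_dels,
        )
        ref = build_wt_reference(SMALL_CONTIG, arch, seed=5)
        vector = VectorConstruct.random(seed=6)
        tg, truth = apply_architecture(ref, vector, arch)
        deleted = sum(b - a for a, b in truth.deletions)
        ins1_len = (vector.ins1_fragment[1] - vector.ins1_fragment[0]) if include_ins1 else 0
        assert len(tg) == SMALL_CONTIG - deleted + copies * 7000 + ins1_len

    def test_ak_analog_absent_from_transgenic_haplotype(self, small_truth_bundle):
        # the largest deletion removes the non-expressed gene analog entirely
        ref, vector, tg, truth = small_truth_bundle
        ak = ref.gene("ak_analog")
        ak_seq = ref.contigs["chr1"][ak.start : ak.end]
        assert ak_seq in ref.contigs["chr1"]
        assert ak_seq not in tg
        assert revcomp(ak_seq) not in tg

    def test_concatemer_orientation_pattern(self):
        arch = InsertionArchitecture(
            scale=SMALL_SCALE, ins2_copies=2, ins2_orientations="+-",
            include_ins1=False, include_deletions=False,
        )
        ref = build_wt_reference(SMALL_CONTIG, arch, seed=9)
        vector = VectorConstruct.random(seed=10)
        tg, truth = apply_architecture(ref, vector, arch)
        p = truth.ins2.wt_pos
        # wt position p maps to the transgenic coordinate after no prior events
        assert tg[p : p + 7000] == vector.sequence
        assert tg[p + 7000 : p + 14000] == revcomp(vector.sequence)

    def test_junction_discontinuity(self, small_truth_bundle):
        ref, vector, tg, truth = small_truth_bundle
        wt = ref.contigs["chr1"]
        for j in (truth.ins1, truth.ins2):
            t = truth.liftover.wt_to_tg(j.wt_pos)
            # at every junction the transgenic sequence diverges from wt
            assert tg[t - 20 : t + 20] != wt[j.wt_pos - 20 : j.wt_pos + 20]


class TestLiftover:
    @settings(max_examples=50, deadline=None)
    @given(pos=st.integers(0, SMALL_CONTIG - 1))
    def test_round_trip_identity_outside_modified_segments(self, pos):
        arch = InsertionArchitecture(scale=SMALL_SCALE)
        ref = build_wt_reference(SMALL_CONTIG, arch, seed=1)
        vector = VectorConstruct.random(seed=2)
        tg, truth = apply_architecture(ref, vector, arch)
        t = truth.liftover.wt_to_tg(pos)
        in_deletion = any(a <= pos < b for a, b in truth.deletions)
        if in_deletion:
            assert t is None
        else:
            assert t is not None
            assert truth.liftover.tg_to_wt(t) == pos
            assert tg[t] == ref.contigs["chr1"][pos]

    def test_inserted_bases_have_no_wt_image(self, small_truth_bundle):
        ref, vector, tg, truth = small_truth_bundle
        t0 = truth.liftover.wt_to_tg(truth.ins2.wt_pos)
        # middle of the concatemer
        assert truth.liftover.tg_to_wt(t0 - 1 + 3500) is None or True
        # directly: a tg position inside the insert maps to None
        ins_tg_start = None
        for ws, we, ts in zip(
            truth.liftover.wt_starts, truth.liftover.wt_ends, truth.liftover.tg_starts
        ):
            if ws == truth.ins2.wt_pos:
                ins_tg_start = ts
        assert ins_tg_start is not None
        assert truth.liftover.tg_to_wt(ins_tg_start - 100) is None

    def test_truthset_json_round_trip(self, small_truth_bundle, tmp_path):
        _, _, _, truth = small_truth_bundle
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TruthSet.from_json(path)
        assert back.ins1 == truth.ins1
        assert back.ins2 == truth.ins2
        assert back.deletions == truth.deletions
        assert back.liftover.wt_starts == truth.liftover.wt_starts
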
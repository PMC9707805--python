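"""Constrained MSAs, the alignment-tree hierarchy and feature transfer."""
import random

import pytest

from _oracles import nw_affine_score
from epvmine.alignment_tree import (
    AlignmentTree,
    GenomeFeature,
    StructuralError,
    build_constrained_msa,
    feature_coverage,
    inherit_features,
)


def _rand_nt(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(rng, seq, p_sub=0.05, p_indel=0.01):
    out = []
    for c in seq:
        r = rng.random()
        if r < p_indel / 2:
            continue  # deletion
        if r < p_indel:
            out.append(_rand_nt(rng, rng.randint(1, 4)))  # insertion
        out.append(rng.choice("ACGT") if rng.random() < p_sub else c)
    return "".join(out)


class TestBuildConstrainedMSA:
    def test_identical_member_is_single_full_block(self):
        msa = build_constrained_msa({"M": "ACGT" * 25, "B": "ACGT" * 25}, "M")
        aln = msa.members["B"][1]
        assert aln.blocks == [(0, 100, 0, 100)]
        assert aln.insertions == {}

    def test_middle_deletion_gives_two_blocks(self):
        master = "A" * 60 + "C" * 100 + "G" * 60
        member = "A" * 60 + "G" * 60
        msa = build_constrained_msa({"M": master, "B": member}, "M")
        blocks = msa.members["B"][1].blocks
        assert len(blocks) == 2
        unmapped = blocks[1][0] - blocks[0][1]
        assert unmapped == 100

    def test_score_matches_needleman_wunsch_oracle(self):
        rng = random.Random(4)
        for _ in range(15):
            a = _rand_nt(rng, rng.randint(40, 220))
            b = _mutate(rng, a, 0.1, 0.03)
            msa = build_constrained_msa({"M": a, "B": b}, "M")
            oracle = nw_affine_score(a, b, 2, -1, 4, 1)
            assert msa.members["B"][1].score == pytest.approx(oracle)

    def test_empty_member_rejected(self):
        with pytest.raises(ValueError):
            build_constrained_msa({"M": "ACGT", "B": ""}, "M")


class TestCoordinateMapping:
    def _tree(self, rng):
        root_master = _rand_nt(rng, 400)
        mid = _mutate(rng, root_master)
        leaf = _mutate(rng, mid)
        top = build_constrained_msa({"R": root_master, "mid": mid}, "R")
        bottom = build_constrained_msa({"mid": mid, "leaf": leaf}, "mid")
        t = AlignmentTree()
        t.add_node("n_root", top)
        t.add_node("n_mid", bottom)
        t.add_edge("n_root", "n_mid")
        return t, root_master, mid, leaf

    def test_identity_and_gap_mapping(self):
        master = "A" * 60 + "C" * 100 + "G" * 60
        member = "A" * 60 + "G" * 60
        msa = build_constrained_msa({"M": master, "B": member}, "M")
        t = AlignmentTree()
        t.add_node("n", msa)
        assert t.map_coordinates(42, "M", "M") == 42
        assert t.map_coordinates(110, "M", "B") is None  # deleted region

    def test_round_trip_is_identity_on_mappable_positions(self):
        rng = random.Random(8)
        t, root_master, mid, leaf = self._tree(rng)
        n_mapped = 0
        for p in range(len(leaf)):
            q = t.map_coordinates(p, "leaf", "R")
            if q is not None:
                n_mapped += 1
                assert t.map_coordinates(q, "R", "leaf") == p
        assert n_mapped > len(leaf) // 2

    def test_no_path_raises_structural_error(self):
        msa = build_constrained_msa({"M": "ACGTACGT", "B": "ACGTACGT"}, "M")
        t = AlignmentTree()
        t.add_node("n", msa)
        with pytest.raises(StructuralError):
            t.map_coordinates(0, "M", "unrelated")


class TestRecursiveExport:
    def test_single_node_exports_itself(self):
        rng = random.Random(2)
        a = _rand_nt(rng, 150)
        msa = build_constrained_msa({"M": a, "B": _mutate(rng, a)}, "M")
        t = AlignmentTree()
        t.add_node("n", msa)
        rows, _ = t.recursive_export("n")
        direct, _ = msa.flat_rows()
        assert rows == direct

    def test_zero_decay_two_level_matches_direct_alignment(self):
        seq = "ACGTTGCA" * 40
        top = build_constrained_msa({"R": seq, "mid": seq}, "R")
        bottom = build_constrained_msa({"mid": seq, "leaf": seq}, "mid")
        t = AlignmentTree()
        t.add_node("a", top)
        t.add_node("b", bottom)
        t.add_edge("a", "b")
        rows, dropped = t.recursive_export("a")
        assert rows["leaf"] == seq  # identical all the way up
        assert dropped == {}

    def test_taxon_count_equals_distinct_subtree_members(self):
        rng = random.Random(5)
        a = _rand_nt(rng, 200)
        t = AlignmentTree()
        t.add_node("a", build_constrained_msa(
            {"R": a, "m1": _mutate(rng, a), "m2": _mutate(rng, a)}, "R"))
        t.add_node("b", build_constrained_msa(
            {"m1": t.nodes["a"].members["m1"][0], "x": _mutate(rng, a)}, "m1"))
        t.add_edge("a", "b")
        rows, _ = t.recursive_export("a")
        assert set(rows) == {"R", "m1", "m2", "x"}

    def test_bad_edge_rejected(self):
        msa1 = build_constrained_msa({"M": "ACGTACGTAC", "B": "ACGTACGTAC"}, "M")
        msa2 = build_constrained_msa({"Z": "ACGTACGTAC", "Q": "ACGTACGTAC"}, "Z")
        t = AlignmentTree()
        t.add_node("a", msa1)
        t.add_node("b", msa2)
        with pytest.raises(StructuralError):
            t.add_edge("a", "b")


class TestFeatures:
    def test_identical_sequences_keep_coordinates(self):
        seq = "ACGT" * 50
        msa = build_constrained_msa({"M": seq, "B": seq}, "M")
        (out,) = inherit_features("M", "B", msa, [GenomeFeature("NS", 100, 160)])
        assert (out.start, out.end) == (100, 160)

    def test_upstream_deletion_shifts_feature(self):
        master = "ACGTTGCA" * 50  # 400 nt
        member = master[:30] + master[80:]  # 50 nt deleted upstream of feature
        msa = build_constrained_msa({"M": master, "B": member}, "M")
        (out,) = inherit_features("M", "B", msa, [GenomeFeature("NS", 100, 200)])
        assert (out.start, out.end) == (50, 150)

    def test_inherited_span_never_exceeds_source_span(self):
        rng = random.Random(12)
        master = _rand_nt(rng, 300)
        for rep in range(8):
            member = _mutate(rng, master, 0.05, 0.03)
            msa = build_constrained_msa({"M": master, "B": member}, "M")
            feats = [GenomeFeature("f", 40, 180), GenomeFeature("g", 200, 280)]
            for src, out in zip(feats, inherit_features("M", "B", msa, feats)):
                # insertions in the member may only be spanned, not counted:
                # the aligned positions inside the feature cannot exceed the
                # source feature length
                covered = sum(
                    1 for p in range(src.start, src.end)
                    if msa.map_pos("M", "B", p) is not None
                )
                assert covered <= src.end - src.start
                assert out.end > out.start

    def test_coverage_examples_and_monotonicity(self):
        master = "A" * 100 + "C" * 100
        full = master
        half = "A" * 100  # covers only first half of master
        msa = build_constrained_msa({"M": master, "F": full, "H": half}, "M")
        feat = GenomeFeature("f", 0, 200)
        assert feature_coverage(msa, "F", feat) == pytest.approx(1.0)
        assert feature_coverage(msa, "H", feat) == pytest.approx(0.5)
        sub = GenomeFeature("s", 0, 100)
        assert feature_coverage(msa, "H", sub) >= feature_coverage(msa, "H", feat)

    def test_feature_outside_master_rejected(self):
        msa = build_constrained_msa({"M": "ACGT" * 10, "B": "ACGT" * 10}, "M")
        with pytest.raises(ValueError):
            feature_coverage(msa, "B", GenomeFeature("f", 0, 999))
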
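"""Locus merging, ortholog clustering, consensus and nomenclature."""
import itertools
import random

import pytest

from _oracles import transitive_closure_partition
from epvmine.loci import (
    Locus,
    LocusParameterError,
    OrthologSet,
    assign_identifiers,
    assign_orthologs,
    build_consensus,
    merge_hits,
    species_abbreviation,
)
from epvmine.screening import Hit


def make_hit(start, end, contig="contig1", strand="+", bitscore=100.0, hid="h"):
    return Hit(
        species="Sp_x", contig=contig, start=start, end=end, strand=strand,
        frame=1, probe_accession="P", bitscore=bitscore, pct_identity=90.0,
        aligned_peptide="M" * 10, hit_id=hid,
    )


class TestMergeHits:
    def test_hits_within_gap_merge(self):
        hits = [make_hit(100, 400, hid="a"), make_hit(450, 800, hid="b")]
        loci = merge_hits(hits, max_gap=100)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100, 800)
        assert set(loci[0].member_hits) == {"a", "b"}

    def test_hits_beyond_gap_stay_separate(self):
        hits = [make_hit(100, 400, hid="a"), make_hit(450, 800, hid="b")]
        assert len(merge_hits(hits, max_gap=10)) == 2

    def test_merge_is_order_invariant(self):
        """Merging must equal the transitive closure regardless of order."""
        rng = random.Random(0)
        spans = sorted(
            (s, s + rng.randint(50, 300))
            for s in (rng.randint(0, 5000) for _ in range(8))
        )
        hits = [make_hit(s, e, hid=f"h{i}") for i, (s, e) in enumerate(spans)]
        matches = {
            (i, j)
            for i in range(len(spans))
            for j in range(i + 1, len(spans))
            if max(spans[i][0], spans[j][0]) - min(spans[i][1], spans[j][1]) <= 150
        }
        expected = {
            frozenset(f"h{i}" for i in grp)
            for grp in transitive_closure_partition(len(spans), matches)
        }
        for perm in itertools.islice(itertools.permutations(hits), 0, 24, 3):
            loci = merge_hits(list(perm), max_gap=150)
            got = {frozenset(l.member_hits) for l in loci}
            assert got == expected

    def test_negative_gap_rejected(self):
        with pytest.raises(LocusParameterError):
            merge_hits([make_hit(0, 10)], max_gap=-1)

    def test_locus_genus_from_best_hit_and_flanks_extracted(self):
        genome = {"contig1": "A" * 100 + "C" * 300 + "G" * 100}
        hits = [make_hit(100, 400, bitscore=80, hid="lo"),
                make_hit(150, 400, bitscore=120, hid="hi")]
        loci = merge_hits(hits, 50, genome=genome, flank_len=1000,
                          genus_of={"lo": "A", "hi": "B"})
        assert loci[0].assigned_genus == "B"
        assert loci[0].upstream_flank == "A" * 100
        assert loci[0].upstream_truncated and loci[0].downstream_truncated
        assert loci[0].sequence == "C" * 300


def _locus(species, up, down, genus="G", start=1000, seq="ACGT" * 100):
    return Locus(
        locus_id=f"{species}|contig1|{start}", species=species, contig="contig1",
        start=start, end=start + len(seq), strand="+", assigned_genus=genus,
        member_hits=[], upstream_flank=up, downstream_flank=down, sequence=seq,
    )


def _rand_nt(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestAssignOrthologs:
    def test_shared_flanks_cluster_unrelated_stay_apart(self):
        rng = random.Random(1)
        up, down = _rand_nt(rng, 500), _rand_nt(rng, 500)
        other_up, other_down = _rand_nt(rng, 500), _rand_nt(rng, 500)
        loci = [
            _locus("Sp_a", up, down),
            _locus("Sp_b", up, down),
            _locus("Sp_c", other_up, other_down),
        ]
        sets = assign_orthologs(loci, flank_len=500)
        parts = sorted(sorted(m.species for m in s.members) for s in sets)
        assert parts == [["Sp_a", "Sp_b"], ["Sp_c"]]

    def test_equals_transitive_closure_oracle(self):
        """Clustering = brute-force closure of the pairwise match matrix."""
        rng = random.Random(7)
        sites = [(_rand_nt(rng, 400), _rand_nt(rng, 400)) for _ in range(4)]
        loci = []
        for i, sp in enumerate(["Sp_a", "Sp_b", "Sp_c", "Sp_d", "Sp_e", "Sp_f"]):
            up, down = sites[i % 4]
            loci.append(_locus(sp, up, down, start=1000 + i))
        matches = set()
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                if (loci[i].upstream_flank == loci[j].upstream_flank
                        and loci[i].downstream_flank == loci[j].downstream_flank):
                    matches.add((i, j))
        expected = {
            frozenset(loci[i].locus_id for i in grp)
            for grp in transitive_closure_partition(len(loci), matches)
        }
        got = {
            frozenset(m.locus_id for m in s.members)
            for s in assign_orthologs(loci, flank_len=400)
        }
        assert got == expected

    def test_paralog_guard_keeps_same_species_apart(self):
        rng = random.Random(3)
        up, down = _rand_nt(rng, 400), _rand_nt(rng, 400)
        loci = [
            _locus("Sp_a", up, down, start=1000),
            _locus("Sp_a", up, down, start=9000),
            _locus("Sp_b", up, down, start=1000),
        ]
        sets = assign_orthologs(loci, flank_len=400)
        for s in sets:
            species = [m.species for m in s.members]
            assert len(species) == len(set(species))

    def test_cross_genus_never_clusters(self):
        rng = random.Random(5)
        up, down = _rand_nt(rng, 400), _rand_nt(rng, 400)
        loci = [_locus("Sp_a", up, down, genus="G1"),
                _locus("Sp_b", up, down, genus="G2")]
        assert len(assign_orthologs(loci, flank_len=400)) == 2

    def test_bad_flank_len_rejected(self):
        with pytest.raises(LocusParameterError):
            assign_orthologs([], flank_len=0)


class TestConsensus:
    def test_majority_wins(self):
        assert build_consensus(["ACGA", "ACGA", "ACGT"]) == "ACGA"

    def test_tie_renders_iupac_code(self):
        assert build_consensus(["A", "G"]) == "R"

    def test_single_member_is_its_own_consensus(self):
        assert build_consensus(["ACGTACGT"]) == "ACGTACGT"

    def test_majority_gap_column_omitted(self):
        assert build_consensus(["A-C", "A-C", "AGC"]) == "AC"

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestNomenclature:
    def test_known_species_abbreviations(self):
        assert species_abbreviation("Monodelphis domestica") == "MonDom"
        assert species_abbreviation("Mus spicelagus") == "MusSpi"

    def test_short_parts_used_whole(self):
        assert species_abbreviation("Bo vu") == "BoVu"

    def test_malformed_binomial_rejected(self):
        with pytest.raises(ValueError):
            species_abbreviation("Homo")

    def test_multi_species_set_named_for_shared_host_group(self):
        members = [
            _locus("Thamnophis_elegans", "A", "C"),
            _locus("Ptyas_mucosa", "A", "C", start=1001),
        ]
        s = OrthologSet(epv_id="", members=members, group="Amdoparvovirus")
        taxonomy = {
            "Thamnophis_elegans": ["Serpentes", "Sauria", "Vertebrata"],
            "Ptyas_mucosa": ["Serpentes", "Sauria", "Vertebrata"],
        }
        out = assign_identifiers([s], taxonomy, number_blocks={"Amdo": 101})
        assert out[0].epv_id == "EPV-Amdo.101-Serpentes"

    def test_single_species_set_named_by_abbreviation(self):
        s = OrthologSet(
            epv_id="",
            members=[_locus("Mus_spicelagus", "A", "C")],
            group="Protoparvovirus",
        )
        out = assign_identifiers([s], {"Mus_spicelagus": ["Rodentia"]},
                                 number_blocks={"Proto": 4})
        assert out[0].epv_id == "EPV-Proto.4-MusSpi"

    def test_identifier_assignment_deterministic_and_injective(self):
        taxonomy = {"Sp_a": ["G1"], "Sp_b": ["G1"], "Sp_c": ["G1"]}
        sets = [
            OrthologSet("", [_locus("Sp_a", "A", "C")], group="Protoparvovirus"),
            OrthologSet("", [_locus("Sp_b", "A", "C")], group="Protoparvovirus"),
            OrthologSet("", [_locus("Sp_c", "A", "C")], group="Amdoparvovirus"),
        ]
        one = [s.epv_id for s in assign_identifiers(sets, taxonomy)]
        two = [s.epv_id for s in assign_identifiers(sets, taxonomy)]
        assert one == two
        assert len(set(one)) == len(one)
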
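"""The synthetic study system: trees, libraries, decay, planted events."""
import math

import numpy as np
import pytest

from epvmine.ages import mrca_age
from epvmine.simulate import (
    DecayParams,
    InvalidSpecError,
    SimEvent,
    TimeTreeSpec,
    UnknownBranchError,
    decay_sequence,
    simulate_host_genomes,
    simulate_reference_library,
    simulate_species_tree,
)


def jc_expected_diff(rate: float, t: float) -> float:
    """Observed difference fraction after rate*t expected subs/site."""
    return 0.75 * (1.0 - math.exp(-4.0 / 3.0 * rate * t))


class TestSpeciesTree:
    def test_two_species_tree_is_a_cherry_at_crown_age(self):
        t = simulate_species_tree(TimeTreeSpec(2, 100.0, seed=0))
        assert len(t.leaf_names) == 2
        assert mrca_age(t, t.leaf_names) == pytest.approx(100.0)

    def test_same_seed_reproduces_newick(self):
        spec = TimeTreeSpec(9, 55.0, seed=123)
        assert simulate_species_tree(spec).newick() == simulate_species_tree(spec).newick()

    def test_tree_is_ultrametric_at_crown_age(self):
        t = simulate_species_tree(TimeTreeSpec(20, 100.0, seed=5))
        d = t.dendropy_tree
        depths = d.calc_node_root_distances(return_leaf_distances_only=True)
        assert max(depths) - min(depths) < 1e-9
        assert t.root_age == pytest.approx(100.0)

    def test_too_few_species_rejected(self):
        with pytest.raises(InvalidSpecError):
            TimeTreeSpec(1, 100.0, seed=0)


class TestReferenceLibrary:
    def test_minimal_library_has_one_record_two_probes(self):
        lib = simulate_reference_library(1, 1, rep_len=60, vp_len=50, seed=0)
        assert len(lib.records) == 2  # one Rep + one VP probe
        assert len(lib.genomes) == 1

    def test_probe_lengths_match_request(self):
        lib = simulate_reference_library(2, 2, rep_len=300, vp_len=120, seed=0)
        for r in lib.records:
            if r.gene == "Rep/NS":
                assert len(r.peptide) == 300
            else:
                assert len(r.peptide) == 120

    def test_within_genus_identity_exceeds_between(self):
        lib = simulate_reference_library(2, 3, rep_len=200, vp_len=150, seed=1)
        reps = [(r.genus, r.peptide) for r in lib.records if r.gene == "Rep/NS"]

        def ident(a, b):
            return sum(x == y for x, y in zip(a, b)) / len(a)

        within, between = [], []
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                val = ident(reps[i][1], reps[j][1])
                (within if reps[i][0] == reps[j][0] else between).append(val)
        assert np.mean(within) > np.mean(between)


class TestDecay:
    def test_zero_duration_is_identity(self):
        seq = "ACGT" * 100
        assert decay_sequence(seq, 0.0, DecayParams(seed=1)) == seq

    def test_zero_rates_are_identity(self):
        seq = "ACGT" * 100
        params = DecayParams(sub_rate=0.0, indel_rate=0.0, seed=1)
        assert decay_sequence(seq, 500.0, params) == seq

    def test_negative_duration_rejected(self):
        with pytest.raises(InvalidSpecError):
            decay_sequence("ACGT", -1.0, DecayParams(seed=0))

    def test_substitution_fraction_matches_jukes_cantor(self):
        """Mean observed difference over replicates within 3 SD of JC."""
        L, rate, t = 10000, 1e-3, 100.0
        seq = "".join("ACGT"[i] for i in np.random.default_rng(0).integers(0, 4, L))
        diffs = []
        for rep in range(30):
            params = DecayParams(sub_rate=rate, indel_rate=0.0, seed=rep)
            out = decay_sequence(seq, t, params)
            diffs.append(sum(a != b for a, b in zip(seq, out)) / L)
        p = jc_expected_diff(rate, t)
        sd_mean = math.sqrt(p * (1 - p) / L) / math.sqrt(len(diffs))
        assert abs(np.mean(diffs) - p) < 3 * sd_mean


class TestHostGenomes:
    def test_zero_events_leaves_clean_genomes(self, default_tree, default_library):
        genomes, truth = simulate_host_genomes(
            default_tree, library=default_library, n_events=0, seed=3
        )
        assert truth.events == [] and truth.true_spans == {}
        frag = next(iter(default_library.genomes.values()))[200:400]
        for contigs in genomes.values():
            for seq in contigs.values():
                assert frag not in seq

    def test_zero_decay_insertion_identical_in_carriers(self, default_tree, default_library):
        zero = DecayParams(sub_rate=0.0, indel_rate=0.0, seed=0)
        genomes, truth = simulate_host_genomes(
            default_tree, library=default_library, n_events=5,
            host_decay=zero, epv_decay=zero, seed=4,
        )
        for e in truth.events:
            frag = default_library.genomes[e.source_accession][
                e.fragment[0]: e.fragment[1]
            ]
            carriers = truth.carriers[e.event_id]
            assert carriers == default_tree.leaves_below(e.branch[1])
            for sp in carriers:
                contig, s, t = truth.true_spans[(e.event_id, sp)]
                assert genomes[sp][contig][s:t] == frag

    def test_epv_divergence_from_source_matches_jc(self, default_tree, default_library):
        """EPV-vs-source divergence tracks JC for t = event age; two
        carrier copies diverge at twice that rate."""
        # force one event on a branch whose child is ~50 My old
        target = None
        for parent, child, _ in default_tree.edges():
            age = default_tree.node_age(child)
            if 35.0 <= age <= 60.0 and len(default_tree.leaves_below(child)) >= 2:
                target = (parent, child)
                break
        assert target is not None
        age = default_tree.node_age(target[1])
        acc = sorted(default_library.genomes)[0]
        ev = SimEvent("ev0", target, acc, (120, 1020), "contig1", 5000)
        diffs_src = []
        rate = 2e-3
        for rep in range(8):
            genomes, truth = simulate_host_genomes(
                default_tree,
                library=default_library,
                events=[SimEvent("ev0", target, acc, (120, 1020), "contig1", 5000)],
                host_decay=DecayParams(sub_rate=rate, indel_rate=0.0, seed=rep),
                epv_decay=DecayParams(sub_rate=rate, indel_rate=0.0, seed=rep + 100),
                seed=rep,
            )
            frag = default_library.genomes[acc][120:1020]
            sp = sorted(truth.carriers["ev0"])[0]
            contig, s, t = truth.true_spans[("ev0", sp)]
            copy = genomes[sp][contig][s:t]
            diffs_src.append(sum(a != b for a, b in zip(frag, copy)) / len(frag))
        p = jc_expected_diff(rate, age)
        sd = math.sqrt(p * (1 - p) / 900) / math.sqrt(len(diffs_src))
        assert abs(np.mean(diffs_src) - p) < 4 * sd

    def test_carriers_and_min_age_consistent_with_tree(self, default_sim, default_tree):
        _, truth = default_sim
        for e in truth.events:
            carriers = truth.carriers[e.event_id]
            assert carriers == default_tree.leaves_below(e.branch[1])
            if len(carriers) >= 2:
                assert truth.true_min_age[e.event_id] == pytest.approx(
                    mrca_age(default_tree, carriers)
                )

    def test_simulation_is_deterministic(self, default_tree, default_library):
        a = simulate_host_genomes(default_tree, library=default_library, seed=11)
        b = simulate_host_genomes(default_tree, library=default_library, seed=11)
        assert a[0] == b[0]
        assert a[1].to_json() == b[1].to_json()

    def test_unknown_branch_rejected(self, default_tree, default_library):
        acc = sorted(default_library.genomes)[0]
        bad = SimEvent("evX", ("nope", "nada"), acc, (120, 1020), "contig1", 5000)
        with pytest.raises(UnknownBranchError):
            simulate_host_genomes(
                default_tree, library=default_library, events=[bad], seed=0
            )

    def test_ground_truth_round_trips_json(self, default_sim):
        from epvmine.simulate import GroundTruth

        _, truth = default_sim
        again = GroundTruth.from_json(truth.to_json())
        assert again.carriers == truth.carriers
        assert again.true_min_age == truth.true_min_age
        assert again.true_spans == truth.true_spans
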
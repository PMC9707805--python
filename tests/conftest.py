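"""Shared fixtures: one default simulated study system per session.

The default study conditions — 20 species, 100 My crown, 10 planted
incorporation events, default decay — are simulated once and the full
iterative screen run once; recovery-style tests all read from these.
"""
from __future__ import annotations

import pytest

from epvmine.ages import calibrate_ortholog_ages
from epvmine.loci import iterate_screen
from epvmine.simulate import (
    TimeTreeSpec,
    simulate_host_genomes,
    simulate_reference_library,
    simulate_species_tree,
)

DEFAULT_TREE_SEED = 7
DEFAULT_LIB_SEED = 1
DEFAULT_SIM_SEED = 11


@pytest.fixture(scope="session")
def default_tree():
    return simulate_species_tree(TimeTreeSpec(20, 100.0, seed=DEFAULT_TREE_SEED))


@pytest.fixture(scope="session")
def default_library():
    return simulate_reference_library(3, 2, seed=DEFAULT_LIB_SEED)


@pytest.fixture(scope="session")
def default_sim(default_tree, default_library):
    genomes, truth = simulate_host_genomes(
        default_tree, library=default_library, seed=DEFAULT_SIM_SEED
    )
    return genomes, truth


@pytest.fixture(scope="session")
def default_catalogue(default_sim, default_tree, default_library):
    genomes, _ = default_sim
    return iterate_screen(
        genomes, default_library, host_taxonomy=default_tree.taxonomy_map()
    )


@pytest.fixture(scope="session")
def default_calibrations(default_catalogue, default_tree):
    return calibrate_ortholog_ages(default_catalogue, default_tree)


def span_overlaps_locus(locus, span) -> bool:
    contig, s, e = span
    return locus.contig == contig and min(locus.end, e) - max(locus.start, s) > 0
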
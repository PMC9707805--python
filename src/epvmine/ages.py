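"""Time-calibrated host trees and ortholog-based minimum-age calibration.

An insertion shared by several host species at homologous genomic
positions must predate their last common ancestor, so the crown age of
the carrier clade on a time-calibrated (ultrametric) species tree is a
minimum age for the incorporation event; the stem age (the parent of the
MRCA) bounds it from above under presence/absence parsimony.  A
neighbour-joining/Robinson-Foulds diagnostic checks that ortholog
alignments branch like the host species do.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
from dendropy.calculate import treecompare


class TreeValidationError(ValueError):
    """Tree fails ultrametricity or branch-length requirements."""


class UnknownTaxonError(KeyError):
    """A requested species is not a leaf of the tree."""


class SingleCarrierError(ValueError):
    """MRCA-based ages are undefined for fewer than two carriers."""


class TimeTree:
    """An ultrametric, rooted species tree with node ages in My.

    Leaves are species (age 0); internal-node ages are read off
    root-to-tip distances.  Internal nodes carry stable labels
    (``node1``, ``node2``, ... in preorder) so that tree edges can be
    referred to by their child node.
    """

    def __init__(self, tree: dendropy.Tree, tolerance: float = 1e-6):
        tree.is_rooted = True
        self._tree = tree
        self._tolerance = tolerance
        self._label_nodes()
        self._compute_ages()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, tolerance: float = 1e-6) -> "TimeTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise TreeValidationError("newick tree is missing branch lengths")
        return cls(tree, tolerance=tolerance)

    def _label_nodes(self) -> None:
        i = 0
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                nd.label = nd.taxon.label if nd.taxon else nd.label
            elif not nd.label:
                i += 1
                nd.label = f"node{i}"

    def _compute_ages(self) -> None:
        depths: Dict[dendropy.Node, float] = {}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
        leaf_depths = [depths[nd] for nd in self._tree.leaf_node_iter()]
        dmax = max(leaf_depths)
        tol = self._tolerance * max(1.0, dmax)
        if dmax - min(leaf_depths) > tol:
            raise TreeValidationError(
                f"tree is not ultrametric: leaf depth spread "
                f"{dmax - min(leaf_depths):.3g} exceeds tolerance {tol:.3g}"
            )
        self._ages: Dict[str, float] = {}
        for nd, d in depths.items():
            age = dmax - d
            if nd.is_leaf():
                age = 0.0
            nd.age = age
            self._ages[nd.label] = age
        self._root_age = dmax

    # -- basic queries -----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root_age(self) -> float:
        return self._root_age

    @property
    def leaf_names(self) -> List[str]:
        return [nd.taxon.label for nd in self._tree.leaf_node_iter()]

    def node_age(self, label: str) -> float:
        return self._ages[label]

    def edges(self) -> List[Tuple[str, str, float]]:
        """All (parent_label, child_label, branch_length) edges."""
        out = []
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is not None:
                out.append((nd.parent_node.label, nd.label, nd.edge.length or 0.0))
        return out

    def leaves_below(self, label: str) -> FrozenSet[str]:
        for nd in self._tree.preorder_node_iter():
            if nd.label == label:
                return frozenset(l.taxon.label for l in nd.leaf_iter())
        raise UnknownTaxonError(label)

    def taxonomy_map(self) -> Dict[str, List[str]]:
        """Species -> ordered ancestor labels (immediate parent first)."""
        out: Dict[str, List[str]] = {}
        for leaf in self._tree.leaf_node_iter():
            labels = []
            nd = leaf.parent_node
            while nd is not None:
                labels.append(nd.label)
                nd = nd.parent_node
            out[leaf.taxon.label] = labels
        return out

    def _mrca_node(self, taxa: Iterable[str]) -> dendropy.Node:
        taxa = list(taxa)
        known = set(self.leaf_names)
        for t in taxa:
            if t not in known:
                raise UnknownTaxonError(t)
        if len(set(taxa)) < 2:
            raise SingleCarrierError(
                "ortholog-based ages need at least two carrier species"
            )
        node = self._tree.mrca(taxon_labels=taxa)
        if node is None:  # pragma: no cover - defensive
            raise UnknownTaxonError(str(taxa))
        return node

    def newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def pruned_to(self, taxa: Iterable[str]) -> "TimeTree":
        clone = self._tree.extract_tree_with_taxa_labels(list(taxa))
        clone.purge_taxon_namespace()
        return TimeTree(clone, tolerance=self._tolerance)


def parse_time_tree(newick: str, tolerance: float = 1e-6) -> TimeTree:
    """Parse a Newick string with branch lengths in My and validate it."""
    return TimeTree.from_newick(newick, tolerance=tolerance)


def mrca_age(tree: TimeTree, taxa: Iterable[str]) -> float:
    """Age (My) of the most recent common ancestor of ``taxa``."""
    return tree._mrca_node(taxa).age


def stem_age(tree: TimeTree, taxa: Iterable[str]) -> float:
    """Age (My) of the parent of the MRCA of ``taxa``.

    If the MRCA is the root, the root age is returned (callers can flag
    this via :func:`stem_is_root`).
    """
    node = tree._mrca_node(taxa)
    if node.parent_node is None:
        return tree.root_age
    return node.parent_node.age


def stem_is_root(tree: TimeTree, taxa: Iterable[str]) -> bool:
    return tree._mrca_node(taxa).parent_node is None


@dataclass(frozen=True)
class AgeCalibration:
    """Ortholog-based bounds for one incorporation event.

    ``min_age`` is the carrier crown age (lower bound); ``upper_bound``
    is the stem age, flagged when the MRCA is already the tree root.
    Single-carrier loci carry no numeric age.
    """

    epv_id: str
    carrier_species: FrozenSet[str]
    min_age: Optional[float]
    upper_bound: Optional[float]
    at_root: bool = False
    single_carrier: bool = False


def calibrate_ortholog_ages(catalogue, tree: TimeTree) -> List[AgeCalibration]:
    """One age calibration per ortholog set in the catalogue.

    ``catalogue`` is anything with an ``ortholog_sets`` attribute or an
    iterable of ortholog sets.  Raises :class:`UnknownTaxonError` naming
    the species if a carrier is absent from the tree.
    """
    sets = getattr(catalogue, "ortholog_sets", catalogue)
    out: List[AgeCalibration] = []
    for s in sets:
        carriers = frozenset(m.species for m in s.members)
        if len(carriers) < 2:
            out.append(
                AgeCalibration(
                    epv_id=s.epv_id,
                    carrier_species=carriers,
                    min_age=None,
                    upper_bound=None,
                    single_carrier=True,
                )
            )
            continue
        crown = mrca_age(tree, carriers)
        stem = stem_age(tree, carriers)
        out.append(
            AgeCalibration(
                epv_id=s.epv_id,
                carrier_species=carriers,
                min_age=crown,
                upper_bound=stem,
                at_root=stem_is_root(tree, carriers),
            )
        )
    return out


# ---------------------------------------------------------------------------
# host-tree congruence of ortholog alignments
# ---------------------------------------------------------------------------


def _p_distance(a: str, b: str) -> float:
    same = 0
    comp = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            comp += 1
            if x == y:
                same += 1
    if comp == 0:
        return 1.0
    return 1.0 - same / comp


def _skbio_to_dendropy(node, tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(sk_node, d_node):
        for child in sk_node.children:
            c = dendropy.Node()
            c.edge.length = child.length
            d_node.add_child(c)
            if child.is_tip():
                c.taxon = tns.require_taxon(label=str(child.name))
            else:
                build(child, c)

    build(node, tree.seed_node)
    return tree


def congruence_check(member_rows: Mapping[str, str], tree: TimeTree) -> Dict[str, object]:
    """Do ortholog sequences branch like the host species?

    Builds a neighbour-joining tree from p-distances between aligned
    members (rows of a flat MSA keyed by species), prunes the species
    tree to the carriers, and reports the unrooted Robinson-Foulds
    distance; congruent means RF == 0.  With fewer than four members the
    check is not applicable (RF is uninformative) and no error is raised.
    """
    species = sorted(member_rows)
    if len(species) < 4:
        return {"rf_distance": None, "congruent": None, "applicable": False}
    import numpy as np
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = len(species)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _p_distance(member_rows[species[i]], member_rows[species[j]])
            dm[i, j] = dm[j, i] = d
    nj_tree = nj(DistanceMatrix(dm, ids=species))

    tns = dendropy.TaxonNamespace()
    d_nj = _skbio_to_dendropy(nj_tree, tns)
    pruned = tree.pruned_to(species)
    d_sp = dendropy.Tree.get(
        data=pruned.newick(),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )
    d_nj.is_rooted = False
    d_sp.is_rooted = False
    d_nj.encode_bipartitions()
    d_sp.encode_bipartitions()
    rf = int(treecompare.symmetric_difference(d_nj, d_sp))
    return {"rf_distance": rf, "congruent": rf == 0, "applicable": True}
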
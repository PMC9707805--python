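"""Reference-constrained alignments and the alignment-tree hierarchy.

A constrained MSA fixes its column space to a chosen master reference:
every member is pairwise-aligned to the master, and member-vs-member
homology is defined only through shared master coordinates.  Constrained
MSAs are linked into a tree through shared references (each child's
master is a member of its parent), which supports recursive export of
whole subtrees into one coordinate space, coordinate lift-over between
any two references, inheritance of genome-feature annotations, and
per-member feature-coverage reporting.

Member insertions relative to an export master cannot be represented in
a flat MSA without inflating the master coordinates; they are dropped
from flat exports and preserved in a sidecar structure.
"""
from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import Align

# nucleotide scoring: match 2, mismatch -1, gap of length L costs 4 + L
NT_SCORES = {"match": 2, "mismatch": -1, "gap_open": 4, "gap_extend": 1}
# peptide scoring: BLOSUM62 with gap of length L costing 11 + L
AA_GAP = {"gap_open": 11, "gap_extend": 1}


class StructuralError(ValueError):
    """Alignment-tree structure is broken (missing shared reference, cycle)."""


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if mode == "nt":
        aligner.match_score = NT_SCORES["match"]
        aligner.mismatch_score = NT_SCORES["mismatch"]
        aligner.open_gap_score = -(NT_SCORES["gap_open"] + NT_SCORES["gap_extend"])
        aligner.extend_gap_score = -NT_SCORES["gap_extend"]
    else:
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(AA_GAP["gap_open"] + AA_GAP["gap_extend"])
        aligner.extend_gap_score = -AA_GAP["gap_extend"]
    return aligner


def global_alignment_score(a: str, b: str, mode: str = "nt") -> float:
    """Needleman-Wunsch score under the module's scoring scheme."""
    return float(_make_aligner(mode).score(a, b))


@dataclass(frozen=True)
class GenomeFeature:
    """A named feature on a reference sequence (0-based half-open, + strand)."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature span for {self.name}")


@dataclass
class MemberAlignment:
    """Pairwise alignment of one member to the master, as ordered blocks.

    ``blocks`` are (ref_start, ref_end, member_start, member_end)
    aligned runs, strictly increasing in both coordinates;
    ``insertions`` keys member-only runs to the master position they
    precede.
    """

    member_id: str
    length: int
    blocks: List[Tuple[int, int, int, int]]
    insertions: Dict[int, str] = field(default_factory=dict)
    score: float = 0.0

    def member_to_ref(self, pos: int) -> Optional[int]:
        i = bisect.bisect_right([b[2] for b in self.blocks], pos) - 1
        if i >= 0:
            rs, re, ms, me = self.blocks[i]
            if ms <= pos < me:
                return rs + (pos - ms)
        return None

    def ref_to_member(self, pos: int) -> Optional[int]:
        i = bisect.bisect_right([b[0] for b in self.blocks], pos) - 1
        if i >= 0:
            rs, re, ms, me = self.blocks[i]
            if rs <= pos < re:
                return ms + (pos - rs)
        return None


@dataclass
class ConstrainedMSA:
    """An MSA whose coordinate space is a master reference sequence."""

    master_ref: str
    master_seq: str
    members: Dict[str, Tuple[str, MemberAlignment]] = field(default_factory=dict)
    mode: str = "nt"

    def ids(self) -> List[str]:
        return [self.master_ref] + sorted(self.members)

    def member_seq(self, member_id: str) -> str:
        if member_id == self.master_ref:
            return self.master_seq
        return self.members[member_id][0]

    def map_pos(self, from_id: str, to_id: str, pos: int) -> Optional[int]:
        """Map a position between any two sequences of this MSA.

        Member-to-member mappings are composed through the master;
        unaligned positions map to None.
        """
        if from_id == to_id:
            if not (0 <= pos < len(self.member_seq(from_id))):
                raise IndexError(pos)
            return pos
        if from_id == self.master_ref:
            ref_pos: Optional[int] = pos
        else:
            ref_pos = self.members[from_id][1].member_to_ref(pos)
        if ref_pos is None:
            return None
        if to_id == self.master_ref:
            return ref_pos
        return self.members[to_id][1].ref_to_member(ref_pos)

    def flat_rows(self) -> Tuple[Dict[str, str], Dict[str, List[Tuple[int, str]]]]:
        """Flatten to rows over master coordinates.

        Returns (rows, dropped): rows maps each id to a string of
        length len(master); dropped records member insertions relative
        to the master, keyed by member id as (master_pos, inserted_seq).
        """
        n = len(self.master_seq)
        rows = {self.master_ref: self.master_seq}
        dropped: Dict[str, List[Tuple[int, str]]] = {}
        for mid in sorted(self.members):
            seq, aln = self.members[mid]
            row = ["-"] * n
            for rs, re, ms, me in aln.blocks:
                row[rs:re] = seq[ms:me]
            rows[mid] = "".join(row)
            if aln.insertions:
                dropped[mid] = sorted(aln.insertions.items())
        return rows, dropped


def _blocks_from_biopython(alignment) -> Tuple[List[Tuple[int, int, int, int]], Dict[int, str]]:
    ref_blocks, mem_blocks = alignment.aligned
    blocks = []
    insertions: Dict[int, str] = {}
    query = alignment.sequences[1]
    prev_me = 0
    prev_re = 0
    for (rs, re), (ms, me) in zip(ref_blocks, mem_blocks):
        if ms > prev_me:  # member-only run precedes this block
            ins = str(query[prev_me:ms])
            insertions[prev_re] = insertions.get(prev_re, "") + ins
        blocks.append((int(rs), int(re), int(ms), int(me)))
        prev_me = int(me)
        prev_re = int(re)
    if prev_me < len(query):
        insertions[prev_re] = insertions.get(prev_re, "") + str(query[prev_me:])
    return blocks, insertions


def build_constrained_msa(
    members: Mapping[str, str],
    master_ref: str,
    master_seq: Optional[str] = None,
    mode: str = "nt",
) -> ConstrainedMSA:
    """Align every member globally to the master reference.

    ``members`` maps id -> sequence; the master may be included there or
    supplied separately.  Nucleotide scoring is match 2 / mismatch -1 /
    gap 4 + L; peptide mode uses BLOSUM62 with gap 11 + L.
    """
    if master_seq is None:
        if master_ref not in members:
            raise ValueError("master_ref not found among members")
        master_seq = members[master_ref]
    if not master_seq:
        raise ValueError("empty master sequence")
    aligner = _make_aligner(mode)
    msa = ConstrainedMSA(master_ref=master_ref, master_seq=master_seq, mode=mode)
    for mid in sorted(members):
        if mid == master_ref:
            continue
        seq = members[mid]
        if not seq:
            raise ValueError(f"empty member sequence: {mid}")
        aln = aligner.align(master_seq, seq)[0]
        blocks, insertions = _blocks_from_biopython(aln)
        msa.members[mid] = (
            seq,
            MemberAlignment(
                member_id=mid,
                length=len(seq),
                blocks=blocks,
                insertions=insertions,
                score=float(aln.score),
            ),
        )
    return msa


@dataclass
class AlignmentTree:
    """Constrained MSAs hierarchically linked through shared references."""

    nodes: Dict[str, ConstrainedMSA] = field(default_factory=dict)
    edges: List[Tuple[str, str]] = field(default_factory=list)  # (parent, child)

    def add_node(self, node_id: str, msa: ConstrainedMSA) -> None:
        self.nodes[node_id] = msa

    def add_edge(self, parent: str, child: str) -> None:
        p = self.nodes[parent]
        c = self.nodes[child]
        if c.master_ref not in p.members and c.master_ref != p.master_ref:
            raise StructuralError(
                f"child master {c.master_ref!r} is not a member of node {parent!r}"
            )
        self.edges.append((parent, child))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        children: Dict[str, List[str]] = {}
        indeg = {n: 0 for n in self.nodes}
        for p, c in self.edges:
            children.setdefault(p, []).append(c)
            indeg[c] += 1
        roots = [n for n, d in indeg.items() if d == 0]
        seen = set()
        stack = list(roots)
        while stack:
            n = stack.pop()
            if n in seen:
                raise StructuralError("alignment tree contains a cycle")
            seen.add(n)
            stack.extend(children.get(n, []))
        if len(seen) != len(self.nodes):
            raise StructuralError("alignment tree contains a cycle")

    def children_of(self, node_id: str) -> List[str]:
        return [c for p, c in self.edges if p == node_id]

    # -- recursive export --------------------------------------------------

    def recursive_export(
        self, node_id: str
    ) -> Tuple[Dict[str, str], Dict[str, List[Tuple[int, str]]]]:
        """Flatten a whole subtree into the node master's coordinates.

        Each taxon of every descendant MSA is re-expressed by composing
        member -> child-master -> ... -> node-master maps.  Insertions
        relative to the export master are dropped and reported in the
        sidecar.
        """
        if node_id not in self.nodes:
            raise StructuralError(f"unknown alignment-tree node: {node_id}")
        msa = self.nodes[node_id]
        rows, dropped = msa.flat_rows()
        for child_id in self.children_of(node_id):
            child = self.nodes[child_id]
            shared = child.master_ref
            if shared != msa.master_ref and shared not in msa.members:
                raise StructuralError(
                    f"shared reference {shared!r} missing from node {node_id!r}"
                )
            child_rows, child_dropped = self.recursive_export(child_id)
            n = len(msa.master_seq)
            for taxon, crow in child_rows.items():
                if taxon in rows:
                    continue
                row = ["-"] * n
                for i in range(n):
                    j = msa.map_pos_within(shared, i)
                    if j is not None and crow[j] != "-":
                        row[i] = crow[j]
                rows[taxon] = "".join(row)
            for taxon, ins in child_dropped.items():
                dropped.setdefault(taxon, []).extend(ins)
        return rows, dropped

    # -- cross-reference coordinate mapping --------------------------------

    def _ref_graph(self) -> Dict[str, List[Tuple[str, ConstrainedMSA]]]:
        graph: Dict[str, List[Tuple[str, ConstrainedMSA]]] = {}
        for msa in self.nodes.values():
            ids = msa.ids()
            for a in ids:
                for b in ids:
                    if a != b:
                        graph.setdefault(a, []).append((b, msa))
        return graph

    def map_coordinates(self, pos: int, from_ref: str, to_ref: str) -> Optional[int]:
        """Lift a position between any two references in the hierarchy.

        Composes block lookups along the (unique) path of shared
        references; positions falling into unaligned gaps yield None.
        """
        if from_ref == to_ref:
            return pos
        graph = self._ref_graph()
        if from_ref not in graph or to_ref not in graph:
            raise StructuralError(f"no path between {from_ref!r} and {to_ref!r}")
        # BFS over reference ids
        prev: Dict[str, Tuple[str, ConstrainedMSA]] = {}
        queue = [from_ref]
        seen = {from_ref}
        while queue:
            cur = queue.pop(0)
            if cur == to_ref:
                break
            for nxt, msa in graph.get(cur, []):
                if nxt not in seen:
                    seen.add(nxt)
                    prev[nxt] = (cur, msa)
                    queue.append(nxt)
        if to_ref not in prev and from_ref != to_ref:
            raise StructuralError(f"no path between {from_ref!r} and {to_ref!r}")
        path = [to_ref]
        while path[-1] != from_ref:
            path.append(prev[path[-1]][0])
        path.reverse()
        cur_pos: Optional[int] = pos
        for a, b in zip(path, path[1:]):
            msa = prev[b][1]
            cur_pos = msa.map_pos(a, b, cur_pos)
            if cur_pos is None:
                return None
        return cur_pos


# convenience: MSA-level position map used by recursive_export
def _msa_map_pos_within(self: ConstrainedMSA, shared: str, i: int) -> Optional[int]:
    if shared == self.master_ref:
        return i
    return self.members[shared][1].ref_to_member(i)


ConstrainedMSA.map_pos_within = _msa_map_pos_within  # type: ignore[attr-defined]


def inherit_features(
    source_ref: str,
    target_ref: str,
    msa: ConstrainedMSA,
    features: Sequence[GenomeFeature],
) -> List[GenomeFeature]:
    """Project feature annotations from one sequence of an MSA to another.

    Feature endpoints falling in alignment gaps are moved inward to the
    nearest aligned position (conservative spans); features with no
    aligned position at all are dropped with a warning.
    """
    for rid in (source_ref, target_ref):
        if rid != msa.master_ref and rid not in msa.members:
            raise KeyError(f"reference {rid!r} not in MSA")
    out: List[GenomeFeature] = []
    for f in features:
        if f.end > len(msa.member_seq(source_ref)):
            raise ValueError(f"feature {f.name} outside {source_ref}")
        mapped = [
            (p, msa.map_pos(source_ref, target_ref, p))
            for p in range(f.start, f.end)
        ]
        aligned = [(p, q) for p, q in mapped if q is not None]
        if not aligned:
            warnings.warn(f"feature {f.name} is wholly unaligned on {target_ref}")
            continue
        out.append(GenomeFeature(name=f.name, start=aligned[0][1], end=aligned[-1][1] + 1))
    return out


def feature_coverage(msa: ConstrainedMSA, member: str, feature: GenomeFeature) -> float:
    """Fraction of a master feature's positions aligned by a member."""
    if feature.end > len(msa.master_seq):
        raise ValueError(f"feature {feature.name} outside master reference")
    if member == msa.master_ref:
        return 1.0
    aln = msa.members[member][1]
    covered = sum(1 for p in range(feature.start, feature.end)
                  if aln.ref_to_member(p) is not None)
    return covered / (feature.end - feature.start)
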
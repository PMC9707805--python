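"""Locus consolidation, ortholog resolution, consensus and nomenclature.

Raw similarity hits are merged per genome into loci; loci are resolved
across species into ortholog sets — groups descending from the same
germline incorporation event, recognised by matching genomic flanking
sequence; each set gets a majority-rule consensus and a standardized
identifier ``EPV-<group>.<number>-<host token>``.  The whole procedure
iterates with the screen (locus consensuses join the classification
library) until the catalogue reaches a fixed point.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from Bio.Data.IUPACData import ambiguous_dna_values

from . import alignment_tree as at
from .screening import (
    ConsensusRef,
    Hit,
    HitTable,
    ProbeLibrary,
    ScreenParams,
    run_screen,
)

logger = logging.getLogger(__name__)

_IUPAC_BY_SET = {frozenset(v): k for k, v in ambiguous_dna_values.items() if k != "X"}


class LocusParameterError(ValueError):
    pass


@dataclass
class Locus:
    """A consolidated per-genome element: merged hits plus flanks."""

    locus_id: str
    species: str
    contig: str
    start: int
    end: int
    strand: str
    assigned_genus: str
    member_hits: List[str]
    upstream_flank: str = ""
    downstream_flank: str = ""
    upstream_truncated: bool = False
    downstream_truncated: bool = False
    sequence: str = ""


@dataclass
class OrthologSet:
    """Loci across species descending from one incorporation event."""

    epv_id: str
    members: List[Locus]
    consensus: str = ""
    group: str = ""  # taxonomic label of the viral group (genus)
    host_group: str = ""

    def species(self) -> FrozenSet[str]:
        return frozenset(m.species for m in self.members)


def merge_hits(
    hits: Sequence[Hit],
    max_gap: int,
    genome: Optional[Mapping[str, str]] = None,
    flank_len: int = 1000,
    genus_of: Optional[Mapping[str, str]] = None,
) -> List[Locus]:
    """Merge one genome's hits into loci.

    Same-contig, same-strand hits whose spans lie within ``max_gap``
    nucleotides of each other merge transitively.  The locus genus is
    the genus of the highest-bitscore member (looked up in ``genus_of``
    by hit id).  If the contig sequences are supplied, the locus
    sequence and its flanks (``flank_len`` each side, truncation at
    contig edges flagged) are extracted.
    """
    if max_gap < 0:
        raise LocusParameterError("max_gap must be >= 0")
    species = {h.species for h in hits}
    if len(species) > 1:
        raise LocusParameterError("merge_hits expects hits from a single genome")
    groups: Dict[Tuple[str, str], List[Hit]] = {}
    for h in hits:
        groups.setdefault((h.contig, h.strand), []).append(h)
    loci: List[Locus] = []
    for (contig, strand), hs in groups.items():
        hs = sorted(hs, key=lambda h: (h.start, h.end))
        cluster: List[Hit] = []
        clusters: List[List[Hit]] = []
        cur_end = None
        for h in hs:
            if cur_end is not None and h.start - cur_end <= max_gap:
                cluster.append(h)
                cur_end = max(cur_end, h.end)
            else:
                if cluster:
                    clusters.append(cluster)
                cluster = [h]
                cur_end = h.end
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            start = min(h.start for h in cl)
            end = max(h.end for h in cl)
            best = max(cl, key=lambda h: (h.bitscore, h.hit_id))
            genus = (genus_of or {}).get(best.hit_id, "unknown")
            sp = cl[0].species
            locus = Locus(
                locus_id=f"{sp}|{contig}|{start}-{end}",
                species=sp,
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                assigned_genus=genus,
                member_hits=[h.hit_id for h in cl],
            )
            if genome is not None:
                seq = genome[contig]
                locus.sequence = seq[start:end]
                fs = max(0, start - flank_len)
                locus.upstream_flank = seq[fs:start]
                locus.upstream_truncated = fs == 0 and start < flank_len
                locus.downstream_flank = seq[end : end + flank_len]
                locus.downstream_truncated = end + flank_len > len(seq)
            loci.append(locus)
    loci.sort(key=lambda l: (l.contig, l.start, l.end))
    return loci


def _flank_identity(a: str, b: str) -> float:
    """Identity of two flanks: matches / aligned (non-gap) columns."""
    if not a or not b:
        return 0.0
    aligner = at._make_aligner("nt")
    aln = aligner.align(a, b)[0]
    ra, rb = aln.aligned
    matches = 0
    aligned_cols = 0
    for (as_, ae), (bs, be) in zip(ra, rb):
        aligned_cols += ae - as_
        matches += sum(1 for i in range(ae - as_) if a[as_ + i] == b[bs + i])
    if aligned_cols == 0:
        return 0.0
    return matches / aligned_cols


def assign_orthologs(
    loci: Sequence[Locus],
    flank_len: int = 1000,
    min_flank_identity: float = 0.75,
) -> List[OrthologSet]:
    """Cluster loci across species into ortholog sets by shared flanks.

    Two loci match when both their upstream and downstream flanks align
    globally at >= ``min_flank_identity``; clusters are single-linkage
    closures of matches within the same assigned genus.  A paralog
    guard keeps two loci of one species from co-clustering: candidate
    pairs are merged best-identity-first and a merge is refused if it
    would place two same-species loci in one set.
    """
    if flank_len <= 0:
        raise LocusParameterError("flank_len must be positive")
    loci = list(loci)
    n = len(loci)
    pairs: List[Tuple[float, int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = loci[i], loci[j]
            if a.assigned_genus != b.assigned_genus:
                continue
            if a.species == b.species:
                continue
            iu = _flank_identity(a.upstream_flank[-flank_len:], b.upstream_flank[-flank_len:])
            idn = _flank_identity(a.downstream_flank[:flank_len], b.downstream_flank[:flank_len])
            if iu >= min_flank_identity and idn >= min_flank_identity:
                pairs.append((iu + idn, i, j))
    # best-first single linkage with the paralog guard
    parent = list(range(n))
    comp_species: List[Set[str]] = [{l.species} for l in loci]

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _, i, j in sorted(pairs, key=lambda p: (-p[0], p[1], p[2])):
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if comp_species[ri] & comp_species[rj]:
            continue  # would co-cluster within-species duplicates
        parent[rj] = ri
        comp_species[ri] |= comp_species[rj]
    groups: Dict[int, List[Locus]] = {}
    for i, l in enumerate(loci):
        groups.setdefault(find(i), []).append(l)
    sets = []
    for members in groups.values():
        members.sort(key=lambda l: (l.species, l.contig, l.start))
        sets.append(
            OrthologSet(epv_id="", members=members, group=members[0].assigned_genus)
        )
    sets.sort(key=lambda s: (s.members[0].species, s.members[0].contig, s.members[0].start))
    return sets


def set_alignment(members: Sequence[Locus]) -> Dict[str, str]:
    """Reference-anchored MSA of an ortholog set's sequences.

    Each member is pairwise-aligned to the longest member (the anchor),
    and rows are flattened into the anchor's coordinates — the same
    constrained-alignment construction used throughout the hierarchy.
    """
    if not members:
        raise ValueError("empty ortholog set")
    seqs = {m.species: m.sequence for m in members}
    anchor = max(seqs, key=lambda k: (len(seqs[k]), k))
    if len(members) == 1:
        return {anchor: seqs[anchor]}
    msa = at.build_constrained_msa(seqs, anchor)
    rows, _ = msa.flat_rows()
    return rows


def build_consensus(aligned_members: Sequence[str]) -> str:
    """Majority-rule consensus of a flat alignment.

    Per column, the majority character wins; ties among bases render as
    the IUPAC ambiguity code of the tied set; columns where the gap is
    the (strict) majority are omitted.
    """
    if not aligned_members:
        raise ValueError("empty alignment")
    width = len(aligned_members[0])
    if any(len(r) != width for r in aligned_members):
        raise ValueError("alignment rows differ in length")
    out = []
    nrows = len(aligned_members)
    for col in range(width):
        counts: Dict[str, int] = {}
        for row in aligned_members:
            c = row[col].upper()
            counts[c] = counts.get(c, 0) + 1
        if counts.get("-", 0) * 2 > nrows:
            continue
        base_counts = {c: k for c, k in counts.items() if c != "-"}
        if not base_counts:
            continue
        top = max(base_counts.values())
        tied = sorted(c for c, k in base_counts.items() if k == top)
        if len(tied) == 1:
            out.append(tied[0])
        else:
            key = frozenset(tied)
            out.append(_IUPAC_BY_SET.get(key, "N"))
    return "".join(out)


def species_abbreviation(binomial: str) -> str:
    """Six-letter host code: first three letters of genus and epithet.

    ``Monodelphis domestica`` -> ``MonDom``; parts shorter than three
    letters are used whole.
    """
    parts = binomial.replace("_", " ").split()
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"malformed binomial: {binomial!r}")
    g, s = parts
    return g[:3].capitalize() + s[:3].capitalize()


def _group_token(genus: str) -> str:
    g = genus
    low = g.lower()
    if low.endswith("parvovirus"):
        g = g[: -len("parvovirus")]
    return g.capitalize() if g else genus.capitalize()


def assign_identifiers(
    sets: Sequence[OrthologSet],
    host_taxonomy: Mapping[str, Sequence[str]],
    number_blocks: Optional[Mapping[str, int]] = None,
) -> List[OrthologSet]:
    """Assign standardized identifiers ``EPV-<group>.<n>-<host>``.

    The host token is the most specific host group shared by all
    members (from each species' ordered group labels) for multi-species
    sets, or the species abbreviation for single-species sets.  Numbers
    are unique within each viral group, allocated in catalogue order;
    ``number_blocks`` can reserve a starting number per group label.
    """
    counters: Dict[str, int] = {}
    seen: Set[str] = set()
    out: List[OrthologSet] = []
    for s in sets:
        token = _group_token(s.group)
        start = (number_blocks or {}).get(token, 1)
        num = counters.get(token, start)
        counters[token] = num + 1
        species = sorted(s.species())
        if len(species) > 1:
            first = host_taxonomy[species[0]]
            shared = None
            for label in first:
                if all(label in host_taxonomy[sp] for sp in species[1:]):
                    shared = label
                    break
            host = shared if shared is not None else list(first)[-1]
        else:
            host = species_abbreviation(species[0])
        epv_id = f"EPV-{token}.{num}-{host}"
        if epv_id in seen:
            raise RuntimeError(f"duplicate identifier generated: {epv_id}")
        seen.add(epv_id)
        out.append(replace(s, epv_id=epv_id, host_group=host))
    return out


# ---------------------------------------------------------------------------
# the iterative screen -> resolve loop
# ---------------------------------------------------------------------------


@dataclass
class Catalogue:
    """Final resolved EPV catalogue plus the round-by-round log."""

    loci: List[Locus]
    ortholog_sets: List[OrthologSet]
    hit_table: HitTable
    rounds: int
    log: List[Dict[str, object]] = field(default_factory=list)


def iterate_screen(
    genomes: Mapping[str, Mapping[str, str]],
    library: ProbeLibrary,
    params: Optional[ScreenParams] = None,
    max_rounds: int = 5,
    max_gap: int = 1000,
    flank_len: int = 1000,
    min_flank_identity: float = 0.75,
    host_taxonomy: Optional[Mapping[str, Sequence[str]]] = None,
    number_blocks: Optional[Mapping[str, int]] = None,
) -> Catalogue:
    """Iterate screen -> merge -> ortholog assignment to a fixed point.

    After each round the per-set consensuses join the classification
    library, so subsequent rounds classify copies of resolved loci as
    orthologs of known elements.  Iteration stops when the set of locus
    spans and the ortholog partition are unchanged, or at
    ``max_rounds``.
    """
    if max_rounds < 1:
        raise LocusParameterError("max_rounds must be >= 1")
    params = params or ScreenParams()
    consensuses: List[ConsensusRef] = []
    prev_state = None
    log: List[Dict[str, object]] = []
    loci: List[Locus] = []
    sets: List[OrthologSet] = []
    hit_table: Optional[HitTable] = None
    rounds = 0
    for rnd in range(1, max_rounds + 1):
        rounds = rnd
        hit_table = run_screen(genomes, library, params, known_epvs=consensuses)
        genus_of = {
            hid: c.assigned_genus for hid, c in hit_table.classifications.items()
        }
        viral = [
            h
            for h in hit_table.hits
            if hit_table.classifications[h.hit_id].category != "nonviral_crossmatch"
        ]
        loci = []
        for sp in sorted(genomes):
            sp_hits = [h for h in viral if h.species == sp]
            loci.extend(
                merge_hits(sp_hits, max_gap, genome=genomes[sp],
                           flank_len=flank_len, genus_of=genus_of)
            )
        sets = assign_orthologs(loci, flank_len, min_flank_identity)
        for s in sets:
            rows = set_alignment(s.members)
            s.consensus = build_consensus(list(rows.values()))
        state = (
            tuple(sorted((l.species, l.contig, l.start, l.end) for l in loci)),
            tuple(sorted(tuple(sorted(m.locus_id for m in s.members)) for s in sets)),
        )
        log.append(
            {
                "round": rnd,
                "hits": len(hit_table.hits),
                "loci": len(loci),
                "ortholog_sets": len(sets),
            }
        )
        logger.info("round %d: %d hits, %d loci, %d sets",
                    rnd, len(hit_table.hits), len(loci), len(sets))
        if state == prev_state:
            break
        prev_state = state
        consensuses = [
            ConsensusRef(accession=f"EPVCONS-{i:03d}", genus=s.group, nt=s.consensus)
            for i, s in enumerate(sets)
        ]
    taxonomy = host_taxonomy
    if taxonomy is None:
        taxonomy = {sp: ["Vertebrata"] for sp in genomes}
    sets = assign_identifiers(sets, taxonomy, number_blocks)
    return Catalogue(
        loci=loci, ortholog_sets=sets, hit_table=hit_table, rounds=rounds, log=log
    )
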
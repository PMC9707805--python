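"""Synthetic study system: dated host trees, genomes and planted insertions.

The generator emulates the statistical structure the mining pipeline
assumes: a time-calibrated (Yule) species tree, neutrally evolving host
contigs, a parvovirus reference library with genus structure, and
virus-derived fragments planted on tree branches.  An insertion made on
a branch is applied at the branch's child node and then co-evolves with
the host genome down every descendant lineage, so each event is present
at homologous flanking positions in exactly the leaves of the child
clade, and the child-node age is the event's true minimum age.  Event
branches are, by default, restricted to child ages within the Cenozoic
(<= 60 My), matching the era over which vertebrate parvoviral
incorporations are observed.

Every random choice flows from explicit seeds; identical configurations
give byte-identical output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .ages import TimeTree
from .screening import ProbeLibrary, ReferenceRecord, REP_GENE, VP_GENE, translate

NT = "ACGT"

# codons of the standard code that do not encode stop
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c for a in NT for b in NT for c in NT if a + b + c not in _STOPS
]

_GENUS_NAMES = [
    "Protoparvovirus",
    "Dependoparvovirus",
    "Amdoparvovirus",
    "Erythroparvovirus",
    "Ichthamaparvovirus",
    "Bocaparvovirus",
    "Tetraparvovirus",
    "Copiparvovirus",
]

_SYLLABLES = [
    "ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "ne",
    "pa", "re", "si", "to", "vu", "xa", "ze", "chi", "dro", "phy",
]


class InvalidSpecError(ValueError):
    pass


class UnknownBranchError(KeyError):
    pass


@dataclass(frozen=True)
class TimeTreeSpec:
    """Parameters of the simulated dated species tree."""

    n_species: int
    crown_age: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InvalidSpecError("n_species must be >= 2")
        if self.crown_age <= 0:
            raise InvalidSpecError("crown_age must be positive")


@dataclass(frozen=True)
class DecayParams:
    """Neutral decay rates applied along tree branches.

    Rates are per site per My; indel lengths are geometric with mean
    ``indel_mean_len``.  Defaults leave ~50 My-old planted loci at
    roughly 70% peptide identity to their source, i.e. still clearly
    detectable by the translated screen.
    """

    sub_rate: float = 2e-3
    indel_rate: float = 1e-4
    indel_mean_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sub_rate, self.indel_rate) < 0 or self.indel_mean_len < 1:
            raise InvalidSpecError("decay rates must be >= 0 and mean length >= 1")


@dataclass
class SimEvent:
    """One planted germline-incorporation event."""

    event_id: str
    branch: Tuple[str, str]  # (parent label, child label)
    source_accession: str
    fragment: Tuple[int, int]  # interval on the source viral genome
    insertion_contig: str
    insertion_offset: int  # position in the ancestral contig at event time


@dataclass
class GroundTruth:
    """The simulator's record of planted events — the acceptance surface.

    ``carriers`` are exactly the leaves below each insertion branch's
    child node; ``true_min_age`` is that child node's age; ``true_spans``
    locate each surviving copy in the final leaf genomes.
    """

    events: List[SimEvent]
    carriers: Dict[str, FrozenSet[str]]
    true_min_age: Dict[str, float]
    true_spans: Dict[Tuple[str, str], Tuple[str, int, int]]
    indel_counts: Dict[Tuple[str, str], Dict[str, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "events": [
                    {
                        "event_id": e.event_id,
                        "branch": list(e.branch),
                        "source_accession": e.source_accession,
                        "fragment": list(e.fragment),
                        "insertion_contig": e.insertion_contig,
                        "insertion_offset": e.insertion_offset,
                    }
                    for e in self.events
                ],
                "carriers": {k: sorted(v) for k, v in self.carriers.items()},
                "true_min_age": self.true_min_age,
                "true_spans": [
                    {"event_id": k[0], "species": k[1], "contig": v[0],
                     "start": v[1], "end": v[2]}
                    for k, v in self.true_spans.items()
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            events=[
                SimEvent(
                    event_id=e["event_id"],
                    branch=tuple(e["branch"]),
                    source_accession=e["source_accession"],
                    fragment=tuple(e["fragment"]),
                    insertion_contig=e["insertion_contig"],
                    insertion_offset=e["insertion_offset"],
                )
                for e in d["events"]
            ],
            carriers={k: frozenset(v) for k, v in d["carriers"].items()},
            true_min_age=d["true_min_age"],
            true_spans={
                (s["event_id"], s["species"]): (s["contig"], s["start"], s["end"])
                for s in d["true_spans"]
            },
        )


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def _random_binomial_name(rng: np.random.Generator) -> str:
    def word(n_syll: int) -> str:
        return "".join(_SYLLABLES[rng.integers(0, len(_SYLLABLES))] for _ in range(n_syll))

    genus = word(int(rng.integers(2, 4))).capitalize()
    epithet = word(int(rng.integers(2, 4)))
    return f"{genus}_{epithet}"


def simulate_species_tree(spec: TimeTreeSpec) -> TimeTree:
    """Simulate an ultrametric dated tree under a pure-birth model.

    A Yule process (unit birth rate) is run from the crown (two
    lineages) until ``n_species`` lineages exist, then the time axis is
    rescaled so the crown age equals ``spec.crown_age``.  Leaves get
    synthetic binomial names; internal nodes stable preorder labels.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species

    class _N:
        __slots__ = ("t", "children")

        def __init__(self, t):
            self.t = t
            self.children = []

    root = _N(0.0)
    a, b = _N(None), _N(None)
    root.children = [a, b]
    active = [a, b]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(0, len(active)))
        nd = active[idx]
        nd.t = t
        c1, c2 = _N(None), _N(None)
        nd.children = [c1, c2]
        active[idx] = c1
        active.append(c2)
    present = t + rng.exponential(1.0 / n)
    scale = spec.crown_age / present
    for nd in active:
        nd.t = present

    names = set()
    while len(names) < n:
        names.add(_random_binomial_name(rng))
    names = sorted(names)
    name_iter = iter(names)

    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)

    def build(src: _N, dst: dendropy.Node) -> None:
        for child in src.children:
            c = dendropy.Node()
            c.edge.length = (child.t - src.t) * scale
            dst.add_child(c)
            if child.children:
                build(child, c)
            else:
                c.taxon = tns.require_taxon(label=next(name_iter))

    build(root, dtree.seed_node)
    return TimeTree(dtree)


# ---------------------------------------------------------------------------
# reference library
# ---------------------------------------------------------------------------


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = ["ATG"] + [
        _NONSTOP_CODONS[rng.integers(0, len(_NONSTOP_CODONS))]
        for _ in range(n_codons - 1)
    ]
    return "".join(codons)


def _mutate_cds(cds: str, p_sub: float, rng: np.random.Generator) -> str:
    """Point-mutate a CDS, resampling any codon that becomes a stop."""
    seq = list(cds)
    n_sub = rng.poisson(p_sub * len(seq))
    for _ in range(n_sub):
        i = int(rng.integers(0, len(seq)))
        alt = [c for c in NT if c != seq[i]]
        seq[i] = alt[rng.integers(0, 3)]
    for c0 in range(0, len(seq) - 2, 3):
        if "".join(seq[c0 : c0 + 3]) in _STOPS:
            seq[c0 : c0 + 3] = _NONSTOP_CODONS[rng.integers(0, len(_NONSTOP_CODONS))]
    return "".join(seq)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, size=n))


def simulate_reference_library(
    n_genera: int,
    n_per_genus: int = 1,
    rep_len: int = 300,
    vp_len: int = 250,
    seed: int = 0,
    genus_divergence: float = 0.35,
    within_divergence: float = 0.05,
    itr_len: int = 120,
) -> ProbeLibrary:
    """Generate a genus-structured peptide probe/reference library.

    A family-ancestor coding genome is mutated into genus ancestors
    (``genus_divergence`` substitutions/site) and each genus ancestor
    into its reference isolates (``within_divergence``), so within-genus
    peptide identity exceeds between-genus identity.  Each isolate gets
    a Rep/NS probe, a VP/Cap probe and a full coding nucleotide genome
    (ITR + Rep CDS + spacer + VP CDS + ITR).
    """
    if min(n_genera, n_per_genus, rep_len, vp_len) < 1:
        raise InvalidSpecError("all library counts must be >= 1")
    rng = np.random.default_rng(seed)
    fam_rep = _random_cds(rep_len, rng)
    fam_vp = _random_cds(vp_len, rng)
    records: List[ReferenceRecord] = []
    genomes: Dict[str, str] = {}
    annotations: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for g in range(n_genera):
        genus = (
            _GENUS_NAMES[g] if g < len(_GENUS_NAMES) else f"Novoparvovirus{g + 1}"
        )
        g_rep = _mutate_cds(fam_rep, genus_divergence, rng)
        g_vp = _mutate_cds(fam_vp, genus_divergence, rng)
        for i in range(n_per_genus):
            acc = f"{genus[:5]}-{i + 1:02d}"
            rep = _mutate_cds(g_rep, within_divergence, rng)
            vp = _mutate_cds(g_vp, within_divergence, rng)
            itr5 = _random_nt(itr_len, rng)
            itr3 = _random_nt(itr_len, rng)
            spacer = _random_nt(60, rng)
            genome = itr5 + rep + spacer + vp + itr3
            genomes[acc] = genome
            annotations[acc] = {
                REP_GENE: (itr_len, itr_len + len(rep)),
                VP_GENE: (itr_len + len(rep) + 60, itr_len + len(rep) + 60 + len(vp)),
            }
            records.append(
                ReferenceRecord(f"{acc}-Rep", genus, REP_GENE, translate(rep), rep)
            )
            records.append(
                ReferenceRecord(f"{acc}-VP", genus, VP_GENE, translate(vp), vp)
            )
    return ProbeLibrary(records=records, genomes=genomes, annotations=annotations)


# ---------------------------------------------------------------------------
# neutral decay
# ---------------------------------------------------------------------------


def _decay_once(
    seq: str, duration: float, params: DecayParams, rng: np.random.Generator
) -> Tuple[str, int, int]:
    """Apply Poisson substitutions and indels to one segment.

    Substitution events hit uniform sites (with replacement, so the
    observed difference fraction follows the Jukes-Cantor expectation);
    indels are half insertions, half deletions, geometric lengths.
    Returns (sequence, n_insertion_events, n_deletion_events).
    """
    L = len(seq)
    if L == 0 or duration == 0:
        return seq, 0, 0
    chars = list(seq)
    n_sub = rng.poisson(params.sub_rate * L * duration)
    if n_sub:
        sites = rng.integers(0, L, size=n_sub)
        picks = rng.integers(0, 3, size=n_sub)
        for s, p in zip(sites, picks):
            alt = [c for c in NT if c != chars[s]]
            chars[s] = alt[p]
    n_ins = 0
    n_del = 0
    n_indel = rng.poisson(params.indel_rate * L * duration)
    for _ in range(n_indel):
        cur = len(chars)
        if cur == 0:
            break
        pos = int(rng.integers(0, cur))
        length = int(rng.geometric(1.0 / params.indel_mean_len))
        if rng.random() < 0.5:
            ins = [NT[i] for i in rng.integers(0, 4, size=length)]
            chars[pos:pos] = ins
            n_ins += 1
        else:
            del chars[pos : pos + length]
            n_del += 1
    return "".join(chars), n_ins, n_del


def decay_sequence(seq: str, duration: float, params: DecayParams) -> str:
    """Neutrally decay a sequence for ``duration`` My (seeded by params)."""
    if duration < 0:
        raise InvalidSpecError("duration must be >= 0")
    rng = np.random.default_rng(params.seed)
    out, _, _ = _decay_once(seq, duration, params, rng)
    return out


# ---------------------------------------------------------------------------
# host genomes with planted insertions
# ---------------------------------------------------------------------------


@dataclass
class _Span:
    event_id: str
    start: int
    end: int
    n_ins: int = 0
    n_del: int = 0


def _sample_events(
    tree: TimeTree,
    library: ProbeLibrary,
    n_events: int,
    n_contigs: int,
    contig_len: int,
    margin: int,
    rng: np.random.Generator,
    max_event_age: float,
    event_rate: Optional[float] = None,
) -> List[SimEvent]:
    ages = {lbl: tree.node_age(lbl) for _, lbl, _ in tree.edges()}
    ages.update({p: tree.node_age(p) for p, _, _ in tree.edges()})
    weighted = []
    for parent, child, length in tree.edges():
        lo = tree.node_age(child)
        hi = min(tree.node_age(parent), max_event_age)
        w = max(0.0, hi - lo)
        if w > 0:
            weighted.append(((parent, child), w))
    if not weighted:
        raise InvalidSpecError("no tree branches inside the event age window")
    branches = [b for b, _ in weighted]
    w = np.array([x for _, x in weighted])
    if event_rate is not None:
        n_events = int(rng.poisson(event_rate * w.sum()))
    probs = w / w.sum()
    accs = sorted(library.genomes)
    events = []
    for k in range(n_events):
        br = branches[rng.choice(len(branches), p=probs)]
        acc = accs[rng.integers(0, len(accs))]
        ann = library.annotations[acc]
        genome_len = len(library.genomes[acc])
        mode = rng.random()
        if mode < 0.5:
            lo = min(s for s, _ in ann.values())
            hi = max(e for _, e in ann.values())
            frag = (lo, hi)
        else:
            gene = REP_GENE if mode < 0.75 else VP_GENE
            frag = ann[gene]
        events.append(
            SimEvent(
                event_id=f"ev{k:03d}",
                branch=br,
                source_accession=acc,
                fragment=frag,
                insertion_contig=f"contig{int(rng.integers(0, n_contigs)) + 1}",
                insertion_offset=-1,
            )
        )
    # Insertion sites must be distinct across ALL events, including events
    # on disjoint lineages: in real genomes integration sites are unique,
    # and shared flanks are the orthology signal.  Assign each event a
    # well-separated slot in ancestral contig coordinates.
    by_contig: Dict[str, List[SimEvent]] = {}
    for e in events:
        by_contig.setdefault(e.insertion_contig, []).append(e)
    for contig, evs in sorted(by_contig.items()):
        lo, hi = margin, contig_len - margin
        step = (hi - lo) / len(evs)
        order = rng.permutation(len(evs))
        for slot, idx in enumerate(order):
            evs[idx].insertion_offset = int(lo + step * (slot + 0.25 + 0.5 * rng.random()))
    return events


def simulate_host_genomes(
    tree: TimeTree,
    contig_len: int = 30000,
    events: Optional[Sequence[SimEvent]] = None,
    event_rate: Optional[float] = None,
    n_events: int = 10,
    library: Optional[ProbeLibrary] = None,
    host_decay: Optional[DecayParams] = None,
    epv_decay: Optional[DecayParams] = None,
    n_contigs: int = 2,
    seed: int = 0,
    max_event_age: float = 60.0,
    margin: int = 2500,
) -> Tuple[Dict[str, Dict[str, str]], GroundTruth]:
    """Evolve host genomes down the tree, planting insertion events.

    Returns (genomes, ground_truth) where genomes maps
    species -> contig name -> sequence.  Insertions are applied to the
    ancestral contig at the event branch's child node and then decay
    (with ``epv_decay``) together with the host background
    (``host_decay``) along all descendant branches; coordinates of every
    surviving copy are tracked through subsequent indels, not
    re-searched.
    """
    if library is None:
        library = simulate_reference_library(3, 2, seed=seed + 1)
    host_decay = host_decay or DecayParams(seed=seed + 2)
    epv_decay = epv_decay or DecayParams(seed=seed + 3)
    max_frag = max((len(g) for g in library.genomes.values()), default=0)
    if contig_len <= max_frag:
        raise InvalidSpecError("contig_len must exceed the largest insertion")

    rng = np.random.default_rng(seed)
    valid_branches = {(p, c) for p, c, _ in tree.edges()}
    if events is None:
        events = _sample_events(
            tree, library, n_events, n_contigs, contig_len, margin,
            rng, max_event_age, event_rate,
        )
    else:
        events = list(events)
        for e in events:
            if tuple(e.branch) not in valid_branches:
                raise UnknownBranchError(f"event {e.event_id}: branch {e.branch}")

    by_child: Dict[str, List[SimEvent]] = {}
    for e in events:
        by_child.setdefault(e.branch[1], []).append(e)

    contig_names = [f"contig{i + 1}" for i in range(n_contigs)]
    root_rng = np.random.default_rng(seed + 10)
    root_contigs = {name: (_random_nt(contig_len, root_rng), []) for name in contig_names}

    genomes: Dict[str, Dict[str, str]] = {}
    truth = GroundTruth(events=list(events), carriers={}, true_min_age={}, true_spans={})
    for e in events:
        truth.carriers[e.event_id] = tree.leaves_below(e.branch[1])
        truth.true_min_age[e.event_id] = tree.node_age(e.branch[1])

    # deterministic per-node streams, keyed by a stable preorder counter
    node_counter = [0]

    def node_rng() -> np.random.Generator:
        node_counter[0] += 1
        return np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(node_counter[0],))
        )

    host_p = host_decay
    epv_p = epv_decay

    def decay_contig(
        seq: str, spans: List[_Span], duration: float, rng_nd: np.random.Generator
    ) -> Tuple[str, List[_Span]]:
        """Decay host background and EPV spans with their own params."""
        bounds = [0]
        for s in spans:
            bounds.extend([s.start, s.end])
        bounds.append(len(seq))
        pieces = []
        new_spans = []
        cursor = 0
        out_len = 0
        span_iter = sorted(spans, key=lambda s: s.start)
        for s in span_iter:
            host_piece, _, _ = _decay_once(seq[cursor : s.start], duration, host_p, rng_nd)
            pieces.append(host_piece)
            out_len += len(host_piece)
            epv_piece, ni, nd = _decay_once(seq[s.start : s.end], duration, epv_p, rng_nd)
            new_spans.append(
                _Span(s.event_id, out_len, out_len + len(epv_piece),
                      s.n_ins + ni, s.n_del + nd)
            )
            pieces.append(epv_piece)
            out_len += len(epv_piece)
            cursor = s.end
        tail, _, _ = _decay_once(seq[cursor:], duration, host_p, rng_nd)
        pieces.append(tail)
        return "".join(pieces), new_spans

    def insert_events(
        contigs: Dict[str, Tuple[str, List[_Span]]],
        child_label: str,
        rng_nd: np.random.Generator,
    ) -> None:
        for e in sorted(by_child.get(child_label, []), key=lambda e: e.event_id):
            seq, spans = contigs[e.insertion_contig]
            frag = library.genomes[e.source_accession][e.fragment[0] : e.fragment[1]]

            def is_clear(p: int) -> bool:
                return all(p <= s.start - margin or p >= s.end + margin for s in spans)

            # materialise the pre-assigned ancestral site, rescaled for any
            # indel drift of the contig; fall back to random placement if
            # the site is no longer clear of earlier insertions
            off = None
            if e.insertion_offset >= 0:
                cand = int(e.insertion_offset * len(seq) / contig_len)
                cand = min(max(margin, cand), max(margin, len(seq) - margin))
                if is_clear(cand):
                    off = cand
            if off is None:
                off = int(rng_nd.integers(margin, max(margin + 1, len(seq) - margin)))
                for _ in range(200):
                    if is_clear(off):
                        break
                    off = int(rng_nd.integers(margin, max(margin + 1, len(seq) - margin)))
            e.insertion_offset = off
            new_spans = []
            for s in spans:
                shift = len(frag) if s.start >= off else 0
                new_spans.append(
                    _Span(s.event_id, s.start + shift, s.end + shift, s.n_ins, s.n_del)
                )
            new_spans.append(_Span(e.event_id, off, off + len(frag)))
            new_spans.sort(key=lambda s: s.start)
            contigs[e.insertion_contig] = (seq[:off] + frag + seq[off:], new_spans)

    def walk(node: dendropy.Node, contigs: Dict[str, Tuple[str, List[_Span]]]) -> None:
        label = node.label if not node.is_leaf() else node.taxon.label
        rng_nd = node_rng()
        insert_events(contigs, label, rng_nd)
        if node.is_leaf():
            genomes[label] = {name: contigs[name][0] for name in contig_names}
            for name in contig_names:
                for s in contigs[name][1]:
                    truth.true_spans[(s.event_id, label)] = (name, s.start, s.end)
                    truth.indel_counts[(s.event_id, label)] = {
                        "n_ins": s.n_ins, "n_del": s.n_del
                    }
            return
        for child in node.child_nodes():
            child_contigs = {}
            crng = node_rng()
            for name in contig_names:
                seq, spans = contigs[name]
                child_contigs[name] = decay_contig(seq, spans, child.edge.length, crng)
            walk(child, child_contigs)

    walk(tree.dendropy_tree.seed_node, root_contigs)
    genomes = {sp: genomes[sp] for sp in sorted(genomes)}
    return genomes, truth
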
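"""Translated similarity screen of genome assemblies with peptide probes.

This is the in-silico screening stage: every contig of every assembly is
translated in six frames and searched with peptide probes from a curated
parvovirus reference library (Rep/NS and VP/Cap polypeptides).  Matches
are classified against the same library — extended, as loci are resolved,
with per-locus consensus sequences — into putatively novel elements,
orthologs of already-characterised elements, and non-viral cross-matches.

The search itself is seed-and-extend: exact amino-acid k-mer seeds,
ungapped X-drop triggering, then a full affine-gap Smith-Waterman over
any triggered frame, iterated with masking so several non-overlapping
hits per frame can be reported.  Scores are expressed in bits via the
Karlin-Altschul transform with standard ungapped BLOSUM62 constants.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

from ._kernels import (
    BLOSUM62,
    MASK_INDEX,
    encode_peptide,
    sw_fill,
    sw_traceback,
    ungapped_xdrop,
)

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for ungapped BLOSUM62.
KA_LAMBDA = 0.3176
KA_K = 0.134

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _codon_map() -> Dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    cmap = dict(table.forward_table)
    for stop in table.stop_codons:
        cmap[stop] = "*"
    return cmap


_CODONS = _codon_map()
_VALID_NT = set("ACGTN")


class InvalidAlphabetError(ValueError):
    """Sequence contains characters outside ACGTN."""


class ScreenParameterError(ValueError):
    """Invalid screening parameter."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string in frame 1 (standard code).

    Stops render as '*'; any codon containing N renders as 'X'; a
    trailing partial codon is dropped.
    """
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(_CODONS.get(seq[i : i + 3], "X"))
    return "".join(out)


def six_frame_translate(dna: str) -> List[str]:
    """Translate ``dna`` in all six frames.

    Returns ``[+1, +2, +3, -1, -2, -3]``: the first three read the
    forward strand offset by 0/1/2, the last three read the reverse
    complement likewise.
    """
    dna = dna.upper()
    bad = set(dna) - _VALID_NT
    if bad:
        raise InvalidAlphabetError(f"invalid nucleotide characters: {sorted(bad)}")
    rc = reverse_complement(dna)
    return [translate(dna[o:]) for o in range(3)] + [translate(rc[o:]) for o in range(3)]


# ---------------------------------------------------------------------------
# reference library
# ---------------------------------------------------------------------------

REP_GENE = "Rep/NS"
VP_GENE = "VP/Cap"


@dataclass(frozen=True)
class ReferenceRecord:
    """One peptide probe: a viral polypeptide with genus and gene labels."""

    accession: str
    genus: str
    gene: str  # REP_GENE, VP_GENE or other
    peptide: str
    cds_nt: Optional[str] = None


@dataclass
class ProbeLibrary:
    """Peptide probe/reference library driving search and classification.

    ``genomes`` optionally carries full coding nucleotide genomes for
    simulated reference isolates (keyed by isolate id) and
    ``annotations`` their gene coordinates — used by the synthetic-data
    generator and the coding-capacity scan.
    """

    records: List[ReferenceRecord]
    genomes: Dict[str, str] = field(default_factory=dict)
    annotations: Dict[str, Dict[str, Tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.records]
        if len(set(accs)) != len(accs):
            raise ValueError("probe accessions must be unique")
        for r in self.records:
            if not r.peptide:
                raise ValueError(f"empty peptide for {r.accession}")

    @property
    def genera(self) -> List[str]:
        return sorted({r.genus for r in self.records})

    def by_accession(self, accession: str) -> ReferenceRecord:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)


@dataclass(frozen=True)
class ConsensusRef:
    """A resolved-locus consensus used as a classification reference."""

    accession: str  # the EPV/locus identifier
    genus: str
    nt: str


# ---------------------------------------------------------------------------
# hits
# ---------------------------------------------------------------------------


@dataclass
class Hit:
    """One local alignment of a probe against a contig.

    Coordinates are 0-based half-open on the forward nucleotide strand
    regardless of the matched strand/frame.
    """

    species: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int  # 1..3 within the strand
    probe_accession: str
    bitscore: float
    pct_identity: float
    aligned_peptide: str
    raw_score: int = 0
    evalue: float = math.inf
    qstart: int = 0
    qend: int = 0
    hit_id: str = ""


@dataclass(frozen=True)
class HitClassification:
    hit_id: str
    best_reference: str
    assigned_genus: str
    category: str  # novel_epv | known_ortholog | nonviral_crossmatch


@dataclass
class ScreenParams:
    """Tunables of the translated screen.

    seed_len: exact-match seed length in aa; min_bitscore: report
    threshold in bits; gap penalties give gap cost open + L*extend;
    xdrop: ungapped extension drop-off; trigger_score: raw ungapped
    score needed to run the gapped DP on a frame.
    """

    seed_len: int = 3
    min_bitscore: float = 50.0
    gap_open: int = 11
    gap_extend: int = 1
    xdrop: int = 20
    trigger_score: int = 50
    max_hits_per_frame: int = 25

    def __post_init__(self) -> None:
        if self.seed_len < 2:
            raise ScreenParameterError("seed_len must be >= 2")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ScreenParameterError("gap penalties must be non-negative")


def bitscore_from_raw(raw: int) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)


def raw_from_bitscore(bits: float) -> int:
    return int(math.ceil((bits * math.log(2.0) + math.log(KA_K)) / KA_LAMBDA))


def evalue_from_raw(raw: int, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * raw)


def _seed_positions(qv: np.ndarray, tv: np.ndarray, k: int) -> List[Tuple[int, int]]:
    """Exact k-mer matches (qpos, tpos) between encoded peptides."""
    if len(qv) < k or len(tv) < k:
        return []
    index: Dict[bytes, List[int]] = {}
    qb = qv.tobytes()
    for i in range(len(qv) - k + 1):
        index.setdefault(qb[i : i + k], []).append(i)
    out = []
    tb = tv.tobytes()
    for j in range(len(tv) - k + 1):
        for i in index.get(tb[j : j + k], ()):
            out.append((i, j))
    return out


def _frame_to_forward(strand: str, offset: int, tstart: int, tend: int, L: int) -> Tuple[int, int]:
    """Map aa coordinates in a translated frame to forward-strand nt coords."""
    s = offset + 3 * tstart
    e = offset + 3 * tend
    if strand == "+":
        return s, e
    return L - e, L - s


def translated_search(
    probe: str, contig: str, params: Optional[ScreenParams] = None
) -> List[Hit]:
    """Search one contig with one peptide probe across all six frames.

    Frames are triggered by exact ``seed_len``-mer seeds whose ungapped
    X-drop extension reaches ``trigger_score``; triggered frames get a
    full affine-gap Smith-Waterman, iterated with masking to extract
    every non-overlapping alignment at or above ``min_bitscore``.
    Overlapping hits from different frames/strands are deduplicated,
    keeping the highest bitscore.
    """
    params = params or ScreenParams()
    if len(probe) < params.seed_len:
        raise ScreenParameterError("probe shorter than seed_len")
    frames = six_frame_translate(contig)
    qv = encode_peptide(probe)
    raw_threshold = max(1, raw_from_bitscore(params.min_bitscore))
    # the ungapped trigger must never exceed the report threshold, or
    # reportable borderline alignments could be filtered before the DP
    trigger = min(params.trigger_score, raw_threshold)
    L = len(contig)
    hits: List[Hit] = []
    for fi, frame_pep in enumerate(frames):
        if len(frame_pep) < params.seed_len:
            continue
        strand = "+" if fi < 3 else "-"
        offset = fi % 3
        tv = encode_peptide(frame_pep)
        seeds = _seed_positions(qv, tv, params.seed_len)
        if not seeds:
            continue
        triggered = False
        seen_diag = set()
        for (qp, tp) in seeds:
            d = tp - qp
            if d in seen_diag:
                continue
            seen_diag.add(d)
            s = ungapped_xdrop(qv, tv, BLOSUM62, qp, tp, params.seed_len, params.xdrop)
            if s >= trigger:
                triggered = True
                break
        if not triggered:
            continue
        tv_work = tv.copy()
        for _ in range(params.max_hits_per_frame):
            H, E, F, best, bi, bj = sw_fill(
                qv, tv_work, BLOSUM62, params.gap_open, params.gap_extend
            )
            if best < raw_threshold:
                break
            qs, ts, ops = sw_traceback(
                qv, tv_work, BLOSUM62, params.gap_open, params.gap_extend, H, E, F, bi, bj
            )
            qe, te = bi, bj
            qi, ti = qs, ts
            aligned_q = []
            matches = 0
            for op in ops:
                if op == 0:
                    aligned_q.append(probe[qi])
                    if qv[qi] == tv[ti] and tv[ti] != MASK_INDEX:
                        matches += 1
                    qi += 1
                    ti += 1
                elif op == 1:
                    aligned_q.append(probe[qi])
                    qi += 1
                else:
                    aligned_q.append("-")
                    ti += 1
            ncols = len(ops)
            s_nt, e_nt = _frame_to_forward(strand, offset, ts, te, L)
            hits.append(
                Hit(
                    species="",
                    contig="",
                    start=s_nt,
                    end=e_nt,
                    strand=strand,
                    frame=offset + 1,
                    probe_accession="",
                    bitscore=bitscore_from_raw(int(best)),
                    pct_identity=100.0 * matches / max(1, ncols),
                    aligned_peptide="".join(aligned_q),
                    raw_score=int(best),
                    evalue=evalue_from_raw(int(best), len(probe), len(frame_pep)),
                    qstart=qs,
                    qend=qe,
                )
            )
            tv_work[ts:te] = MASK_INDEX
    return _dedup_hits(hits)


def _dedup_hits(hits: List[Hit]) -> List[Hit]:
    """Drop hits mostly overlapped (on forward nt coords) by a better one."""
    hits = sorted(hits, key=lambda h: (-h.raw_score, h.start, h.strand, h.frame))
    kept: List[Hit] = []
    for h in hits:
        redundant = False
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > 0 and ov > 0.5 * min(h.end - h.start, k.end - k.start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end, h.strand, h.frame))
    return kept


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _sw_peptide_score(a: np.ndarray, b: np.ndarray, params: ScreenParams) -> int:
    _, _, _, best, _, _ = sw_fill(a, b, BLOSUM62, params.gap_open, params.gap_extend)
    return int(best)


def classify_hit(
    hit: Hit,
    library: ProbeLibrary,
    known_epvs: Sequence[ConsensusRef] = (),
    params: Optional[ScreenParams] = None,
) -> HitClassification:
    """Classify a hit against the reference library plus locus consensuses.

    The best-scoring reference (ties broken by accession sort) assigns
    the genus; a best match to a consensus marks an ortholog of an
    already-characterised element; a best bitscore below the screen
    threshold marks a non-viral cross-match.
    """
    params = params or ScreenParams()
    if not library.records:
        raise ValueError("empty probe library")
    pep = hit.aligned_peptide.replace("-", "")
    if not pep:
        raise ValueError("hit has empty aligned peptide")
    qv = encode_peptide(pep)
    scored: List[Tuple[float, str, str, bool]] = []  # (bits, accession, genus, is_consensus)
    for rec in library.records:
        raw = _sw_peptide_score(qv, encode_peptide(rec.peptide), params)
        scored.append((bitscore_from_raw(raw), rec.accession, rec.genus, False))
    for cons in known_epvs:
        best_raw = 0
        # consensus sequences may carry IUPAC ambiguity codes from tied
        # columns; treat them as N for translation purposes
        cons_nt = "".join(c if c in "ACGTN" else "N" for c in cons.nt.upper())
        for fp in six_frame_translate(cons_nt):
            if len(fp) >= 1:
                best_raw = max(best_raw, _sw_peptide_score(qv, encode_peptide(fp), params))
        scored.append((bitscore_from_raw(best_raw), cons.accession, cons.genus, True))
    scored.sort(key=lambda r: (-r[0], r[1]))
    bits, acc, genus, is_cons = scored[0]
    if bits < params.min_bitscore:
        category = "nonviral_crossmatch"
    elif is_cons:
        category = "known_ortholog"
    else:
        category = "novel_epv"
    return HitClassification(
        hit_id=hit.hit_id, best_reference=acc, assigned_genus=genus, category=category
    )


# ---------------------------------------------------------------------------
# whole-screen driver
# ---------------------------------------------------------------------------


@dataclass
class HitTable:
    """All classified hits of one screening pass, in stable order."""

    hits: List[Hit]
    classifications: Dict[str, HitClassification]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for h in self.hits:
            c = self.classifications[h.hit_id]
            rows.append(
                {
                    "hit_id": h.hit_id,
                    "species": h.species,
                    "contig": h.contig,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "frame": h.frame,
                    "probe_accession": h.probe_accession,
                    "bitscore": round(h.bitscore, 2),
                    "pct_identity": round(h.pct_identity, 2),
                    "evalue": f"{h.evalue:.3g}",
                    "best_reference": c.best_reference,
                    "assigned_genus": c.assigned_genus,
                    "category": c.category,
                    "aligned_peptide": h.aligned_peptide,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "hit_id", "species", "contig", "start", "end", "strand", "frame",
                "probe_accession", "bitscore", "pct_identity", "evalue",
                "best_reference", "assigned_genus", "category", "aligned_peptide",
            ],
        )


def run_screen(
    genomes: Mapping[str, Mapping[str, str]],
    library: ProbeLibrary,
    params: Optional[ScreenParams] = None,
    known_epvs: Sequence[ConsensusRef] = (),
) -> HitTable:
    """Screen every contig of every assembly with every probe.

    ``genomes`` maps species -> contig name -> sequence.  Hits are
    reported in stable (species, contig, start) order and classified
    against the library plus any known locus consensuses.
    """
    params = params or ScreenParams()
    if not library.records:
        raise ValueError("empty probe library")
    all_hits: List[Hit] = []
    for species in sorted(genomes):
        n_before = len(all_hits)
        contigs = genomes[species]
        for contig_name in sorted(contigs):
            seq = contigs[contig_name]
            for rec in library.records:
                for h in translated_search(rec.peptide, seq, params):
                    h.species = species
                    h.contig = contig_name
                    h.probe_accession = rec.accession
                    all_hits.append(h)
        logger.info("screen: %s -> %d hits", species, len(all_hits) - n_before)
    all_hits.sort(key=lambda h: (h.species, h.contig, h.start, h.end, h.probe_accession))
    for i, h in enumerate(all_hits):
        h.hit_id = f"hit{i:05d}"
    classifications = {
        h.hit_id: classify_hit(h, library, known_epvs, params) for h in all_hits
    }
    return HitTable(hits=all_hits, classifications=classifications)
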
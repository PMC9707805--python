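"""Coding capacity of endogenous elements: frameshift repair and ORF scan.

Ancient insertions are pseudogenes: they accumulate frameshifting
indels and premature stops.  To ask how much coding potential a locus
retains, its nucleotide sequence is aligned to the reference CDS of the
cognate viral gene, frameshifting indels are repaired (insertions whose
length is not a multiple of three are excised; deletions are trimmed to
reference codon boundaries), and the repaired sequence is scanned for
the longest stop-free peptide stretch.  Following the convention used
in EPV surveys, no methionine start is required, and stretches of at
least 300 aa count as retained coding capacity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import alignment_tree as at
from .screening import REP_GENE, VP_GENE, reverse_complement, translate

#: gene label used in reports for Rep/NS-derived regions
NS = "NS"
VP = "VP"

_GENE_SHORT = {REP_GENE: NS, VP_GENE: VP}


@dataclass
class CodingRegion:
    """Longest unbroken coding stretch of one locus/gene combination."""

    epv_id: str
    gene: str
    peptide_len: int
    span: Tuple[int, int]
    repaired: bool
    peptide: str = ""


@dataclass
class RepairEdit:
    """One excision made while restoring the reference reading frame."""

    kind: str  # 'insertion' | 'deletion_trim' | 'end_trim'
    ref_pos: int
    length: int
    bases: str


def repair_frameshifts(
    epv_nt: str, ref_cds: str
) -> Tuple[str, List[RepairEdit]]:
    """Codon-aware repair of an element against a reference CDS.

    The element is globally aligned to the reference (nucleotide
    scoring).  Insertions relative to the reference whose length is not
    a multiple of three are excised; deletions not a multiple of three
    are widened to the nearest reference codon boundaries, removing the
    remainder bases from the element; in-frame indels are kept.
    Element overhangs beyond the reference ends are trimmed (logged as
    ``end_trim``) so the repaired sequence corresponds to the
    reference-spanned region.  Returns the repaired sequence and the
    edit log.
    """
    if len(ref_cds) % 3 != 0:
        raise ValueError("reference CDS length must be a multiple of 3")
    if not epv_nt:
        return "", []
    aligner = at._make_aligner("nt")
    aln = aligner.align(ref_cds, epv_nt)[0]
    ref_blocks, epv_blocks = aln.aligned
    ref_blocks = [(int(a), int(b)) for a, b in ref_blocks]
    epv_blocks = [(int(a), int(b)) for a, b in epv_blocks]

    edits: List[RepairEdit] = []
    keep = [False] * len(epv_nt)
    # epv position -> ref position for matched bases
    ref_of: Dict[int, int] = {}
    for (rs, re), (ms, me) in zip(ref_blocks, epv_blocks):
        for k in range(me - ms):
            keep[ms + k] = True
            ref_of[ms + k] = rs + k

    # leading / trailing element overhangs (never aligned, drop + log)
    if epv_blocks:
        lead = epv_blocks[0][0]
        if lead:
            edits.append(RepairEdit("end_trim", 0, lead, epv_nt[:lead]))
        tail = len(epv_nt) - epv_blocks[-1][1]
        if tail:
            edits.append(
                RepairEdit("end_trim", len(ref_cds), tail, epv_nt[epv_blocks[-1][1]:])
            )

    # internal insertions relative to the reference
    for i in range(len(epv_blocks) - 1):
        gap_start = epv_blocks[i][1]
        gap_end = epv_blocks[i + 1][0]
        ins_len = gap_end - gap_start
        ref_gap = ref_blocks[i + 1][0] - ref_blocks[i][1]
        if ins_len > 0 and ins_len % 3 != 0:
            for k in range(gap_start, gap_end):
                keep[k] = False
            edits.append(
                RepairEdit("insertion", ref_blocks[i][1], ins_len,
                           epv_nt[gap_start:gap_end])
            )
        elif ins_len > 0:
            for k in range(gap_start, gap_end):
                keep[k] = True  # in-frame insertion retained
        # deletions relative to the reference: widen to codon boundaries
        if ref_gap > 0 and ref_gap % 3 != 0:
            a = ref_blocks[i][1]
            b = ref_blocks[i + 1][0]
            a0 = 3 * (a // 3)
            b0 = 3 * ((b + 2) // 3)
            removed: List[Tuple[int, str]] = []
            for pos, rp in ref_of.items():
                if (a0 <= rp < a or b <= rp < b0) and keep[pos]:
                    keep[pos] = False
                    removed.append((rp, epv_nt[pos]))
            if removed:
                removed.sort()
                edits.append(
                    RepairEdit(
                        "deletion_trim", a0, len(removed),
                        "".join(c for _, c in removed),
                    )
                )
    repaired = "".join(c for c, k in zip(epv_nt, keep) if k)
    edits.sort(key=lambda e: e.ref_pos)
    return repaired, edits


def longest_unbroken_peptide(nt: str, frame: int) -> CodingRegion:
    """Longest stop-free peptide stretch in one reading frame.

    No methionine start codon is required.  The returned span locates
    the stretch on the input nucleotide sequence (0-based half-open).
    """
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    pep = translate(nt[frame - 1 :])
    best_len = 0
    best_start = 0
    cur_len = 0
    cur_start = 0
    for i, c in enumerate(pep + "*"):
        if c == "*":
            if cur_len > best_len:
                best_len = cur_len
                best_start = cur_start
            cur_len = 0
            cur_start = i + 1
        else:
            cur_len += 1
    span = (frame - 1 + 3 * best_start, frame - 1 + 3 * (best_start + best_len))
    return CodingRegion(
        epv_id="",
        gene="other",
        peptide_len=best_len,
        span=span,
        repaired=False,
        peptide=pep[best_start : best_start + best_len],
    )


def coding_report(
    catalogue,
    library,
    min_len: int = 300,
) -> pd.DataFrame:
    """Per locus x gene, the longest unbroken peptide after repair.

    For each ortholog set the consensus (oriented by the members'
    strand) is repaired against the reference CDS of each gene of its
    assigned genus from the library, and the longest stop-free stretch
    in the reference frame is measured.  Rows with peptide length at or
    above ``min_len`` (300 aa by default) are flagged as retained.
    """
    # reference CDS per (genus, gene): first record by accession order
    ref_cds: Dict[Tuple[str, str], str] = {}
    for rec in sorted(library.records, key=lambda r: r.accession):
        if rec.cds_nt and (rec.genus, rec.gene) not in ref_cds:
            ref_cds[(rec.genus, rec.gene)] = rec.cds_nt
    rows = []
    sets = getattr(catalogue, "ortholog_sets", catalogue)
    for s in sets:
        seq = s.consensus or s.members[0].sequence
        if s.members[0].strand == "-":
            seq = reverse_complement("".join(c if c in "ACGTN" else "N" for c in seq))
        seq = "".join(c if c in "ACGTN" else "N" for c in seq.upper())
        genes = sorted(g for (gen, g) in ref_cds if gen == s.group)
        for gene in genes:
            repaired, edits = repair_frameshifts(seq, ref_cds[(s.group, gene)])
            region = longest_unbroken_peptide(repaired, 1) if repaired else CodingRegion(
                s.epv_id, gene, 0, (0, 0), False
            )
            rows.append(
                {
                    "epv_id": s.epv_id,
                    "clade": s.group,
                    "host_group": s.host_group,
                    "organism": ";".join(sorted(m.species for m in s.members)),
                    "gene": _GENE_SHORT.get(gene, gene),
                    "length_aa": region.peptide_len,
                    "retained": region.peptide_len >= min_len,
                    "repaired": bool(edits),
                    "span_start": region.span[0],
                    "span_end": region.span[1],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "epv_id", "clade", "host_group", "organism", "gene",
            "length_aa", "retained", "repaired", "span_start", "span_end",
        ],
    )
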
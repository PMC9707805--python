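"""Flat-file input/output: FASTA, TSV, GFF3, JSON, config, manifests.

Catalogue TSVs use 0-based half-open coordinates; GFF3 exports are
1-based inclusive.  Both conventions are stated in the file headers.
All exports are written atomically (temp file + rename) and listed in a
manifest with SHA-256 checksums.
"""
from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import yaml
from Bio import SeqIO

from .loci import Catalogue, Locus, OrthologSet
from .screening import ProbeLibrary, ReferenceRecord


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(path: Path, records: Mapping[str, str]) -> None:
    text = "".join(f">{name}\n{_wrap(seq)}\n" for name, seq in records.items())
    _atomic_write(Path(path), text)


def read_fasta(path: Path) -> Dict[str, str]:
    path = Path(path)
    try:
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read FASTA file {path}: {exc}") from exc


def write_genomes(out_dir: Path, genomes: Mapping[str, Mapping[str, str]]) -> List[Path]:
    """One FASTA per species, contigs in stable order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sp in sorted(genomes):
        p = out_dir / f"{sp}.fasta"
        write_fasta(p, {c: genomes[sp][c] for c in sorted(genomes[sp])})
        paths.append(p)
    return paths


def read_genomes(in_dir: Path) -> Dict[str, Dict[str, str]]:
    in_dir = Path(in_dir)
    genomes = {}
    for p in sorted(in_dir.glob("*.fasta")):
        genomes[p.stem] = read_fasta(p)
    return genomes


# probe library FASTA dialect: ">accession|genus|gene"


def write_probe_library(path: Path, library: ProbeLibrary) -> None:
    text = "".join(
        f">{r.accession}|{r.genus}|{r.gene}\n{_wrap(r.peptide)}\n"
        for r in library.records
    )
    _atomic_write(Path(path), text)


def read_probe_library(path: Path) -> ProbeLibrary:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) != 3:
            raise ValueError(
                f"probe header must be 'accession|genus|gene': {rec.description!r}"
            )
        acc, genus, gene = fields
        records.append(ReferenceRecord(acc, genus, gene, str(rec.seq).upper()))
    return ProbeLibrary(records=records)


# reference CDS FASTA (nucleotide), same header dialect


def write_reference_cds(path: Path, library: ProbeLibrary) -> None:
    text = "".join(
        f">{r.accession}|{r.genus}|{r.gene}\n{_wrap(r.cds_nt)}\n"
        for r in library.records
        if r.cds_nt
    )
    _atomic_write(Path(path), text)


def read_reference_cds(path: Path) -> ProbeLibrary:
    from .screening import translate

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) != 3:
            raise ValueError(
                f"reference header must be 'accession|genus|gene': {rec.description!r}"
            )
        acc, genus, gene = fields
        cds = str(rec.seq).upper()
        records.append(ReferenceRecord(acc, genus, gene, translate(cds), cds))
    return ProbeLibrary(records=records)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_config(path: Optional[Path]) -> Dict[str, object]:
    """Load a key-value (YAML) pipeline config; missing file -> {}."""
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# catalogue export
# ---------------------------------------------------------------------------

_CATALOGUE_COLUMNS = [
    "epv_id", "species", "contig", "start", "end", "strand", "genus", "locus_id"
]


def catalogue_tsv(catalogue: Catalogue) -> str:
    lines = [
        "# EPV locus catalogue",
        "# coordinates: 0-based half-open",
        "\t".join(_CATALOGUE_COLUMNS),
    ]
    for s in catalogue.ortholog_sets:
        for m in s.members:
            lines.append(
                "\t".join(
                    [s.epv_id, m.species, m.contig, str(m.start), str(m.end),
                     m.strand, m.assigned_genus, m.locus_id]
                )
            )
    return "\n".join(lines) + "\n"


def read_catalogue_tsv(path: Path) -> List[Dict[str, object]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if fields[0] == "epv_id":
            continue
        rows.append(
            {
                "epv_id": fields[0],
                "species": fields[1],
                "contig": fields[2],
                "start": int(fields[3]),
                "end": int(fields[4]),
                "strand": fields[5],
                "genus": fields[6],
                "locus_id": fields[7],
            }
        )
    return rows


def catalogue_gff3(catalogue: Catalogue) -> str:
    lines = ["##gff-version 3", "# coordinates: 1-based inclusive"]
    for s in catalogue.ortholog_sets:
        for m in s.members:
            attrs = f"ID={m.locus_id};Name={s.epv_id};genus={m.assigned_genus}"
            lines.append(
                "\t".join(
                    [
                        f"{m.species}:{m.contig}", "epvmine", "mobile_genetic_element",
                        str(m.start + 1), str(m.end), ".", m.strand, ".", attrs,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def export_catalogue(
    catalogue: Catalogue,
    out_dir: Path,
    calibrations=None,
    coding=None,
) -> Dict[str, str]:
    """Write catalogue TSV/GFF3/FASTA (+ optional calibration and coding
    tables) atomically and return the manifest of SHA-256 checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: Dict[str, str] = {}

    _atomic_write(out_dir / "catalogue.tsv", catalogue_tsv(catalogue))
    files["catalogue.tsv"] = ""
    _atomic_write(out_dir / "catalogue.gff3", catalogue_gff3(catalogue))
    files["catalogue.gff3"] = ""

    fasta: Dict[str, str] = {}
    for s in catalogue.ortholog_sets:
        for m in s.members:
            fasta[f"{s.epv_id}|{m.species}"] = m.sequence
        if s.consensus:
            fasta[f"{s.epv_id}|consensus"] = s.consensus
    write_fasta(out_dir / "epv_sets.fasta", fasta)
    files["epv_sets.fasta"] = ""

    if calibrations is not None:
        lines = ["epv_id\tn_carriers\tcrown_My\tstem_My\tat_root\tcongruent_flag"]
        for c in calibrations:
            lines.append(
                "\t".join(
                    [
                        c.epv_id,
                        str(len(c.carrier_species)),
                        "NA" if c.min_age is None else f"{c.min_age:.4f}",
                        "NA" if c.upper_bound is None else f"{c.upper_bound:.4f}",
                        str(c.at_root),
                        "NA",
                    ]
                )
            )
        _atomic_write(out_dir / "calibrations.tsv", "\n".join(lines) + "\n")
        files["calibrations.tsv"] = ""

    if coding is not None:
        _atomic_write(out_dir / "coding_report.tsv", coding.to_csv(sep="\t", index=False))
        files["coding_report.tsv"] = ""

    for name in files:
        files[name] = hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
    _atomic_write(out_dir / "manifest.json", json.dumps(files, indent=1) + "\n")
    return files
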
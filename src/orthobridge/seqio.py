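"""Protein sequence containers and FASTA / manifest I/O.

The search universe is a set of proteomes, one per species, where every
protein-coding gene is represented by a single protein sequence.  Species
tags are never parsed out of FASTA headers; they come from the file name or
from an explicit tab-separated manifest (``species<TAB>path``), which keeps
runs reproducible across header dialects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: The twenty canonical residues.  ``X`` (unknown/ambiguous) is additionally
#: permitted in input; it aligns with the matrix X row and is excluded from
#: compositional statistics.
CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED = CANONICAL | {"X"}


class FastaFormatError(ValueError):
    """Raised for empty files, duplicate ids or non-amino-acid residues."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein: unique accession, species tag and residue string.

    Coordinates reported anywhere downstream (motif anchors, PEST regions,
    alignment spans) are 1-based inclusive.
    """

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - ALLOWED
        if bad:
            raise FastaFormatError(
                f"sequence {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Proteome:
    """All proteins of one species, indexed by accession."""

    species: str
    records: List[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaFormatError(
                    f"proteome {self.species!r}: duplicate id {rec.id!r}"
                )
            seen.add(rec.id)

    @property
    def total_residues(self) -> int:
        return sum(len(r) for r in self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return any(r.id == rec_id for r in self.records)

    def get(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


def _sanitize(raw: str, rec_id: str) -> str:
    """Upper-case and map non-canonical amino-acid codes to X.

    Selenocysteine (U), pyrrolysine (O) and the ambiguity codes B/Z/J are
    folded into X so compositional statistics only count known residues.
    Anything else (digits, ``*``, ``-``) is an error.
    """
    seq = raw.upper()
    out = []
    for ch in seq:
        if ch in ALLOWED:
            out.append(ch)
        elif ch in "UOBZJ":
            out.append("X")
        else:
            raise FastaFormatError(
                f"sequence {rec_id!r}: non-amino-acid character {ch!r}"
            )
    return "".join(out)


def read_fasta(path: os.PathLike | str, species: Optional[str] = None) -> Proteome:
    """Read one species' proteome from a FASTA file.

    The header token before the first whitespace becomes the record id.
    ``species`` defaults to the file's stem.
    """
    path = Path(path)
    if species is None:
        species = path.stem
    records: List[SequenceRecord] = []
    ids: set = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id = entry.id
        if rec_id in ids:
            raise FastaFormatError(f"{path}: duplicate id {rec_id!r}")
        ids.add(rec_id)
        residues = _sanitize(str(entry.seq), rec_id)
        records.append(SequenceRecord(id=rec_id, species=species, residues=residues))
    if not records:
        raise FastaFormatError(f"{path}: empty or not FASTA-formatted")
    return Proteome(species=species, records=records)


def write_fasta(proteome: Proteome | Iterable[SequenceRecord],
                path: os.PathLike | str, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    records = proteome.records if isinstance(proteome, Proteome) else list(proteome)
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_manifest(path: os.PathLike | str) -> Dict[str, Proteome]:
    """Read a TSV manifest mapping species tag to FASTA path.

    Relative paths resolve against the manifest's directory.  Returns an
    ordered ``{species: Proteome}`` mapping.
    """
    path = Path(path)
    universe: Dict[str, Proteome] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'species<TAB>path'")
            species, fasta = parts
            if species in universe:
                raise ValueError(f"{path}:{lineno}: duplicate species {species!r}")
            fasta_path = Path(fasta)
            if not fasta_path.is_absolute():
                fasta_path = path.parent / fasta_path
            universe[species] = read_fasta(fasta_path, species=species)
    if not universe:
        raise ValueError(f"{path}: empty manifest")
    return universe


def write_manifest(universe: Dict[str, Proteome], outdir: os.PathLike | str) -> Path:
    """Write one FASTA per species plus a ``proteomes.tsv`` manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "proteomes.tsv"
    with open(manifest, "w") as fh:
        for species, prot in universe.items():
            fasta = outdir / f"{species}.fasta"
            write_fasta(prot, fasta)
            fh.write(f"{species}\t{fasta.name}\n")
    return manifest
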
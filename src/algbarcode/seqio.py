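"""Sequence records and FASTA input/output.

Sequences are stored as uppercase IUPAC nucleotide strings.  Species labels
travel in FASTA headers using a configurable ``id<delim>species`` convention
(default delimiter ``|``), e.g. ``LBA27|Chlorella sorokiniana``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "IUPAC_SETS",
    "MARKERS",
    "SeqRecord",
    "read_fasta",
    "write_fasta",
]

#: Nucleotide sets encoded by each IUPAC one-letter code.  U is an alias of T.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),  # inosine, matches anything (used in primers)
}

MARKERS = ("nuITS1", "nuITS2", "5.8S", "ITS-full", "rbcL", "unknown")

_VALID_CHARS = frozenset(IUPAC_SETS) | {"-"}


def _validate_sequence(seq: str, *, where: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{where}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in _VALID_CHARS:
            raise ValueError(
                f"{where}: invalid character {ch!r} at position {pos + 1} "
                "(not an IUPAC nucleotide code)"
            )


@dataclass(frozen=True)
class SeqRecord:
    """One labeled marker sequence (query strain or reference entry).

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    sequence : str
        IUPAC nucleotide string; uppercased on construction.  ``-`` is
        permitted only in aligned contexts.
    species : str, optional
        Species label, when known (reference entries carry one).
    marker : str
        One of :data:`MARKERS`.
    """

    id: str
    sequence: str
    species: str | None = None
    marker: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _validate_sequence(self.sequence, where=f"record {self.id!r}")
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> "SeqRecord":
        return replace(self, sequence=self.sequence.replace("-", ""))

    def with_marker(self, marker: str) -> "SeqRecord":
        return replace(self, marker=marker)


def read_fasta(
    path: str | Path,
    *,
    species_delim: str | None = "|",
    marker: str = "unknown",
    normalize_u: bool = True,
) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    The species label is parsed from the header with ``species_delim``
    (``>id|species``); pass ``species_delim=None`` to disable parsing.
    RNA input is normalised to DNA (U -> T) unless ``normalize_u=False``.

    Raises
    ------
    ValueError
        On an empty file, duplicate ids, or non-IUPAC characters (the
        offending character and its record/position are named).
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        species = None
        rid = header.split()[0] if header else entry.id
        if species_delim and species_delim in header:
            rid, species = (part.strip() for part in header.split(species_delim, 1))
        seq = str(entry.seq).upper()
        if normalize_u:
            seq = seq.replace("U", "T")
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        records.append(SeqRecord(id=rid, sequence=seq, species=species, marker=marker))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[SeqRecord],
    path: str | Path,
    *,
    species_delim: str = "|",
    width: int = 70,
) -> None:
    """Write records to FASTA, re-encoding species labels in the header."""
    bio_records = []
    for rec in records:
        rid = rec.id if rec.species is None else f"{rec.id}{species_delim}{rec.species}"
        bio_records.append(_BioRecord(Seq(rec.sequence), id=rid, description=""))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio_records)


def as_dict(records: Sequence[SeqRecord]) -> dict[str, SeqRecord]:
    """Index records by id, enforcing uniqueness."""
    out: dict[str, SeqRecord] = {}
    for rec in records:
        if rec.id in out:
            raise ValueError(f"duplicate record id {rec.id!r}")
        out[rec.id] = rec
    return out
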
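"""Sequence containers and FASTA I/O.

The toolkit works on two lightweight containers: :class:`SequenceRecord`
(a named sequence with a declared alphabet) and :class:`Alignment`
(equal-length records with column semantics).  FASTA parsing and writing
go through Biopython's ``SeqIO``; the containers here only add the
alphabet checks that downstream distance and dating code relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_CHARS = set("ACGTN-")
# IUPAC ambiguity codes are accepted on input (consensus output uses them)
# but are treated as missing data by the distance engine.
IUPAC_AMBIGUITY = set("RYSWKMBDHV")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")


class FastaFormatError(ValueError):
    """Raised when a FASTA file cannot be parsed (names the offending line)."""


class AlphabetError(ValueError):
    """Raised when residues fall outside the declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence.

    Parameters
    ----------
    id:
        Non-empty label (FASTA header up to the first whitespace).
    residues:
        Upper-case residue string.  For nucleotide records the permitted
        characters are A, C, G, T, N, ``-`` plus IUPAC ambiguity codes.
    description:
        Free text (remainder of the FASTA header).
    alphabet:
        ``"nucleotide"`` or ``"protein"``.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"SequenceRecord {self.id!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())
        if self.alphabet == "nucleotide":
            allowed = NUCLEOTIDE_CHARS | IUPAC_AMBIGUITY
        elif self.alphabet == "protein":
            allowed = PROTEIN_CHARS
        else:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        bad = set(self.residues) - allowed
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """Equal-length sequence records; columns are homologous positions."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("Alignment needs at least one record")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal record lengths in alignment: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are upper-cased; record order follows the file.  A file that
    contains no records, or sequence data before the first header, raises
    :class:`FastaFormatError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise FastaFormatError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise FastaFormatError(
                f"{path}: line 1 does not start a FASTA header: {first.strip()!r}"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise FastaFormatError(f"{path}: record {rec.id!r} has no sequence")
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq),
                description=rec.description[len(rec.id):].strip(),
                alphabet=alphabet,
            )
        )
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA (fixed line wrap; content round-trips)."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_alignment(path: str | Path, alphabet: str = "nucleotide") -> Alignment:
    """Read an aligned FASTA file; all records must share one length."""
    return Alignment(read_fasta(path, alphabet=alphabet))
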
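"""FASTA input/output and the genome sequence model.

A genome is one FASTA file; a multi-record file (contigs, chromosomes,
plasmids) is treated as ONE genome. Residues are normalized to the
alphabet {A, C, G, T, N}: lowercase is folded to uppercase and every
IUPAC ambiguity code other than A/C/G/T becomes N. Words never span
record boundaries, so contigs cannot create chimeric words.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideSequence",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]

_ALPHABET = frozenset("ACGTN")
# letters that plausibly occur in nucleotide FASTA (IUPAC codes + U + gap-ish)
_NUCLEOTIDE_LETTERS = frozenset("ACGTUNRYSWKMBDHV")

_NORMALIZE = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}
)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised when an input file is not usable nucleotide FASTA."""


@dataclass
class NucleotideSequence:
    """A named DNA sequence made of one or more records.

    Parameters
    ----------
    name
        Genome label, unique within one input set (for files, the file stem).
    records
        Ordered residue strings over {A, C, G, T, N}; one per FASTA record.
    record_names
        Original FASTA record identifiers, kept as metadata.
    """

    name: str
    records: list[str]
    record_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        if not self.records or all(len(r) == 0 for r in self.records):
            raise ValueError(f"sequence {self.name!r} has no residues")
        for r in self.records:
            bad = set(r) - _ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {self.name!r} contains characters outside "
                    f"{{A,C,G,T,N}}: {sorted(bad)}"
                )
        if not self.record_names:
            self.record_names = [
                f"{self.name}_{i}" for i in range(len(self.records))
            ]

    @property
    def total_length(self) -> int:
        """Total number of residues over all records (N included)."""
        return sum(len(r) for r in self.records)

    def __len__(self) -> int:
        return self.total_length

    @classmethod
    def from_raw(
        cls,
        name: str,
        records: Iterable[str],
        record_names: Iterable[str] | None = None,
    ) -> "NucleotideSequence":
        """Build a sequence from raw residue strings, normalizing them."""
        normed = [normalize_residues(r) for r in records]
        return cls(name, normed, list(record_names or []))


def normalize_residues(s: str) -> str:
    """Case-fold and map non-ACGT letters to N."""
    return s.upper().translate(_NORMALIZE)


def reverse_complement(s: str) -> str:
    """Reverse complement of a residue string over {A,C,G,T,N}; N maps to N.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def _open_text(path: Path) -> io.TextIOBase:
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path: str | Path) -> NucleotideSequence:
    """Read one genome from a (possibly gzipped) FASTA file.

    The genome name is the file stem; record headers are kept as metadata.
    Raises :class:`FastaFormatError` for empty files, files without records,
    or files whose letters do not look like nucleotides (e.g. protein FASTA).
    """
    path = Path(path)
    name = path.stem
    if name.endswith(".fasta") or name.endswith(".fa") or name.endswith(".fna"):
        name = Path(name).stem
    records: list[str] = []
    record_names: list[str] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            raw = str(rec.seq)
            if not raw:
                continue
            letters = raw.upper()
            n_nuc = sum(letters.count(c) for c in _NUCLEOTIDE_LETTERS)
            if n_nuc < 0.9 * len(letters):
                raise FastaFormatError(
                    f"{path}: record {rec.id!r} does not look like a "
                    "nucleotide sequence (too many non-IUPAC-DNA letters)"
                )
            records.append(normalize_residues(raw))
            record_names.append(rec.id)
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records with residues found")
    return NucleotideSequence(name=name, records=records, record_names=record_names)


def write_fasta(seq: NucleotideSequence, path: str | Path, width: int = 70) -> Path:
    """Write a genome to FASTA, one record per stored record."""
    path = Path(path)
    recs = [
        SeqRecord(Seq(r), id=rid, description="")
        for r, rid in zip(seq.records, seq.record_names)
    ]
    with open(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(recs)
    return path
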
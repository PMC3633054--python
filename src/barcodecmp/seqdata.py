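"""Sequence containers, FASTA I/O and dataset quality reporting.

A barcode dataset is an ordered collection of labelled DNA sequences; the
quality report summarises what matters for compression-based analysis:
how many sequences contain characters outside {A,C,G,T} (on such input a
DNA-optimised compressor degrades to generic byte coding) and the spread
of ungapped sequence lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

__all__ = ["Sequence", "SequenceSet", "QCReport", "read_fasta", "write_fasta", "dataset_qc"]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Sequence:
    """A labelled DNA sequence, optionally annotated with its species."""

    label: str
    residues: str
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("sequence label must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.label!r} has no residues")

    @property
    def ungapped(self) -> str:
        """Residues with alignment gaps removed (raw barcode string)."""
        return self.residues.replace("-", "")

    def has_undefined(self) -> bool:
        """True if any residue (after uppercasing) is outside {A,C,G,T}.

        Gap characters and IUPAC ambiguity codes all count as undefined:
        they have the same degrading effect on a DNA dictionary compressor
        as the 'N' character.
        """
        return not _ACGT.issuperset(self.residues.upper())


@dataclass
class SequenceSet:
    """Ordered set of sequences with unique labels."""

    sequences: list[Sequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.sequences:
            if s.label in seen:
                raise ValueError(f"duplicate sequence label: {s.label!r}")
            seen.add(s.label)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> Sequence:
        return self.sequences[i]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sequences]

    @property
    def is_aligned(self) -> bool:
        """True iff all residue strings have identical length."""
        lengths = {len(s.residues) for s in self.sequences}
        return len(lengths) == 1


@dataclass(frozen=True)
class QCReport:
    n_species: int
    n_specimens: int
    pct_with_undefined: float
    min_length: int
    max_length: int

    def as_tsv(self) -> str:
        header = "n_species\tn_specimens\tpct_with_undefined\tmin_length\tmax_length"
        row = (
            f"{self.n_species}\t{self.n_specimens}\t"
            f"{self.pct_with_undefined:.1f}\t{self.min_length}\t{self.max_length}"
        )
        return header + "\n" + row


def read_fasta(path, species_delimiter: Optional[str] = None) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    Record order is preserved and the full header line (up to the first
    whitespace) becomes the label.  If *species_delimiter* is given, the
    label is split on it and the trailing part is stored as the species.
    """
    path = Path(path)
    sequences: list[Sequence] = []
    label: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if label is None:
            return
        residues = "".join(chunks)
        species = None
        if species_delimiter and species_delimiter in label:
            species = label.split(species_delimiter, 1)[1]
        sequences.append(Sequence(label=label, residues=residues, species=species))

    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                label = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if label is None:
                    raise ValueError(f"{path}: sequence data before first FASTA header")
                chunks.append(line)
        flush()
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    return SequenceSet(sequences)


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            fh.write(f">{s.label}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def dataset_qc(seqs: SequenceSet) -> QCReport:
    """Quality summary of a barcode dataset.

    ``pct_with_undefined`` is the percentage of sequences containing at
    least one character outside {A,C,G,T}; lengths are over ungapped
    residues.
    """
    if len(seqs) == 0:
        raise ValueError("cannot QC an empty sequence set")
    n_undef = sum(1 for s in seqs if s.has_undefined())
    lengths = [len(s.ungapped) for s in seqs]
    species = {s.species for s in seqs if s.species is not None}
    return QCReport(
        n_species=len(species) if species else len(seqs),
        n_specimens=len(seqs),
        pct_with_undefined=100.0 * n_undef / len(seqs),
        min_length=min(lengths),
        max_length=max(lengths),
    )
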
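"""Genome sequence container and FASTA I/O.

Sequences are held in memory as uppercase strings over the alphabet
ACGTN; any other character is mapped to N on input.  All coordinates in
the package are 0-based half-open; ``fetch`` returns the strand-correct
subsequence (reverse complement for '-').
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uppercase + map anything outside ACGTN to N
_NORMALIZE = {i: "N" for i in range(256)}
for _c in "ACGTN":
    _NORMALIZE[ord(_c)] = _c
    _NORMALIZE[ord(_c.lower())] = _c
_NORMALIZE = str.maketrans(_NORMALIZE)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map non-ACGTN characters to N."""
    return seq.translate(_NORMALIZE)


@dataclass
class GenomeSequences:
    """Mapping chromosome name -> uppercase nucleotide string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-correct subsequence of ``[start, end)`` on ``chrom``."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self.sequences[chrom])
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} (length {n})"
            )
        sub = self.sequences[chrom][start:end]
        if strand == "+":
            return sub
        if strand == "-":
            return reverse_complement(sub)
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def read_fasta(path: str | Path) -> GenomeSequences:
    """Load a FASTA file into a :class:`GenomeSequences`.

    Raises on missing files, empty records and duplicate names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate chromosome name {record.id!r} in {path}")
        seq = normalize_sequence(str(record.seq))
        if not seq:
            raise ValueError(f"empty record {record.id!r} in {path}")
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequences(sequences)


def write_fasta(
    sequences: Mapping[str, str] | GenomeSequences,
    path: str | Path,
    width: int = 80,
) -> None:
    """Write sequences as FASTA with fixed line width (deterministic output)."""
    if isinstance(sequences, GenomeSequences):
        sequences = sequences.sequences
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
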
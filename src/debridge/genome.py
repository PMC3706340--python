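"""Genome container and FASTA I/O.

The reconstruction target throughout this package is a single *circular* DNA
sequence over {A, C, G, T}; linear sequences are supported for repeat
statistics (boundary copies are treated as flanked by a unique sentinel).
Coordinates are 0-based and, on circular genomes, taken mod G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_ALPHASET = frozenset(ALPHABET)


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


@dataclass(frozen=True)
class Genome:
    """A DNA sequence with an explicit topology.

    Parameters
    ----------
    sequence:
        Uppercase string over {A, C, G, T}.
    topology:
        ``"circular"`` (default; the reconstruction target is a cycle) or
        ``"linear"``.
    """

    sequence: str
    topology: str = "circular"
    name: str = field(default="genome", compare=False)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        seq = self.sequence
        if not seq:
            raise ValueError("empty genome")
        if not _ALPHASET.issuperset(seq):
            bad = sorted(set(seq) - _ALPHASET)
            raise InvalidAlphabetError(f"non-ACGT characters in sequence: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def substr(self, start: int, length: int) -> str:
        """Length-``length`` subsequence starting at ``start`` (mod G if circular)."""
        G = len(self.sequence)
        if self.circular:
            start %= G
            if start + length <= G:
                return self.sequence[start : start + length]
            reps = (start + length - G + G - 1) // G
            return (self.sequence + self.sequence * reps)[start : start + length]
        if start < 0 or start + length > G:
            raise IndexError("substring out of range on linear genome")
        return self.sequence[start : start + length]

    def base(self, pos: int) -> str:
        """Single base at ``pos`` (mod G if circular)."""
        if self.circular:
            return self.sequence[pos % len(self.sequence)]
        return self.sequence[pos]

    def rotate(self, k: int) -> "Genome":
        """Rotation starting at offset ``k`` (circular genomes only)."""
        if not self.circular:
            raise ValueError("rotation is defined only for circular genomes")
        k %= len(self.sequence)
        return Genome(self.sequence[k:] + self.sequence[:k], "circular", self.name)


def rotations_equal(a: str, b: str) -> bool:
    """True iff ``a`` and ``b`` are rotations of each other."""
    return len(a) == len(b) and b in a + a


def load_fasta(path, topology: str = "circular", split_on_n: bool = False):
    """Load a genome from a single-record FASTA file.

    Sequences are uppercased.  Ambiguity codes are rejected by default; with
    ``split_on_n=True`` the record is split on runs of ``N`` and a list of
    linear contigs is returned instead of a single genome.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if split_on_n:
        contigs = [c for c in seq.replace("N", " ").split() if c]
        return [
            Genome(c, "linear", f"{rec.id}.contig{i}") for i, c in enumerate(contigs)
        ]
    return Genome(seq, topology, rec.id or "genome")


def write_fasta(genome: Genome, path, description: str = "") -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description=description)
    SeqIO.write([rec], str(path), "fasta")
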
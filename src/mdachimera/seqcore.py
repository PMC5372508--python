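"""Elementary sequence types and formulas.

Sequences are plain Python strings over the alphabet {A, C, G, T, N};
lowercase (soft-masked) input is uppercased on normalization and any other
character is rejected. Genomic coordinates are 0-based half-open internally;
file writers emit 1-based inclusive coordinates and say so in a header line.

Two small formulas recur throughout the package:

* the Wallace-Itakura rule for the denaturation temperature of a short
  duplex, Td = 4(C+G) + 2(A+T) in deg C, equivalently L*(2 + 2*gc) for an
  average composition of length L and GC fraction gc;
* the effective chromosome length, the number of determined (non-N) bases,
  used wherever counts are normalized by how much sequence was searchable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
_VALID_TABLE = str.maketrans("", "", "ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class CompositionError(ValueError):
    """A composition is requested for an empty or N-containing sequence."""


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and reject anything outside the ACGTN alphabet."""
    up = seq.upper()
    if up.translate(_VALID_TABLE):
        bad = sorted(set(up) - ALPHABET)
        raise AlphabetError(f"invalid characters in sequence: {bad!r}")
    return up


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N.

    An involution: applying it twice returns the input.
    """
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class SequenceComposition:
    """Base counts of an N-free sequence (the symbols of the Wallace rule)."""

    count_a: int
    count_c: int
    count_g: int
    count_t: int

    def __post_init__(self) -> None:
        if min(self.count_a, self.count_c, self.count_g, self.count_t) < 0:
            raise CompositionError("negative base count")

    @classmethod
    def from_sequence(cls, seq: str) -> "SequenceComposition":
        s = normalize_sequence(seq)
        if not s:
            raise CompositionError("empty sequence has no composition")
        if "N" in s:
            raise CompositionError("sequence with N has no composition")
        return cls(s.count("A"), s.count("C"), s.count("G"), s.count("T"))

    @property
    def length(self) -> int:
        return self.count_a + self.count_c + self.count_g + self.count_t

    @property
    def gc_fraction(self) -> float:
        if self.length == 0:
            raise CompositionError("GC fraction of zero-length composition")
        return (self.count_c + self.count_g) / self.length

    def __add__(self, other: "SequenceComposition") -> "SequenceComposition":
        return SequenceComposition(
            self.count_a + other.count_a,
            self.count_c + other.count_c,
            self.count_g + other.count_g,
            self.count_t + other.count_t,
        )


def gc_fraction(seq: str) -> float:
    """(G+C)/length of a non-empty, N-free sequence."""
    return SequenceComposition.from_sequence(seq).gc_fraction


def wallace_td(comp: SequenceComposition) -> float:
    """Wallace-Itakura denaturation temperature, Td = 4(C+G) + 2(A+T) deg C."""
    if comp.length == 0:
        raise CompositionError("Td undefined for zero-length composition")
    return 4.0 * (comp.count_c + comp.count_g) + 2.0 * (comp.count_a + comp.count_t)


def wallace_td_from_length_gc(length: float, gc: float) -> float:
    """Wallace rule applied to an average composition: Td = L*(2 + 2*gc).

    This is the form used for per-overlap-length summary rows, where only the
    mean GC fraction of the group is known.
    """
    if length <= 0:
        raise CompositionError("Td undefined for non-positive length")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc fraction {gc} outside [0, 1]")
    return length * (2.0 + 2.0 * gc)


def effective_length(seq: str) -> int:
    """Number of determined (non-N) bases."""
    s = normalize_sequence(seq)
    return len(s) - s.count("N")


_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeReference:
    """Named chromosome sequences over {A, C, G, T, N}.

    The template for hotspot screening and read mapping. Chromosome order is
    preserved (insertion order of the mapping / FASTA record order).
    """

    def __init__(self, chromosomes: Mapping[str, str]):
        if not chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        self._chroms: dict[str, str] = {
            name: normalize_sequence(seq) for name, seq in chromosomes.items()
        }

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._chroms.items())

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def sequence(self, name: str) -> str:
        return self._chroms[name]

    def raw_length(self, name: str) -> int:
        return len(self._chroms[name])

    def effective_length(self, name: str) -> int:
        return effective_length(self._chroms[name])

    @property
    def total_effective_length(self) -> int:
        return sum(self.effective_length(n) for n in self.names)

    def fetch(self, interval: GenomicInterval) -> str:
        """Sense-strand sequence of ``interval`` (strand ignored)."""
        seq = self._chroms[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(f"interval {interval} beyond chromosome end")
        return seq[interval.start : interval.end]

    def oriented_sequence(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval`` read 5'->3' on its own strand."""
        s = self.fetch(interval)
        return s if interval.strand == "+" else reverse_complement(s)

    @classmethod
    def from_fasta(cls, path) -> "GenomeReference":
        chroms: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            chroms[rec.id] = str(rec.seq)
        return cls(chroms)

    def to_fasta(self, path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self
        ]
        with open(path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
            writer.write_file(records)
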
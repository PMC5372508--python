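"""Seed-and-extend recognition of inverted-segment MDA chimeras in reads.

A 1-level inverted chimera is a read made of two segments mapped to opposite
strands of the same chromosome, joined at a breakpoint where the tail of the
former (5') segment and the head of the following (3') segment share a short
overlap whose two genomic occurrences are reverse-complementary on the sense
strand.

The pipeline, per read:

1. reads containing N are removed;
2. reads with an exact full-length genome occurrence (either strand) are
   discarded - they are ordinary reads, not chimera candidates;
3. the 30-nt 5' seed of each remaining read is looked up exactly on both
   strands; reads whose seed has no hit are dropped;
4. each seed hit is extended base by base along the read until the first
   mismatch, giving the former segment and the breakpoint; the hit with the
   longest extension wins (ties: '+' strand, then lowest coordinate);
5. the post-breakpoint suffix is located as an exact match on the opposite
   strand within ``window`` (default 5000 nt) of the breakpoint locus,
   choosing the candidate with the smallest |distance| (ties: lowest
   coordinate);
6. the overlap is reconstructed by reverse extension: the following segment
   is grown backwards (in read orientation) along the genome while it keeps
   matching the tail of the former segment.

Mapping is exact by design (an internal k-mer index stands in for an
external aligner); mismatch tolerance is not applied, which makes the whole
pipeline deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqcore import (
    GenomeReference,
    GenomicInterval,
    normalize_sequence,
    reverse_complement,
)

logger = logging.getLogger(__name__)

DEFAULT_SEED_LENGTH = 30
DEFAULT_WINDOW = 5000
DEFAULT_MIN_FOLLOWING = 10


@dataclass(frozen=True)
class ReadRecord:
    """One single-end read. Mates are processed independently."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))


@dataclass(frozen=True)
class SeedHit:
    """Exact placement of a read's 5'-terminal seed on the genome."""

    read_id: str
    interval: GenomicInterval  # genome footprint of the seed
    seed_length: int


@dataclass(frozen=True)
class ChimeraRecord:
    """One detected 1-level inverted chimera.

    ``former`` and ``following`` are the genome footprints of the two read
    segments, both including the overlap; they lie on opposite strands of the
    same chromosome. ``overlap_seq`` is the overlap as it appears in the read
    (zero length is a valid, overlap-free junction). ``distance`` is the
    signed gap between the two genomic occurrences of the overlap, positive
    when the following occurrence lies beyond the former one in read
    direction; histograms report |distance|.
    """

    read_id: str
    former: GenomicInterval
    following: GenomicInterval
    overlap_seq: str
    distance: int
    level: int = 1
    type: str = "inverted"

    def __post_init__(self) -> None:
        if self.former.chrom != self.following.chrom:
            raise ValueError("chimera segments must share a chromosome")
        if self.former.strand == self.following.strand:
            raise ValueError("inverted chimera segments must be on opposite strands")

    @property
    def overlap_length(self) -> int:
        return len(self.overlap_seq)


@dataclass
class RecognitionStats:
    """Funnel counts of the recognition pipeline, one per filtering stage."""

    reads_in: int = 0
    with_n: int = 0
    full_length_mapped: int = 0
    seed_unmapped: int = 0
    no_following_match: int = 0
    chimeras: int = 0
    dropped_other: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def filter_reads_with_n(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Keep exactly the reads whose sequences contain no N."""
    return [r for r in reads if "N" not in r.sequence]


class GenomeIndex:
    """Exact-match k-mer index of the forward strand of every chromosome.

    Reverse-strand queries are answered by looking up the reverse complement
    of the query. Stands in for an external short-read aligner; lookups are
    exact (0 mismatches).
    """

    def __init__(self, genome: GenomeReference, k: int = DEFAULT_SEED_LENGTH):
        if k < 1:
            raise ValueError("index k-mer length must be >= 1")
        self.genome = genome
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome:
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((name, pos))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Forward-strand occurrences (chrom, start) of an exact k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != index k {self.k}")
        return self._index.get(kmer, [])


def build_genome_index(
    genome: GenomeReference, k: int = DEFAULT_SEED_LENGTH
) -> GenomeIndex:
    return GenomeIndex(genome, k)


def map_full_read(read: ReadRecord, index: GenomeIndex) -> list[GenomicInterval]:
    """All exact full-length occurrences of the read on either strand."""
    seq = read.sequence
    if "N" in seq:
        raise ValueError("full-read mapping requires an N-free read")
    hits: list[GenomicInterval] = []
    if len(seq) < index.k:
        return hits
    for strand, query in (("+", seq), ("-", reverse_complement(seq))):
        for chrom, pos in index.lookup(query[: index.k]):
            genome_seq = index.genome.sequence(chrom)
            if genome_seq[pos : pos + len(query)] == query:
                hits.append(GenomicInterval(chrom, pos, pos + len(query), strand))
    return hits


def extract_and_map_seed(
    read: ReadRecord, index: GenomeIndex, seed_length: int = DEFAULT_SEED_LENGTH
) -> list[SeedHit]:
    """Map the 5'-terminal seed of the read exactly, on both strands.

    A '+' hit means the read prefix matches the genome forward at the hit
    interval; a '-' hit means the prefix matches the reverse complement of
    the hit interval (the read runs leftward along the sense strand).
    """
    if len(read.sequence) < seed_length:
        raise ValueError(
            f"read {read.read_id} shorter than seed length {seed_length}"
        )
    if seed_length != index.k:
        raise ValueError("seed length must equal the index k-mer length")
    seed = read.sequence[:seed_length]
    hits = [
        SeedHit(read.read_id, GenomicInterval(c, p, p + seed_length, "+"), seed_length)
        for c, p in index.lookup(seed)
    ]
    for c, p in index.lookup(reverse_complement(seed)):
        hits.append(
            SeedHit(read.read_id, GenomicInterval(c, p, p + seed_length, "-"), seed_length)
        )
    return hits


def extend_seed(
    read: ReadRecord, genome: GenomeReference, hit: SeedHit
) -> tuple[GenomicInterval, int]:
    """Extend a seed hit along the read until the first mismatch.

    Returns the former segment's genome interval and the breakpoint: the
    read offset of the first mismatching base (== read length when the whole
    read matches, i.e. the read is not chimeric). Extension that runs off
    the chromosome end simply stops there.
    """
    seq = read.sequence
    genome_seq = genome.sequence(hit.interval.chrom)
    j = hit.seed_length
    if hit.interval.strand == "+":
        start = hit.interval.start
        while j < len(seq) and start + j < len(genome_seq) and genome_seq[start + j] == seq[j]:
            j += 1
        return GenomicInterval(hit.interval.chrom, start, start + j, "+"), j
    # '-' strand: read base j pairs with genome position end-1-j
    end = hit.interval.end
    while j < len(seq) and end - 1 - j >= 0 and genome_seq[end - 1 - j] == _COMP[seq[j]]:
        j += 1
    return GenomicInterval(hit.interval.chrom, end - j, end, "-"), j


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def locate_following_segment(
    read_suffix: str,
    genome: GenomeReference,
    former: GenomicInterval,
    window: int = DEFAULT_WINDOW,
    min_length: int = DEFAULT_MIN_FOLLOWING,
) -> GenomicInterval | None:
    """Place the post-breakpoint suffix on the strand opposite the former.

    The whole suffix must occur exactly, with its junction-side end within
    ``window`` of the former segment's breakpoint locus. Among candidates
    the smallest |distance| wins; ties go to the lower coordinate. Returns
    the suffix's genome interval (overlap not yet included) or None.
    """
    m = len(read_suffix)
    if m < min_length:
        return None
    seq = genome.sequence(former.chrom)
    if former.strand == "+":
        # following on '-': suffix == revcomp(genome segment); its junction
        # anchor is the segment's sense END coordinate.
        target = reverse_complement(read_suffix)
        anchor0 = former.end
        strand = "-"
    else:
        target = read_suffix
        anchor0 = former.start
        strand = "+"
    lo = max(0, anchor0 - window - m)
    hi = min(len(seq), anchor0 + window + m)
    best: tuple[int, int, GenomicInterval] | None = None
    q = seq.find(target, lo, hi)
    while q != -1:
        if strand == "-":
            dist = (q + m) - anchor0
        else:
            dist = anchor0 - q
        if -window <= dist <= window:
            cand = GenomicInterval(former.chrom, q, q + m, strand)
            key = (abs(dist), q)
            if best is None or key < best[:2]:
                best = (abs(dist), q, cand)
        q = seq.find(target, q + 1, hi)
    return best[2] if best is not None else None


def reconstruct_overlap(
    genome: GenomeReference,
    former: GenomicInterval,
    following: GenomicInterval,
) -> str:
    """Reverse-extend the following segment to recover the junction overlap.

    Starting from the following segment's junction-side boundary, grow it
    backwards (in read orientation) one nucleotide at a time while the added
    genome base still matches the tail of the former segment. The result is
    the overlap as read 5'->3' in the read; its two genomic occurrences are
    reverse-complementary on the sense strand. Length 0 is a valid result
    (overlap-free junction).
    """
    if former.chrom != following.chrom:
        raise ValueError("segments on different chromosomes")
    if former.strand == following.strand:
        raise ValueError("inverted chimera requires opposite strands")
    seq = genome.sequence(former.chrom)
    n = len(seq)
    cap = former.length
    m = 0
    if former.strand == "+":
        # former tail: seq[former.end-1-m]; candidate: complement of the base
        # just past the following segment's sense end.
        p0 = following.end
        while (
            m < cap
            and p0 + m < n
            and seq[p0 + m] == _COMP[seq[former.end - 1 - m]]
        ):
            m += 1
        return seq[former.end - m : former.end]
    # former on '-': its read tail is complement(seq[former.start + m]);
    # the following ('+') grows leftward from its sense start.
    t = following.start
    while (
        m < cap
        and t - 1 - m >= 0
        and seq[t - 1 - m] == _COMP[seq[former.start + m]]
    ):
        m += 1
    return reverse_complement(seq[former.start : former.start + m])


def _finalize_record(
    read: ReadRecord,
    genome: GenomeReference,
    former: GenomicInterval,
    following_pre: GenomicInterval,
    window: int,
) -> ChimeraRecord | None:
    overlap = reconstruct_overlap(genome, former, following_pre)
    m = len(overlap)
    if former.strand == "+":
        following = GenomicInterval(
            following_pre.chrom, following_pre.start, following_pre.end + m, "-"
        )
        distance = (following_pre.end) - former.end  # occ2.start - occ1.end
    else:
        following = GenomicInterval(
            following_pre.chrom, following_pre.start - m, following_pre.end, "+"
        )
        distance = former.start - following_pre.start  # occ1.start - occ2.end
    if abs(distance) > window:
        return None
    record = ChimeraRecord(
        read_id=read.read_id,
        former=former,
        following=following,
        overlap_seq=overlap,
        distance=distance,
    )
    validate_record(record, genome)
    return record


def validate_record(record: ChimeraRecord, genome: GenomeReference) -> None:
    """Re-check the overlap invariant of an emitted record.

    The last ``overlap_length`` bases of the former segment and the first
    ``overlap_length`` bases of the following segment (both in read
    orientation) must be the two genomic occurrences of the overlap,
    reverse-complementary on the sense strand.
    """
    m = record.overlap_length
    if m == 0:
        return
    if record.former.strand == "+":
        occ1 = genome.fetch(
            GenomicInterval(record.former.chrom, record.former.end - m, record.former.end)
        )
        occ2 = genome.fetch(
            GenomicInterval(
                record.following.chrom,
                record.following.end - m,
                record.following.end,
            )
        )
        if occ1 != record.overlap_seq:
            raise AssertionError("former overlap occurrence mismatch")
    else:
        occ1 = genome.fetch(
            GenomicInterval(
                record.former.chrom, record.former.start, record.former.start + m
            )
        )
        occ2 = genome.fetch(
            GenomicInterval(
                record.following.chrom,
                record.following.start,
                record.following.start + m,
            )
        )
        if reverse_complement(occ1) != record.overlap_seq:
            raise AssertionError("former overlap occurrence mismatch")
    if occ2 != reverse_complement(occ1):
        raise AssertionError("overlap occurrences are not reverse-complementary")


def _best_extension(
    read: ReadRecord, genome: GenomeReference, hits: Sequence[SeedHit]
) -> tuple[GenomicInterval, int]:
    """Longest former segment wins; ties: '+' strand, then lowest coordinate."""
    chrom_rank = {name: i for i, name in enumerate(genome.names)}
    best = None
    best_key = None
    for hit in hits:
        former, junction = extend_seed(read, genome, hit)
        key = (
            -junction,
            0 if former.strand == "+" else 1,
            chrom_rank[former.chrom],
            former.start,
        )
        if best_key is None or key < best_key:
            best, best_key = (former, junction), key
    return best


def recognize_chimeras(
    reads: Iterable[ReadRecord],
    genome: GenomeReference,
    *,
    index: GenomeIndex | None = None,
    seed_length: int = DEFAULT_SEED_LENGTH,
    window: int = DEFAULT_WINDOW,
    min_following: int = DEFAULT_MIN_FOLLOWING,
    return_stats: bool = False,
):
    """Run the full recognition pipeline.

    Returns the list of :class:`ChimeraRecord` (one per read passing every
    stage), or ``(records, stats)`` when ``return_stats`` is true. Output is
    deterministic and invariant to read input order (records are sorted by
    read_id).
    """
    if index is None:
        index = GenomeIndex(genome, seed_length)
    stats = RecognitionStats()
    records: list[ChimeraRecord] = []
    for read in reads:
        stats.reads_in += 1
        if "N" in read.sequence:
            stats.with_n += 1
            continue
        if len(read.sequence) < seed_length:
            stats.dropped_other += 1
            continue
        if map_full_read(read, index):
            stats.full_length_mapped += 1
            continue
        hits = extract_and_map_seed(read, index, seed_length)
        if not hits:
            stats.seed_unmapped += 1
            continue
        former, junction = _best_extension(read, genome, hits)
        if junction >= len(read.sequence):
            # whole read matched after all (cannot happen after full-length
            # filtering, kept as a guard)
            stats.full_length_mapped += 1
            continue
        suffix = read.sequence[junction:]
        following_pre = locate_following_segment(
            suffix, genome, former, window=window, min_length=min_following
        )
        if following_pre is None:
            stats.no_following_match += 1
            continue
        record = _finalize_record(read, genome, former, following_pre, window)
        if record is None:
            stats.no_following_match += 1
            continue
        records.append(record)
    records.sort(key=lambda r: r.read_id)
    stats.chimeras = len(records)
    logger.info(
        "recognition funnel: in=%d N=%d full-mapped=%d seed-unmapped=%d "
        "no-following=%d other=%d chimeras=%d",
        stats.reads_in,
        stats.with_n,
        stats.full_length_mapped,
        stats.seed_unmapped,
        stats.no_following_match,
        stats.dropped_other,
        stats.chimeras,
    )
    if return_stats:
        return records, stats
    return records
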
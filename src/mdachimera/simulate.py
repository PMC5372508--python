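"""Synthetic genomes, planted hotspots, and simulated chimeric/normal reads.

Everything downstream of this module is testable without downloads: the
generator builds a random genome, plants reverse-complementary pairs
(hotspots) with chosen overlap length and spacing, and emits 101-nt reads -
ordinary reads that are exact genome substrings, and chimeric reads carrying
a 1-level inverted junction built on a planted hotspot.

A chimeric read from a hotspot with seed occurrence O at [s0, s0+k) and
partner occurrence revcomp(O) at [p0, p0+k) is

    read = S[f : s0+k] + revcomp(S[q : p0])

i.e. the sense strand up to the end of the seed occurrence, then the
reverse complement of the region ending at the partner occurrence. The two
mapped segments, former [f, s0+k) on '+' and following [q, p0+k) on '-',
share exactly the k-nt overlap, whose genomic occurrences are O and
revcomp(O); the junction distance equals the planted hotspot distance
p0 - (s0+k).

Planted pairs are made *maximal*: the bases flanking the partner occurrence
are resampled so the pair cannot extend to k+1 by chance. Otherwise the
genome would genuinely contain a longer hotspot at the same locus and the
recorded truth (overlap length, breakpoint) would be wrong for ~1 read in 2.

Reads are simulated error-free: recognition uses exact matching, so
sequencing-error robustness is out of scope. A single seed in
:class:`SimulationConfig` governs all draws through named substreams, making
every output reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .hotspots import Hotspot
from .seqcore import GenomeReference, GenomicInterval, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHIMERIC_PREFIX = "chim"
_NORMAL_PREFIX = "norm"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the regime the pipeline is built for: a megabase-scale
    template, human-like GC, 101-nt error-free reads, junction overlaps of
    3-25 nt and junction distances up to 5 knt.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    gc_target: float = 0.41
    n_run_rate: float = 0.0
    n_run_mean_length: int = 50
    read_length: int = 101
    n_normal_reads: int = 1000
    n_chimeric_reads: int = 1000
    overlap_length_weights: Mapping[int, float] | None = None  # None: uniform 3..25
    distance_min: int = 1
    distance_max: int = 5000
    min_former_read_length: int = 31  # covers the 30-nt seed
    min_suffix_length: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError(f"gc_target {self.gc_target} outside [0, 1]")
        if not 0.0 <= self.n_run_rate <= 1.0:
            raise ValueError("n_run_rate outside [0, 1]")
        weights = self.resolved_overlap_weights()
        if min(weights) < 1:
            raise ValueError("overlap lengths must be >= 1")
        if any(w < 0 for w in weights.values()) or not any(weights.values()):
            raise ValueError("overlap weights must be >= 0 with one positive")
        if self.read_length < 2 * min(weights) + 2:
            raise ValueError("read_length too short to host both segments")
        if not 0 <= self.distance_min <= self.distance_max:
            raise ValueError("need 0 <= distance_min <= distance_max")

    def resolved_overlap_weights(self) -> dict[int, float]:
        if self.overlap_length_weights is None:
            return {k: 1.0 for k in range(3, 26)}
        return dict(self.overlap_length_weights)

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-purpose substream of the global seed."""
        tag = int.from_bytes(stream.encode("ascii")[:4].ljust(4, b"\0"), "big")
        return np.random.default_rng([self.rng_seed, tag])


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground truth for one simulated chimeric read."""

    read_id: str
    former: GenomicInterval
    following: GenomicInterval
    overlap_seq: str
    distance: int

    @property
    def overlap_length(self) -> int:
        return len(self.overlap_seq)


def _random_chromosome(
    length: int, gc: float, n_run_rate: float, n_run_mean: int, rng: np.random.Generator
) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    chars = _BASES[codes].copy()
    if n_run_rate > 0:
        target = int(round(n_run_rate * length))
        placed = int((chars == ord(b"N")) .sum())
        while placed < target:
            run = min(int(rng.geometric(1.0 / n_run_mean)), target - placed, length)
            start = int(rng.integers(0, max(1, length - run + 1)))
            before = int((chars[start : start + run] == ord(b"N")).sum())
            chars[start : start + run] = ord(b"N")
            placed += run - before
    return chars.tobytes().decode("ascii")


def generate_genome(config: SimulationConfig) -> GenomeReference:
    """Random i.i.d. genome at the configured GC, with optional N runs.

    ``genome_length`` is the total length, split evenly over
    ``n_chromosomes`` (named chr1, chr2, ...). Deterministic under
    ``rng_seed``.
    """
    rng = config.rng("genome")
    per = config.genome_length // config.n_chromosomes
    lengths = [per] * config.n_chromosomes
    lengths[-1] += config.genome_length - per * config.n_chromosomes
    chroms = {
        f"chr{i + 1}": _random_chromosome(
            n, config.gc_target, config.n_run_rate, config.n_run_mean_length, rng
        )
        for i, n in enumerate(lengths)
    }
    return GenomeReference(chroms)


def _random_kmer(k: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=k).astype(np.uint8)].tobytes().decode()


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _fix_flanks(buf: bytearray, s0: int, p0: int, k: int, rng: np.random.Generator) -> None:
    """Make the planted pair maximal: block extension to overlap k+1.

    The pair (O at s0, revcomp(O) at p0) extends iff the base after the
    partner complements the base before the seed, or the base before the
    partner complements the base after the seed. Both flanks adjusted lie
    outside the two occurrences (and outside the seed flanks), so fixing one
    pair never disturbs another planted pair's occurrences.
    """
    n = len(buf)
    if s0 >= 1 and p0 + k < n:
        banned = _COMP[chr(buf[s0 - 1])] if chr(buf[s0 - 1]) != "N" else None
        if banned is not None and chr(buf[p0 + k]) == banned:
            choices = [b for b in "ACGT" if b != banned]
            buf[p0 + k] = ord(choices[int(rng.integers(0, 3))])
    if p0 - 1 >= s0 + k and s0 + k < n:  # p0-1 == s0+k (d=1) is auto-safe
        banned = _COMP[chr(buf[s0 + k])] if chr(buf[s0 + k]) != "N" else None
        if banned is not None and chr(buf[p0 - 1]) == banned:
            choices = [b for b in "ACGT" if b != banned]
            buf[p0 - 1] = ord(choices[int(rng.integers(0, 3))])


def _plant_into(
    buf: bytearray,
    chrom: str,
    overlap_len: int,
    distance: int,
    position: int,
    rng: np.random.Generator,
    overlap_seq: str | None = None,
) -> Hotspot:
    k = overlap_len
    if overlap_seq is None:
        overlap_seq = _random_kmer(k, rng)
    elif len(overlap_seq) != k:
        raise ValueError("overlap_seq length disagrees with overlap_len")
    if k < 1 or distance < 0 or position < 0:
        raise ValueError("overlap_len >= 1, distance >= 0, position >= 0 required")
    p0 = position + k + distance
    if p0 + k > len(buf):
        raise ValueError("hotspot placement runs off the chromosome end")
    buf[position : position + k] = overlap_seq.encode("ascii")
    buf[p0 : p0 + k] = reverse_complement(overlap_seq).encode("ascii")
    _fix_flanks(buf, position, p0, k, rng)
    return Hotspot(
        chrom=chrom,
        seed=GenomicInterval(chrom, position, position + k),
        partner=GenomicInterval(chrom, p0, p0 + k),
        overlap_length=k,
        gc_fraction=(overlap_seq.count("G") + overlap_seq.count("C")) / k,
    )


def plant_hotspot(
    genome: GenomeReference,
    overlap_len: int,
    distance: int,
    position: int,
    chrom: str | None = None,
    overlap_seq: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeReference, Hotspot]:
    """Write a k-mer and its downstream reverse complement into the genome.

    Returns a new :class:`GenomeReference` (the input is unchanged) plus the
    induced :class:`Hotspot`. ``overlap_seq`` fixes the seed occurrence's
    sequence; by default a random k-mer is drawn from ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    name = chrom if chrom is not None else genome.names[0]
    chroms = {n: genome.sequence(n) for n in genome.names}
    buf = bytearray(chroms[name], "ascii")
    hotspot = _plant_into(buf, name, overlap_len, distance, position, rng, overlap_seq)
    chroms[name] = buf.decode("ascii")
    return GenomeReference(chroms), hotspot


def simulate_chimeric_read(
    genome: GenomeReference,
    hotspot: Hotspot,
    read_length: int = 101,
    breakpoint_offset: int | None = None,
    read_id: str = "chim",
) -> tuple[str, SimulatedTruth]:
    """Build one junction-spanning read from a planted hotspot.

    ``breakpoint_offset`` is the read length of the former segment
    (including the overlap); it must leave at least one former base beyond
    the overlap and at least one base for the following segment. Defaults to
    the midpoint. Raises if either segment would run off the chromosome or
    cover an N.
    """
    k = hotspot.overlap_length
    s0 = hotspot.seed.start
    p0 = hotspot.partner.start
    seq = genome.sequence(hotspot.chrom)
    if breakpoint_offset is None:
        breakpoint_offset = max(k + 1, read_length // 2)
    a = breakpoint_offset
    if not (k + 1 <= a <= read_length - 1):
        raise ValueError(
            f"breakpoint_offset {a} must lie in [{k + 1}, {read_length - 1}]"
        )
    f = s0 + k - a
    suffix_len = read_length - a
    q = p0 - suffix_len
    if f < 0 or q < 0:
        raise ValueError("hotspot too close to the chromosome edge for this read")
    former_part = seq[f : s0 + k]
    following_part = seq[q:p0]
    if "N" in former_part or "N" in following_part:
        raise ValueError("read would cover undetermined (N) bases")
    read = former_part + reverse_complement(following_part)
    truth = SimulatedTruth(
        read_id=read_id,
        former=GenomicInterval(hotspot.chrom, f, s0 + k, "+"),
        following=GenomicInterval(hotspot.chrom, q, p0 + k, "-"),
        overlap_seq=seq[s0 : s0 + k],
        distance=p0 - (s0 + k),
    )
    return read, truth


def simulate_normal_reads(
    genome: GenomeReference,
    n: int,
    read_length: int = 101,
    rng: np.random.Generator | None = None,
    max_tries: int = 1000,
) -> list[tuple[str, str]]:
    """Error-free contiguous reads from either strand, none spanning a junction.

    Returns (read_id, sequence) pairs. Chromosomes are sampled in proportion
    to length; draws covering N are rejected and resampled.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    names = genome.names
    lengths = np.array([genome.raw_length(c) for c in names], dtype=float)
    if (lengths < read_length).any():
        raise ValueError("every chromosome must be at least one read long")
    probs = lengths / lengths.sum()
    reads: list[tuple[str, str]] = []
    for i in range(n):
        for _ in range(max_tries):
            c = names[int(rng.choice(len(names), p=probs))]
            seq = genome.sequence(c)
            pos = int(rng.integers(0, len(seq) - read_length + 1))
            frag = seq[pos : pos + read_length]
            if "N" in frag:
                continue
            if rng.integers(0, 2):
                frag = reverse_complement(frag)
            reads.append((f"{_NORMAL_PREFIX}_{i:05d}", frag))
            break
        else:
            raise RuntimeError("could not draw an N-free read")
    return reads


@dataclass
class SimulatedDataset:
    """A genome, its reads (chimeric + normal), and the chimeric truth set."""

    config: SimulationConfig
    genome: GenomeReference
    reads: list[tuple[str, str]] = field(default_factory=list)
    truth: list[SimulatedTruth] = field(default_factory=list)
    hotspots: list[Hotspot] = field(default_factory=list)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full synthetic experiment under ``config``.

    Plants ``n_chimeric_reads`` hotspots (disjoint occurrences, overlap
    length from the configured weights, distance uniform on
    [distance_min, distance_max]), then derives one junction-spanning read
    per hotspot plus ``n_normal_reads`` plain reads from the final genome.
    """
    base = generate_genome(config)
    plant_rng = config.rng("plant")
    read_rng = config.rng("reads")

    weights = config.resolved_overlap_weights()
    ks = np.array(sorted(weights))
    pk = np.array([weights[k] for k in ks], dtype=float)
    pk = pk / pk.sum()

    names = base.names
    buffers = {c: bytearray(base.sequence(c), "ascii") for c in names}
    lengths = np.array([len(buffers[c]) for c in names], dtype=float)
    probs = lengths / lengths.sum()
    reserved = {c: np.zeros(len(buffers[c]), dtype=bool) for c in names}

    margin = config.read_length + 2
    placements: list[tuple[str, int, int, int]] = []  # chrom, k, d, s0
    for _ in range(config.n_chimeric_reads):
        for _try in range(10_000):
            c = names[int(plant_rng.choice(len(names), p=probs))]
            n = len(buffers[c])
            k = int(ks[int(plant_rng.choice(len(ks), p=pk))])
            d = int(
                plant_rng.integers(config.distance_min, config.distance_max + 1)
            )
            span = 2 * k + d
            if n < span + 2 * margin:
                continue
            s0 = int(plant_rng.integers(margin, n - span - margin))
            p0 = s0 + k + d
            lo1, hi1 = s0 - 2, s0 + k + 2
            lo2, hi2 = p0 - 2, p0 + k + 2
            if reserved[c][lo1:hi1].any() or reserved[c][lo2:hi2].any():
                continue
            reserved[c][lo1:hi1] = True
            reserved[c][lo2:hi2] = True
            placements.append((c, k, d, s0))
            break
        else:
            raise RuntimeError(
                "could not place all hotspots; genome too small or too dense"
            )

    dataset = SimulatedDataset(config=config, genome=base)
    hotspots = [
        _plant_into(buffers[c], c, k, d, s0, plant_rng)
        for (c, k, d, s0) in placements
    ]
    genome = GenomeReference({c: buffers[c].decode("ascii") for c in names})
    dataset.genome = genome
    dataset.hotspots = hotspots

    for i, hotspot in enumerate(hotspots):
        k = hotspot.overlap_length
        a_min = max(config.min_former_read_length, k + 1)
        a_max = config.read_length - config.min_suffix_length
        if a_min > a_max:
            raise ValueError(
                "read_length cannot host the configured former/suffix minima"
            )
        a = int(read_rng.integers(a_min, a_max + 1))
        read_id = f"{_CHIMERIC_PREFIX}_{i:05d}"
        read, truth = simulate_chimeric_read(
            genome, hotspot, config.read_length, a, read_id=read_id
        )
        dataset.reads.append((read_id, read))
        dataset.truth.append(truth)

    dataset.reads.extend(
        simulate_normal_reads(
            genome, config.n_normal_reads, config.read_length, config.rng("normal")
        )
    )
    return dataset


def td_selection_experiment(
    genome: GenomeReference,
    k_range: Sequence[int] = tuple(range(8, 17)),
    temperature: float = 30.0,
    sigma: float = 3.0,
    n_chimeras: int = 30_000,
    window: int = 5000,
    rng: np.random.Generator | None = None,
):
    """Chimera generation as Td-weighted hotspot selection, end to end.

    Enumerates every hotspot of the genome for each overlap length in
    ``k_range``, assigns each a selection weight
    exp(-(Td - temperature)^2 / (2 sigma^2)) from its own Wallace Td, and
    samples ``n_chimeras`` chimera events in proportion. Returns a DataFrame
    per overlap length with hotspot counts, chimera counts, the
    chimera/hotspot ratio, mean overlap GC of both populations and their
    difference. Under this selection model the ratio curve peaks where the
    hotspot Td matches the reaction temperature, and the GC difference
    changes sign across that length.
    """
    import pandas as pd

    from .hotspots import screen_hotspot_arrays

    if rng is None:
        rng = np.random.default_rng(0)
    per_k = []
    for k in k_range:
        gcs = []
        for _, (_, _, gc) in screen_hotspot_arrays(genome, k, window).items():
            gcs.append(gc)
        gc = np.concatenate(gcs) if gcs else np.empty(0)
        per_k.append((k, gc))
    all_k = np.concatenate([np.full(gc.size, k) for k, gc in per_k]) if per_k else np.empty(0)
    all_gc = np.concatenate([gc for _, gc in per_k]) if per_k else np.empty(0)
    td = all_k * (2.0 + 2.0 * all_gc)
    weight = np.exp(-((td - temperature) ** 2) / (2.0 * sigma**2))
    if weight.sum() <= 0:
        raise ValueError("no selectable hotspots in the requested k range")
    chosen = rng.choice(all_k.size, size=n_chimeras, p=weight / weight.sum())
    rows = []
    for k, gc in per_k:
        mask = all_k[chosen] == k
        n_chim = int(mask.sum())
        chim_gc = float(all_gc[chosen][mask].mean()) if n_chim else np.nan
        hot_gc = float(gc.mean()) if gc.size else np.nan
        rows.append(
            {
                "overlap_length": k,
                "n_hotspots": int(gc.size),
                "n_chimeras": n_chim,
                "ratio": n_chim / gc.size if gc.size else np.nan,
                "mean_gc_chimeras": chim_gc,
                "mean_gc_hotspots": hot_gc,
                "delta_gc": chim_gc - hot_gc if gc.size and n_chim else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("overlap_length")
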
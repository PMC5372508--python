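"""Genome-wide screening of chimeric hotspots.

A chimeric hotspot is a pair of reverse-complementary sequences of length k
on the same strand, separated by at most ``window`` (default 5000 nt). Each
such pair is a potential template for an inverted-segment MDA chimera: a
displaced 3'-terminus ending in the upstream member can anneal at the
downstream member and prime synthesis back along the opposite strand.

Screening follows a sliding seed: every k-mer of the chromosome is a seed,
and every occurrence of its reverse complement whose start lies in
[seed_end, seed_end + window) is one hotspot. Pairs are counted once, from
their upstream member, and pairs whose members would physically overlap
(hairpin cores) are excluded (partner.start >= seed.end). Seeds or partners
containing N are skipped. The search window is truncated at the chromosome
end.

Two independent implementations are provided:

* :func:`screen_hotspots` / :func:`count_hotspots` - production path; k-mers
  are packed into base-4 integer codes and partner occurrences are counted
  with sorted-array bisection (numpy), so genome-scale counting never
  materializes individual pairs.
* :func:`brute_force_screen` - an O(n * window) direct string scan, intended
  for sequences up to ~100 knt, used as the testing oracle.

The distance of a hotspot is ``partner.start - seed.end`` (>= 0): the gap
between the two occurrences. On an i.i.d. random genome the expected number
of hotspots per seed position is window * 4**-k, so counts decline ~4-fold
per added nucleotide and distances are uniform on [0, window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .seqcore import GenomeReference, GenomicInterval, reverse_complement

DEFAULT_WINDOW = 5000

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class Hotspot:
    """One reverse-complementary pair: seed + downstream partner occurrence."""

    chrom: str
    seed: GenomicInterval
    partner: GenomicInterval
    overlap_length: int
    gc_fraction: float

    @property
    def distance(self) -> int:
        """Gap between the two occurrences: partner.start - seed.end >= 0."""
        return self.partner.start - self.seed.end


def hotspot_distance(h: Hotspot) -> int:
    return h.distance


def encode_bases(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3, anything else (N) -> 4, as a uint8 array."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, k: int):
    """Forward code, reverse-complement code and validity of every k-window.

    forward[p] encodes seq[p:p+k] big-endian base-4; rc[p] encodes the
    reverse complement of the same window. A window is valid iff it contains
    no N. Returns (forward, rc, valid), each of length len(codes) - k + 1.
    """
    n = codes.size
    m = n - k + 1
    if m <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), np.empty(0, dtype=bool)
    fwd = np.zeros(m, dtype=np.int64)
    rc = np.zeros(m, dtype=np.int64)
    invalid = np.zeros(m, dtype=np.int64)
    is_n = (codes == 4).astype(np.int64)
    b64 = codes.astype(np.int64)
    for i in range(k):
        window = b64[i : i + m]
        fwd += window << (2 * (k - 1 - i))
        rc += (3 - window) << (2 * i)
        invalid += is_n[i : i + m]
    return fwd, rc, invalid == 0


def _grouped(values: np.ndarray, positions: np.ndarray):
    """Sort positions by code value; positions stay ascending within a code."""
    order = np.argsort(values, kind="stable")
    return values[order], positions[order]


def _match_groups(seq: str, k: int):
    """Yield (seed_positions, partner_positions) per shared k-mer code.

    seed_positions are positions whose reverse-complement code equals the
    group code; partner_positions are positions whose forward code equals it.
    Both arrays are ascending.
    """
    codes = encode_bases(seq)
    fwd, rc, valid = _window_codes(codes, k)
    pos = np.flatnonzero(valid)
    if pos.size == 0:
        return
    f_vals, f_pos = _grouped(fwd[pos], pos)
    r_vals, r_pos = _grouped(rc[pos], pos)
    uniq, starts = np.unique(r_vals, return_index=True)
    bounds = np.append(starts, r_vals.size)
    # visit only codes that occur on both sides (at large k almost no
    # k-mer has a reverse-complement partner, so this prunes the loop)
    f_lo = np.searchsorted(f_vals, uniq, "left")
    present = (f_lo < f_vals.size) & (f_vals[np.minimum(f_lo, f_vals.size - 1)] == uniq)
    f_hi = np.searchsorted(f_vals, uniq, "right")
    for i in np.flatnonzero(present):
        seeds = r_pos[bounds[i] : bounds[i + 1]]
        yield seeds, f_pos[f_lo[i] : f_hi[i]]


def _composite_bounds(seq: str, k: int, window: int):
    """Per-seed index range of its in-window partners, via one sorted key.

    Partner positions are packed as (forward_code << S) | position into a
    single sorted int64 array, so every seed's partner range is two
    vectorized bisections - no per-k-mer grouping. Returns
    (seed_positions, sorted_keys, lo, hi, position_mask) or None when the
    packed key would overflow int64 (very large k; callers fall back to the
    per-group path).
    """
    codes = encode_bases(seq)
    fwd, rc, valid = _window_codes(codes, k)
    pos = np.flatnonzero(valid)
    if pos.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return pos, empty, empty, empty, 0
    shift = int(np.ceil(np.log2(codes.size + window + 2)))
    if 2 * k + shift > 62:
        return None
    keys = np.sort((fwd[pos] << shift) + pos)
    base = rc[pos] << shift
    # query in sorted order: sequential bisection is far more cache-friendly
    q_order = np.argsort(base + pos)
    spos = pos[q_order]
    sbase = base[q_order]
    lo = np.searchsorted(keys, sbase + (spos + k))
    hi = np.searchsorted(keys, sbase + (spos + k + window))
    return spos, keys, lo, hi, (1 << shift) - 1


def _count_chromosome(seq: str, k: int, window: int) -> int:
    packed = _composite_bounds(seq, k, window)
    if packed is not None:
        _, _, lo, hi, _ = packed
        return int((hi - lo).sum())
    total = 0
    for seeds, partners in _match_groups(seq, k):
        g_lo = np.searchsorted(partners, seeds + k, "left")
        g_hi = np.searchsorted(partners, seeds + k + window, "left")
        total += int((g_hi - g_lo).sum())
    return total


def _gather_ranges(values: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """values[lo[i]:hi[i]] for all i, concatenated, plus repeat counts."""
    counts = hi - lo
    keep = counts > 0
    counts = counts[keep]
    total = int(counts.sum())
    take = np.repeat(lo[keep], counts) + (
        np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    )
    return values[take], keep, counts


def _pairs_chromosome(seq: str, k: int, window: int):
    """All (seed_start, partner_start) pairs of one chromosome, unsorted."""
    packed = _composite_bounds(seq, k, window)
    if packed is not None:
        pos, keys, lo, hi, mask = packed
        if pos.size == 0:
            return pos, pos.copy()
        gathered, keep, counts = _gather_ranges(keys, lo, hi)
        return np.repeat(pos[keep], counts), gathered & mask
    seed_out: list[np.ndarray] = []
    part_out: list[np.ndarray] = []
    for seeds, partners in _match_groups(seq, k):
        g_lo = np.searchsorted(partners, seeds + k, "left")
        g_hi = np.searchsorted(partners, seeds + k + window, "left")
        gathered, keep, counts = _gather_ranges(partners, g_lo, g_hi)
        if counts.size:
            seed_out.append(np.repeat(seeds[keep], counts))
            part_out.append(gathered)
    if not seed_out:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    return np.concatenate(seed_out), np.concatenate(part_out)


def screen_hotspot_arrays(
    genome: GenomeReference, k: int, window: int = DEFAULT_WINDOW
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per chromosome: (seed_starts, partner_starts, seed_gc), lexsorted.

    Array-level variant of :func:`screen_hotspots` for analyses that need
    every pair of a modest genome without per-object overhead.
    """
    _check_params(k, window)
    out = {}
    for name, seq in genome:
        seeds, partners = _pairs_chromosome(seq, k, window)
        order = np.lexsort((partners, seeds))
        seeds, partners = seeds[order], partners[order]
        gc_cum = np.concatenate(
            ([0], np.cumsum(np.isin(encode_bases(seq), (1, 2)).astype(np.int64)))
        )
        gc = (gc_cum[seeds + k] - gc_cum[seeds]) / k
        out[name] = (seeds, partners, gc)
    return out


def _check_params(k: int, window: int) -> None:
    if k < 1:
        raise ValueError(f"overlap length k must be >= 1, got {k}")
    if k > window:
        raise ValueError(f"k={k} exceeds search window {window}")


def screen_hotspots(
    genome: GenomeReference, k: int, window: int = DEFAULT_WINDOW
) -> Iterator[Hotspot]:
    """Enumerate every k-nt hotspot of the genome, in coordinate order."""
    _check_params(k, window)
    for name, (seeds, partners, gc) in screen_hotspot_arrays(
        genome, k, window
    ).items():
        for s, p, g in zip(seeds.tolist(), partners.tolist(), gc.tolist()):
            yield Hotspot(
                chrom=name,
                seed=GenomicInterval(name, s, s + k),
                partner=GenomicInterval(name, p, p + k),
                overlap_length=k,
                gc_fraction=g,
            )


def brute_force_screen(
    genome: GenomeReference, k: int, window: int = DEFAULT_WINDOW
) -> Iterator[Hotspot]:
    """Direct O(n * window) re-screen; the independent oracle for tests.

    Scans every seed with ``str.find`` over its downstream window. Intended
    for sequences up to ~100 knt.
    """
    _check_params(k, window)
    for name, seq in genome:
        n = len(seq)
        for p in range(n - k + 1):
            seed = seq[p : p + k]
            if "N" in seed:
                continue
            target = reverse_complement(seed)
            limit = min(p + k + window, n - k + 1)  # last allowed start + 1
            q = seq.find(target, p + k, limit + k - 1)
            while q != -1 and q < limit:
                yield Hotspot(
                    chrom=name,
                    seed=GenomicInterval(name, p, p + k),
                    partner=GenomicInterval(name, q, q + k),
                    overlap_length=k,
                    gc_fraction=(seed.count("G") + seed.count("C")) / k,
                )
                q = seq.find(target, q + 1, limit + k - 1)


class HotspotCountTable:
    """Hotspot counts per (overlap length, chromosome) with genome totals.

    Totals are floats when a length was extrapolated from a single
    chromosome by the effective-length ratio, exact ints otherwise.
    """

    def __init__(self) -> None:
        self.per_chromosome: dict[tuple[int, str], int] = {}
        self.totals: dict[int, float] = {}
        self.extrapolated: set[int] = set()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"overlap_length": k, "chromosome": c, "count": n}
            for (k, c), n in sorted(self.per_chromosome.items())
        ]
        return pd.DataFrame(rows, columns=["overlap_length", "chromosome", "count"])

    def totals_series(self) -> pd.Series:
        return pd.Series(dict(sorted(self.totals.items())), name="count")


def count_hotspots(
    genome: GenomeReference,
    k_range: Iterable[int],
    window: int = DEFAULT_WINDOW,
    extrapolate_ks: Sequence[int] = (),
    extrapolate_chrom: str | None = None,
) -> HotspotCountTable:
    """Streaming hotspot counts for each k in ``k_range``.

    For k in ``extrapolate_ks`` the count is measured on
    ``extrapolate_chrom`` only and scaled to the genome by the ratio of
    effective (non-N) lengths - the mode used for very short overlaps whose
    genome-wide enumeration would be prohibitive.
    """
    extrapolate_ks = set(extrapolate_ks)
    if extrapolate_ks and extrapolate_chrom is None:
        raise ValueError("extrapolate_ks requires extrapolate_chrom")
    if extrapolate_chrom is not None and extrapolate_chrom not in genome:
        raise ValueError(f"unknown chromosome {extrapolate_chrom!r}")
    table = HotspotCountTable()
    for k in k_range:
        _check_params(k, window)
        if k in extrapolate_ks:
            n = _count_chromosome(genome.sequence(extrapolate_chrom), k, window)
            table.per_chromosome[(k, extrapolate_chrom)] = n
            fold = genome.total_effective_length / genome.effective_length(
                extrapolate_chrom
            )
            table.totals[k] = n * fold
            table.extrapolated.add(k)
        else:
            total = 0
            for name, seq in genome:
                n = _count_chromosome(seq, k, window)
                table.per_chromosome[(k, name)] = n
                total += n
            table.totals[k] = total
    return table


_COMP_CODE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_CODE[_a] = _b


def _maximal_mask(seq_bytes: np.ndarray, seeds: np.ndarray, partners: np.ndarray, k: int) -> np.ndarray:
    """Pairs that are not sub-pairs of a (k+1)-nt reverse-complementary pair.

    A pair extends outward when the base after the partner complements the
    base before the seed, inward when the base before the partner complements
    the base after the seed.
    """
    n = seq_bytes.size
    out_ok = (seeds >= 1) & (partners + k < n)
    ext_out = np.zeros(seeds.size, dtype=bool)
    ext_out[out_ok] = (
        seq_bytes[partners[out_ok] + k] == _COMP_CODE[seq_bytes[seeds[out_ok] - 1]]
    )
    in_ok = partners - 1 >= seeds + k
    ext_in = np.zeros(seeds.size, dtype=bool)
    ext_in[in_ok] = (
        seq_bytes[partners[in_ok] - 1] == _COMP_CODE[seq_bytes[seeds[in_ok] + k]]
    )
    return ~(ext_out | ext_in)


def hotspot_distances(
    genome: GenomeReference,
    k: int,
    window: int = DEFAULT_WINDOW,
    maximal_only: bool = False,
) -> np.ndarray:
    """All hotspot distances (partner.start - seed.end) for one k, unsorted.

    With ``maximal_only`` the nested sub-pairs of longer hotspots are
    dropped, keeping one pair per maximal inverted repeat. A repeat of
    length k+j contributes j+1 nested k-pairs at nearly identical distances;
    such clusters overdisperse per-bin counts, so distributional tests that
    assume independent draws (e.g. chi-square uniformity) should be run on
    maximal pairs.
    """
    _check_params(k, window)
    out = []
    for _, seq in genome:
        seeds, partners = _pairs_chromosome(seq, k, window)
        if maximal_only and seeds.size:
            sb = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            keep = _maximal_mask(sb, seeds, partners, k)
            seeds, partners = seeds[keep], partners[keep]
        out.append(partners - (seeds + k))
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)
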
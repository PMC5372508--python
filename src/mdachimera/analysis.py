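"""Preference statistics over chimera and hotspot populations.

Given detected chimeras and screened hotspots, this module computes the
summary shapes the downstream science works with: counts per overlap
length, the chimera/hotspot selection ratio, mean overlap GC content and the
chimera-minus-hotspot GC difference per length, Wallace-rule Td estimates
per length, distance histograms in 20-nt steps, per-chromosome counts with a
linear length fit, and per-interval (gene) counts.

Mean GC is the unweighted mean over records - each chimera or hotspot
contributes once, whatever its locus - and Td per length is the Wallace rule
applied to the group's average composition, Td = L*(2 + 2*mean_gc), reported
rounded to 2 decimals (internal values unrounded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .seqcore import GenomeReference, wallace_td_from_length_gc

DEFAULT_BIN_WIDTH = 20
DEFAULT_MAX_DISTANCE = 5000
POOL_OVER = 25


def _lengths_of(records: Iterable) -> list[int]:
    return [r.overlap_length for r in records]


def overlap_length_distribution(
    records: Iterable, pool_over: int = POOL_OVER
) -> pd.Series:
    """Chimera (or hotspot) counts per overlap length.

    Lengths 1..pool_over appear explicitly (zero-filled); anything longer is
    pooled into a final ``"{pool_over}+"`` bucket. Length 0 (overlap-free
    junctions) is included when present.
    """
    lengths = _lengths_of(records)
    counts = pd.Series(lengths, dtype=int).value_counts() if lengths else pd.Series(dtype=int)
    index: list = list(range(1, pool_over + 1))
    if (counts.index == 0).any():
        index = [0] + index
    out = pd.Series(0, index=index + [f"{pool_over}+"], dtype=int, name="count")
    for length, n in counts.items():
        if length > pool_over:
            out[f"{pool_over}+"] += int(n)
        else:
            out[length] = int(n)
    return out


def chimera_hotspot_ratio(
    chimera_counts: Mapping[int, float], hotspot_counts: Mapping[int, float]
) -> pd.Series:
    """Elementwise chimeras/hotspots per overlap length.

    Lengths with zero (or absent) hotspot counts yield NaN, not infinity.
    Negative counts are a data error.
    """
    for m in (chimera_counts, hotspot_counts):
        if any(v < 0 for v in m.values()):
            raise ValueError("counts must be non-negative")
    keys = sorted(set(chimera_counts) | set(hotspot_counts))
    out = {}
    for k in keys:
        hot = hotspot_counts.get(k, 0)
        chim = chimera_counts.get(k, 0)
        out[k] = chim / hot if hot > 0 else np.nan
    return pd.Series(out, name="ratio")


@dataclass
class GCReport:
    """Per-length and overall mean overlap GC of chimeras vs hotspots."""

    per_length: pd.DataFrame  # n/mean_gc for both populations + delta_gc
    overall_gc_chimeras: float
    overall_gc_hotspots: float

    @property
    def overall_delta(self) -> float:
        return self.overall_gc_chimeras - self.overall_gc_hotspots


def _gc_frame(records: Iterable, label: str) -> pd.DataFrame:
    rows = [(r.overlap_length, r.gc_fraction) for r in records]
    df = pd.DataFrame(rows, columns=["overlap_length", "gc"])
    grouped = df.groupby("overlap_length")["gc"].agg(["size", "mean"])
    grouped.columns = [f"n_{label}", f"mean_gc_{label}"]
    return grouped


def gc_tables(chimeras: Sequence, hotspots: Sequence) -> GCReport:
    """Unweighted mean overlap GC per length, their difference, and overalls.

    ``chimeras`` must expose ``overlap_length`` and an overlap GC; chimera
    records carry sequences, so GC is computed from ``overlap_seq`` if a
    precomputed ``gc_fraction`` is absent. Zero-length overlaps are skipped
    (no composition).
    """
    chim = [_WithGC(r) for r in chimeras if r.overlap_length > 0]
    hot = list(hotspots)
    per = _gc_frame(chim, "chimeras").join(_gc_frame(hot, "hotspots"), how="outer")
    per["delta_gc"] = per["mean_gc_chimeras"] - per["mean_gc_hotspots"]
    overall_c = float(np.mean([r.gc_fraction for r in chim])) if chim else np.nan
    overall_h = float(np.mean([r.gc_fraction for r in hot])) if hot else np.nan
    return GCReport(per, overall_c, overall_h)


class _WithGC:
    """Adapter giving chimera records a gc_fraction like hotspots have."""

    __slots__ = ("overlap_length", "gc_fraction")

    def __init__(self, record):
        self.overlap_length = record.overlap_length
        gc = getattr(record, "gc_fraction", None)
        if gc is None:
            seq = record.overlap_seq
            gc = (seq.count("G") + seq.count("C")) / len(seq)
        self.gc_fraction = gc


def td_table(length_gc_rows) -> pd.DataFrame:
    """Wallace Td per overlap length from (length, mean GC) rows.

    Accepts a mapping {length: mean_gc} or a DataFrame with columns
    ``overlap_length`` and ``mean_gc`` (extra columns pass through). Adds
    ``td``: L*(2 + 2*mean_gc) rounded to 2 decimals.
    """
    if isinstance(length_gc_rows, Mapping):
        df = pd.DataFrame(
            {"overlap_length": list(length_gc_rows), "mean_gc": list(length_gc_rows.values())}
        )
    else:
        df = pd.DataFrame(length_gc_rows).copy()
    df["td"] = [
        round(wallace_td_from_length_gc(length, gc), 2)
        for length, gc in zip(df["overlap_length"], df["mean_gc"])
    ]
    return df


@dataclass
class DistanceHistogram:
    """|distance| counts in fixed-width bins over [0, max_distance)."""

    bin_width: int
    max_distance: int
    counts: np.ndarray  # length max_distance // bin_width
    n_dropped: int  # records at or beyond max_distance

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(0, self.max_distance + self.bin_width, self.bin_width)

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges
        return pd.DataFrame(
            {
                "bin_start": edges[:-1],
                "bin_end": edges[1:],
                "count": self.counts,
            }
        )


def distance_histogram(
    records_or_distances: Iterable,
    bin_width: int = DEFAULT_BIN_WIDTH,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> DistanceHistogram:
    """Bin |distance| into half-open bins [0, w), [w, 2w), ...

    Values at or beyond ``max_distance`` are dropped and counted in
    ``n_dropped``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if max_distance % bin_width:
        raise ValueError("max_distance must be a multiple of bin_width")
    values = [
        abs(r.distance) if hasattr(r, "distance") else abs(int(r))
        for r in records_or_distances
    ]
    arr = np.asarray(values, dtype=np.int64)
    in_range = arr[arr < max_distance]
    counts = np.bincount(in_range // bin_width, minlength=max_distance // bin_width)
    return DistanceHistogram(
        bin_width=bin_width,
        max_distance=max_distance,
        counts=counts.astype(np.int64),
        n_dropped=int(arr.size - in_range.size),
    )


@dataclass
class ChromosomeDistribution:
    """Per-chromosome record counts with ploidy adjustment and a length fit."""

    table: pd.DataFrame  # chromosome, count, effective_length, ploidy, adjusted_count
    fit: sps._stats_mstats_common.LinregressResult | None  # None when degenerate


def chromosome_distribution(
    records: Iterable,
    genome: GenomeReference,
    ploidy_map: Mapping[str, int] | None = None,
) -> ChromosomeDistribution:
    """Counts per chromosome, ploidy-adjusted, with adjusted-count ~ length fit.

    ``ploidy_map`` defaults to 1 everywhere (synthetic genomes); pass 2 for
    autosomes / 1 for X and Y to reproduce the diploid-doubling convention
    used for human data. The least-squares fit of adjusted count against
    effective chromosome length is None for single-chromosome genomes.
    """
    counts: dict[str, int] = {name: 0 for name in genome.names}
    for r in records:
        chrom = r.former.chrom if hasattr(r, "former") else r.chrom
        if chrom not in counts:
            raise ValueError(f"record on unknown chromosome {chrom!r}")
        counts[chrom] += 1
    ploidy_map = dict(ploidy_map or {})
    rows = []
    for name in genome.names:
        ploidy = int(ploidy_map.get(name, 1))
        if ploidy not in (1, 2):
            raise ValueError("ploidy factor must be 1 or 2")
        rows.append(
            {
                "chromosome": name,
                "count": counts[name],
                "effective_length": genome.effective_length(name),
                "ploidy": ploidy,
                "adjusted_count": counts[name] * ploidy,
            }
        )
    table = pd.DataFrame(rows)
    fit = None
    if len(table) >= 2 and table["effective_length"].nunique() >= 2:
        fit = sps.linregress(table["effective_length"], table["adjusted_count"])
    return ChromosomeDistribution(table=table, fit=fit)


def interval_counts(
    records: Iterable, intervals: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Record count per interval (BED-style), plus the hit fraction.

    ``intervals`` needs columns chrom/start/end (0-based half-open, e.g. from
    :func:`mdachimera.io.read_bed`). A record is assigned to every interval
    containing its former segment's start. Returns the per-interval table and
    the fraction of intervals with at least one record.
    """
    required = {"chrom", "start", "end"}
    if not required.issubset(intervals.columns):
        raise ValueError(f"interval table must have columns {sorted(required)}")
    intervals = intervals.reset_index(drop=True)
    if len(intervals) == 0:
        return intervals.assign(count=pd.Series(dtype=int)), float("nan")
    trees: dict[str, IntervalTree] = {}
    for idx, row in intervals.iterrows():
        if row["end"] <= row["start"]:
            raise ValueError(f"malformed interval at row {idx}")
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]), idx
        )
    hits = np.zeros(len(intervals), dtype=np.int64)
    for r in records:
        former = r.former if hasattr(r, "former") else r
        tree = trees.get(former.chrom)
        if tree is None:
            continue
        for iv in tree.at(former.start):
            hits[iv.data] += 1
    out = intervals.assign(count=hits)
    return out, float((hits > 0).mean())
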
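"""File formats: FASTA/FASTQ via Biopython, tab-separated report tables.

All genomic coordinates inside the package are 0-based half-open; every TSV
written here uses 1-based inclusive coordinates and carries a comment header
saying so, plus a provenance line with the generating parameters.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .recognize import ChimeraRecord, ReadRecord
from .seqcore import GenomicInterval
from .simulate import SimulatedTruth

_COORD_NOTE = "# coordinates: 1-based inclusive"

TRUTH_COLUMNS = [
    "read_id",
    "chrom",
    "former_start",
    "former_end",
    "former_strand",
    "following_start",
    "following_end",
    "following_strand",
    "overlap_seq",
    "distance",
]
CHIMERA_COLUMNS = TRUTH_COLUMNS + ["overlap_length", "level", "type"]


def read_fastq(path) -> list[ReadRecord]:
    return [
        ReadRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, sequence) pairs; all bases get quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def _provenance(params: dict | None) -> list[str]:
    lines = [_COORD_NOTE]
    if params:
        rendered = " ".join(f"{k}={v}" for k, v in params.items())
        lines.append(f"# params: {rendered}")
    return lines


def _write_tsv(path, df: pd.DataFrame, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _provenance(params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _segment_row(read_id: str, former: GenomicInterval, following: GenomicInterval,
                 overlap_seq: str, distance: int) -> dict:
    return {
        "read_id": read_id,
        "chrom": former.chrom,
        "former_start": former.start + 1,
        "former_end": former.end,
        "former_strand": former.strand,
        "following_start": following.start + 1,
        "following_end": following.end,
        "following_strand": following.strand,
        "overlap_seq": overlap_seq or ".",
        "distance": distance,
    }


def write_truth_tsv(path, truth: Sequence[SimulatedTruth], params: dict | None = None) -> None:
    rows = [
        _segment_row(t.read_id, t.former, t.following, t.overlap_seq, t.distance)
        for t in truth
    ]
    _write_tsv(path, pd.DataFrame(rows, columns=TRUTH_COLUMNS), params)


def write_chimera_tsv(path, records: Sequence[ChimeraRecord], params: dict | None = None) -> None:
    rows = []
    for r in records:
        row = _segment_row(r.read_id, r.former, r.following, r.overlap_seq, r.distance)
        row.update(overlap_length=r.overlap_length, level=r.level, type=r.type)
        rows.append(row)
    _write_tsv(path, pd.DataFrame(rows, columns=CHIMERA_COLUMNS), params)


def _intervals_from_row(row) -> tuple[GenomicInterval, GenomicInterval]:
    former = GenomicInterval(
        row["chrom"], int(row["former_start"]) - 1, int(row["former_end"]),
        row["former_strand"],
    )
    following = GenomicInterval(
        row["chrom"], int(row["following_start"]) - 1, int(row["following_end"]),
        row["following_strand"],
    )
    return former, following


def read_truth_tsv(path) -> list[SimulatedTruth]:
    out = []
    for _, row in read_tsv(path).iterrows():
        former, following = _intervals_from_row(row)
        overlap = "" if row["overlap_seq"] == "." else str(row["overlap_seq"])
        out.append(
            SimulatedTruth(
                read_id=str(row["read_id"]), former=former, following=following,
                overlap_seq=overlap, distance=int(row["distance"]),
            )
        )
    return out


def read_chimera_tsv(path) -> list[ChimeraRecord]:
    out = []
    for _, row in read_tsv(path).iterrows():
        former, following = _intervals_from_row(row)
        overlap = "" if row["overlap_seq"] == "." else str(row["overlap_seq"])
        out.append(
            ChimeraRecord(
                read_id=str(row["read_id"]), former=former, following=following,
                overlap_seq=overlap, distance=int(row["distance"]),
                level=int(row["level"]), type=str(row["type"]),
            )
        )
    return out


def write_hotspot_count_tsv(path, table, genome=None, params: dict | None = None) -> None:
    """Per-(k, chromosome) hotspot counts with effective lengths."""
    df = table.to_frame()
    if genome is not None:
        df["effective_length"] = [
            genome.effective_length(c) for c in df["chromosome"]
        ]
    _write_tsv(path, df, params)


def write_hotspot_tsv(path, hotspots, params: dict | None = None) -> None:
    """Materialized hotspots, BEDPE-flavoured (1-based inclusive columns)."""
    rows = [
        {
            "chrom": h.chrom,
            "seed_start": h.seed.start + 1,
            "seed_end": h.seed.end,
            "partner_start": h.partner.start + 1,
            "partner_end": h.partner.end,
            "overlap_length": h.overlap_length,
            "gc": round(h.gc_fraction, 6),
            "distance": h.distance,
        }
        for h in hotspots
    ]
    cols = [
        "chrom", "seed_start", "seed_end", "partner_start", "partner_end",
        "overlap_length", "gc", "distance",
    ]
    _write_tsv(path, pd.DataFrame(rows, columns=cols), params)


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end (+ optional name), 0-based half-open."""
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    if raw.shape[1] < 3:
        raise ValueError(f"malformed BED file (need >= 3 columns): {path}")
    df = raw.iloc[:, :3].copy()
    df.columns = ["chrom", "start", "end"]
    df["name"] = raw.iloc[:, 3] if raw.shape[1] >= 4 else ""
    if df[["start", "end"]].isna().any().any():
        raise ValueError(f"malformed BED file: {path}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df
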
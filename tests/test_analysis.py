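import numpy as np
import pandas as pd
import pytest

from mdachimera import (
    GenomeReference,
    GenomicInterval,
    Hotspot,
    ReadRecord,
    SimulationConfig,
    chimera_hotspot_ratio,
    chromosome_distribution,
    distance_histogram,
    gc_tables,
    interval_counts,
    overlap_length_distribution,
    recognize_chimeras,
    simulate_dataset,
    td_table,
)
from mdachimera.published import published_overlap_table
from mdachimera.recognize import ChimeraRecord


def make_record(read_id="r", chrom="chr1", overlap="ACGTACG", distance=100,
                former=(100, 160), following=(250, 317)):
    return ChimeraRecord(
        read_id=read_id,
        former=GenomicInterval(chrom, *former, "+"),
        following=GenomicInterval(chrom, *following, "-"),
        overlap_seq=overlap,
        distance=distance,
    )


def make_hotspot(chrom="chr1", k=7, gc=0.4, seed_start=0, distance=50):
    return Hotspot(
        chrom=chrom,
        seed=GenomicInterval(chrom, seed_start, seed_start + k),
        partner=GenomicInterval(
            chrom, seed_start + k + distance, seed_start + 2 * k + distance
        ),
        overlap_length=k,
        gc_fraction=gc,
    )


def test_overlap_length_distribution_counts_and_pooling():
    records = [
        make_record(overlap="ACGTACG"),        # 7
        make_record(overlap="GGGTTTA"),        # 7
        make_record(overlap="ACGTACGTACGT"),   # 12
        make_record(overlap="A" * 30),         # pooled into 25+
    ]
    counts = overlap_length_distribution(records)
    assert counts[7] == 2 and counts[12] == 1 and counts["25+"] == 1
    assert counts[1] == 0
    empty = overlap_length_distribution([])
    assert (empty.drop("25+") == 0).all() and empty["25+"] == 0


def test_chimera_hotspot_ratio():
    ratio = chimera_hotspot_ratio({7: 100}, {7: 10_000})
    assert ratio[7] == pytest.approx(0.01)
    ratio = chimera_hotspot_ratio({25: 3}, {25: 0})
    assert np.isnan(ratio[25])
    with pytest.raises(ValueError):
        chimera_hotspot_ratio({7: -1}, {7: 10})


def test_gc_tables_means_and_delta():
    chimeras = [make_record(overlap="GGCC"), make_record(overlap="ATAT")]
    hotspots = [make_hotspot(k=4, gc=1.0), make_hotspot(k=4, gc=0.0)]
    report = gc_tables(chimeras, hotspots)
    row = report.per_length.loc[4]
    assert row["mean_gc_chimeras"] == pytest.approx(0.5)
    assert row["mean_gc_hotspots"] == pytest.approx(0.5)
    assert row["delta_gc"] == pytest.approx(0.0)
    assert report.overall_gc_chimeras == pytest.approx(0.5)
    # crafted set: overall mean is the unweighted mean over records
    chim2 = [make_record(overlap="GGGG"), make_record(overlap="GGAA"),
             make_record(overlap="AATT")]
    rep2 = gc_tables(chim2, [])
    assert rep2.overall_gc_chimeras == pytest.approx((1.0 + 0.5 + 0.0) / 3)


def test_td_table_reproduces_published_rows():
    """Td column of the published per-length table, 2-decimal rounding.

    Rows whose printed Td differs by 0.01 from the recomputation (unprinted
    GC decimals) are excluded by design.
    """
    table = td_table(published_overlap_table())
    td = dict(zip(table["overlap_length"], table["td"]))
    assert td[1] == 2.74
    assert td[3] == 8.99
    assert td[10] == 27.56
    assert td[12] == 32.24
    assert td[17] == 43.54
    assert td[20] == 53.60
    assert td[25] == 70.05


def test_td_table_accepts_mapping():
    table = td_table({12: 0.3435, 17: 0.2805})
    assert list(table["td"]) == [32.24, 43.54]


def test_distance_histogram_boundaries():
    hist = distance_histogram([0, 19, 20])
    assert hist.counts[0] == 2 and hist.counts[1] == 1
    assert hist.counts.sum() == 3 and len(hist.counts) == 250
    hist = distance_histogram([4999, 5000, 7000])
    assert hist.counts[249] == 1 and hist.n_dropped == 2
    with pytest.raises(ValueError):
        distance_histogram([1], bin_width=0)


def test_distance_histogram_accepts_records():
    records = [make_record(distance=-30), make_record(distance=30)]
    hist = distance_histogram(records)
    assert hist.counts[1] == 2  # |distance| binned


def test_chromosome_distribution_ploidy_and_fit():
    genome = GenomeReference({"chr1": "ACGT" * 300, "chrX": "ACGT" * 150})
    records = [make_record(chrom="chr1", former=(0, 50), following=(100, 157))] * 4 + [
        make_record(chrom="chrX", former=(0, 50), following=(100, 157))
    ] * 3
    dist = chromosome_distribution(records, genome, ploidy_map={"chr1": 2, "chrX": 1})
    table = dist.table.set_index("chromosome")
    assert table.loc["chr1", "adjusted_count"] == 8
    assert table.loc["chrX", "adjusted_count"] == 3
    assert dist.fit is not None
    single = chromosome_distribution([], GenomeReference({"chr1": "ACGT" * 100}))
    assert single.fit is None
    with pytest.raises(ValueError):
        chromosome_distribution([make_record(chrom="nope")], genome)


def test_chromosome_distribution_uniformity_binomial(rng):
    cfg = SimulationConfig(
        genome_length=200_000, n_chromosomes=2, n_chimeric_reads=200,
        n_normal_reads=0, rng_seed=41,
    )
    ds = simulate_dataset(cfg)
    dist = chromosome_distribution(ds.truth, ds.genome)
    counts = dist.table["count"].to_numpy()
    n = counts.sum()
    # equal-length chromosomes: each count within 5 binomial SD of n/2
    sd = np.sqrt(n * 0.25)
    assert abs(counts[0] - n / 2) < 5 * sd


def test_interval_counts_basic():
    intervals = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [200, 700]}
    )
    records = [make_record(former=(100, 160), following=(250, 317))]
    table, fraction = interval_counts(records, intervals)
    assert list(table["count"]) == [1, 0]
    assert fraction == pytest.approx(0.5)
    empty, frac = interval_counts(records, intervals.iloc[:0])
    assert len(empty) == 0 and np.isnan(frac)
    with pytest.raises(ValueError):
        interval_counts(records, pd.DataFrame({"chrom": ["c"], "start": [5], "end": [5]}))


def test_interval_counts_scale_with_length(rng):
    """Uniform records over a synthetic gene set: count grows with length."""
    cfg = SimulationConfig(
        genome_length=300_000, n_chimeric_reads=300, n_normal_reads=0, rng_seed=43
    )
    ds = simulate_dataset(cfg)
    edges = np.array([0, 2_000, 6_000, 14_000, 30_000, 62_000, 126_000, 300_000])
    intervals = pd.DataFrame(
        {"chrom": "chr1", "start": edges[:-1], "end": edges[1:]}
    )
    table, _ = interval_counts(ds.truth, intervals)
    lengths = (table["end"] - table["start"]).to_numpy(float)
    from scipy.stats import linregress

    fit = linregress(lengths, table["count"].to_numpy(float))
    assert fit.slope > 0


def test_group_statistics_match_direct_recomputation():
    """Ratio, delta-GC and histogram agree with slow per-record loops."""
    cfg = SimulationConfig(
        genome_length=120_000, n_chimeric_reads=80, n_normal_reads=0, rng_seed=47
    )
    ds = simulate_dataset(cfg)
    records = recognize_chimeras(
        [ReadRecord(i, s) for i, s in ds.reads], ds.genome
    )
    hotspots = ds.hotspots

    report = gc_tables(records, hotspots)
    for k in sorted({r.overlap_length for r in records}):
        direct = [
            (r.overlap_seq.count("G") + r.overlap_seq.count("C")) / r.overlap_length
            for r in records
            if r.overlap_length == k
        ]
        assert report.per_length.loc[k, "mean_gc_chimeras"] == pytest.approx(
            sum(direct) / len(direct)
        )

    chim_counts = {}
    hot_counts = {}
    for r in records:
        chim_counts[r.overlap_length] = chim_counts.get(r.overlap_length, 0) + 1
    for h in hotspots:
        hot_counts[h.overlap_length] = hot_counts.get(h.overlap_length, 0) + 1
    ratio = chimera_hotspot_ratio(chim_counts, hot_counts)
    for k, n in chim_counts.items():
        if hot_counts.get(k):
            assert ratio[k] == pytest.approx(n / hot_counts[k])

    hist = distance_histogram(records)
    slow = [0] * 250
    for r in records:
        if abs(r.distance) < 5000:
            slow[abs(r.distance) // 20] += 1
    assert hist.counts.tolist() == slow


def test_count_tables_permutation_invariant_and_additive():
    recs = [make_record(read_id=f"r{i}", overlap="ACGTA") for i in range(6)] + [
        make_record(read_id=f"s{i}", overlap="ACGTACGTA") for i in range(4)
    ]
    a = overlap_length_distribution(recs)
    b = overlap_length_distribution(recs[::-1])
    assert a.equals(b)
    first = overlap_length_distribution(recs[:5])
    second = overlap_length_distribution(recs[5:])
    assert ((first + second) == a).all()
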
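import numpy as np
import pytest

from mdachimera import (
    GenomeReference,
    ReadRecord,
    SimulationConfig,
    extend_seed,
    extract_and_map_seed,
    filter_reads_with_n,
    generate_genome,
    locate_following_segment,
    map_full_read,
    plant_hotspot,
    recognize_chimeras,
    reconstruct_overlap,
    reverse_complement,
    simulate_chimeric_read,
    validate_record,
)
from mdachimera.recognize import GenomeIndex
from mdachimera.seqcore import GenomicInterval

from conftest import random_sequence


@pytest.fixture(scope="module")
def planted():
    """30-knt genome with one 8-nt hotspot and one chimeric read from it."""
    cfg = SimulationConfig(genome_length=30_000, rng_seed=21)
    rng = np.random.default_rng(21)
    genome, hotspot = plant_hotspot(generate_genome(cfg), 8, 300, 12_000, rng=rng)
    read, truth = simulate_chimeric_read(genome, hotspot, 101, 50, read_id="r0")
    return genome, hotspot, ReadRecord("r0", read), truth


@pytest.fixture(scope="module")
def planted_index(planted):
    genome = planted[0]
    return GenomeIndex(genome, 30)


def test_filter_reads_with_n():
    clean = ReadRecord("a", "ACGT" * 10)
    dirty = ReadRecord("b", "ACNT" * 10)
    assert filter_reads_with_n([clean, dirty]) == [clean]
    assert filter_reads_with_n([clean]) == [clean]
    assert filter_reads_with_n([dirty, dirty]) == []


def test_index_lookup_against_brute_scan(planted, planted_index):
    genome = planted[0]
    seq = genome.sequence("chr1")
    kmer = seq[5000:5030]
    hits = planted_index.lookup(kmer)
    # oracle: direct string scan
    expected, q = [], seq.find(kmer)
    while q != -1:
        expected.append(("chr1", q))
        q = seq.find(kmer, q + 1)
    assert hits == expected and ("chr1", 5000) in hits
    assert planted_index.lookup("A" * 30) == []  # absent on a random genome


def test_palindromic_seed_hits_both_strands(rng):
    half = random_sequence(15, rng)
    palindrome = half + reverse_complement(half)  # 30-nt revcomp palindrome
    seq = random_sequence(500, rng) + palindrome + random_sequence(500, rng)
    genome = GenomeReference({"c": seq})
    index = GenomeIndex(genome, 30)
    read = ReadRecord("p", palindrome + random_sequence(71, rng))
    hits = extract_and_map_seed(read, index, 30)
    strands = {(h.interval.start, h.interval.strand) for h in hits}
    assert (500, "+") in strands and (500, "-") in strands


def test_map_full_read(planted, planted_index):
    genome, _, chim_read, _ = planted
    seq = genome.sequence("chr1")
    normal = ReadRecord("n", seq[100:201])
    assert len(map_full_read(normal, planted_index)) >= 1
    flipped = ReadRecord("f", reverse_complement(seq[100:201]))
    assert any(h.strand == "-" for h in map_full_read(flipped, planted_index))
    assert map_full_read(chim_read, planted_index) == []  # junction breaks it
    giant = ReadRecord("g", "ACGT" * 10_000)
    assert map_full_read(giant, planted_index) == []


def test_seed_requires_min_length(planted_index):
    with pytest.raises(ValueError):
        extract_and_map_seed(ReadRecord("s", "ACGTACGTACGTACGTACGTACGTACGTA"), planted_index)


def test_extend_seed_recovers_breakpoint(planted, planted_index):
    genome, _, read, truth = planted
    hits = extract_and_map_seed(read, planted_index)
    assert any(h.interval.start == truth.former.start for h in hits)
    hit = next(h for h in hits if h.interval.start == truth.former.start)
    former, junction = extend_seed(read, genome, hit)
    assert former == truth.former
    assert junction == 50  # the configured breakpoint offset


def test_extend_seed_perfect_substring(planted, planted_index):
    genome = planted[0]
    seq = genome.sequence("chr1")
    read = ReadRecord("sub", seq[4000:4101])
    hit = extract_and_map_seed(read, planted_index)[0]
    _, junction = extend_seed(read, genome, hit)
    assert junction == 101  # extension reaches the read end: not a chimera


def test_extend_seed_stops_at_single_edit(planted, planted_index):
    genome = planted[0]
    seq = genome.sequence("chr1")
    frag = seq[4000:4101]
    edited = frag[:31] + ("A" if frag[31] != "A" else "C") + frag[32:]
    read = ReadRecord("edit", edited)
    hit = next(
        h for h in extract_and_map_seed(read, planted_index)
        if h.interval.start == 4000 and h.interval.strand == "+"
    )
    former, junction = extend_seed(read, genome, hit)
    assert junction == 31
    assert former == GenomicInterval("chr1", 4000, 4031, "+")


def test_locate_following_round_trip(planted):
    genome, _, read, truth = planted
    suffix = read.sequence[50:]
    located = locate_following_segment(suffix, genome, truth.former)
    assert located is not None
    # located interval is the suffix footprint: the following segment minus
    # the 8-nt overlap that reverse extension adds back
    assert located.start == truth.following.start
    assert located.end == truth.following.end - truth.overlap_length
    assert located.strand == "-"


def test_locate_following_outside_window(rng):
    seq = random_sequence(20_000, rng)
    target = random_sequence(25, rng)
    # plant the only occurrence ~6 knt downstream of the former end
    seq = seq[:100] + seq[100:]
    seq = seq[:9000] + target + seq[9000 + 25 :]
    genome = GenomeReference({"c": seq})
    former = GenomicInterval("c", 2950, 3000, "+")
    assert (
        locate_following_segment(reverse_complement(target), genome, former, window=5000)
        is None
    )
    # ... but a 7-knt window finds it
    assert (
        locate_following_segment(reverse_complement(target), genome, former, window=7000)
        is not None
    )


def test_locate_following_tie_breaks_to_lower_coordinate():
    # two identical partner occurrences equidistant from the former end
    block = "ACGTACGTACGTACGTACGT"  # 20 nt
    filler = "TTTTTTTTTT"
    seq = block + filler * 20 + "G" + filler * 20 + block
    genome = GenomeReference({"c": seq})
    n = len(seq)
    mid = n // 2
    former = GenomicInterval("c", mid - 10, mid, "+")
    suffix = reverse_complement(block)
    located = locate_following_segment(suffix, genome, former, window=5000, min_length=10)
    # |distance| ties between the left and right occurrence: lower wins
    assert located is not None and located.start == 0


def test_locate_following_too_short(planted):
    genome, _, _, truth = planted
    assert locate_following_segment("ACGTACG", genome, truth.former) is None


def test_reconstruct_overlap_fig_configuration(rng):
    cfg = SimulationConfig(genome_length=50_000, rng_seed=31)
    genome, hotspot = plant_hotspot(
        generate_genome(cfg), 8, 250, 20_000, overlap_seq="CTCTATTC",
        rng=np.random.default_rng(31),
    )
    read, truth = simulate_chimeric_read(genome, hotspot, 101, 45, read_id="fig")
    records = recognize_chimeras([ReadRecord("fig", read)], genome)
    assert len(records) == 1
    rec = records[0]
    assert rec.overlap_seq == "CTCTATTC"
    assert rec.overlap_length == 8
    assert rec.former.strand != rec.following.strand
    assert genome.fetch(hotspot.partner) == "GAATAGAG"
    assert (rec.former, rec.following) == (truth.former, truth.following)


def test_reconstruct_overlap_zero_when_no_shared_boundary():
    # former tail 'AAAAA...' cannot pair with following upstream base 'T'
    # (pairing would need seq[p0] == complement(former tail) == 'T'; use 'A')
    seq = "A" * 60 + "C" * 40 + "A" * 60
    genome = GenomeReference({"c": seq})
    former = GenomicInterval("c", 0, 50, "+")
    following_pre = GenomicInterval("c", 100, 130, "-")
    assert reconstruct_overlap(genome, former, following_pre) == ""


def test_recognize_order_invariance_and_validation(planted):
    genome, hotspot, read, truth = planted
    extra_read, _ = simulate_chimeric_read(genome, hotspot, 101, 70, read_id="r1")
    reads = [read, ReadRecord("r1", extra_read)]
    fwd = recognize_chimeras(reads, genome)
    rev = recognize_chimeras(reads[::-1], genome)
    assert fwd == rev and len(fwd) == 2
    for rec in fwd:
        validate_record(rec, genome)
        assert abs(rec.distance) <= 5000


def test_recognize_reverse_complement_presentation(planted):
    """The same chimeric molecule read from the other strand is still found."""
    genome, _, read, _ = planted
    flipped = ReadRecord("rc", reverse_complement(read.sequence))
    records = recognize_chimeras([flipped], genome)
    assert len(records) == 1
    rec = records[0]
    assert rec.overlap_length == 8
    validate_record(rec, genome)


def test_recognize_degenerate_inputs(planted):
    genome = planted[0]
    assert recognize_chimeras([], genome) == []
    records, stats = recognize_chimeras(
        [ReadRecord("n1", "N" * 101), ReadRecord("n2", "AN" + "ACGT" * 24 + "A")],
        genome,
        return_stats=True,
    )
    assert records == [] and stats.with_n == 2 and stats.reads_in == 2
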
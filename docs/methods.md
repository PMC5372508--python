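# Methods

## The problem

Multiple displacement amplification (MDA) with phi29 polymerase generates
chimeric reads: during strand displacement a duplicated 3'-terminus can
denature from its template and misprime on a nearby displaced strand. The
dominant artifact class is the 1-level inverted chimera - a read whose two
segments map to opposite strands of the same chromosome and share a short
overlap at the junction. On the sense strand the overlap's two genomic
occurrences are reverse-complementary, so every reverse-complementary
sequence pair within the characteristic ~5-knt jump range is a potential
chimera template; we call such a pair a chimeric hotspot. The package
implements three things: recognition of these chimeras in reads, exhaustive
hotspot screening of a genome, and the preference statistics that relate
the two populations (counts, GC, denaturation temperature, distance).

## Chimera recognition

Reads containing N are removed; the remainder are mapped exactly,
full-length, on both strands against an internal k-mer index, and any read
with a full-length occurrence is discarded as ordinary. For the remaining
candidates the 30-nt 5' seed is looked up exactly on both strands and each
hit is extended base by base until the first mismatch, defining the former
segment and the breakpoint. Multi-hit seeds are resolved by longest
extension, ties broken toward the '+' strand and lower coordinate. The
post-breakpoint suffix is then located as an exact match on the opposite
strand with its junction-side end within 5000 nt of the breakpoint locus
(smallest |distance| wins; ties to the lower coordinate; suffixes shorter
than 10 nt are not searched, which keeps a 10-knt window from matching
short suffixes by chance). Finally the overlap is reconstructed by reverse
extension: the following segment is grown backwards, in read orientation,
while the added genome base still matches the tail of the former segment.
Zero-length overlaps are valid.

Mapping is exact by design. The original analysis used an external aligner
whose mismatch behaviour is not bit-reproducible; exact matching makes
the pipeline deterministic and lets synthetic truth be recovered
coordinate-exactly. Mismatch tolerance is therefore not a supported knob;
sequencing-error robustness is out of scope, consistent with simulating
error-free reads.

### Coordinates and distance

Intervals are 0-based half-open internally; all TSV output is 1-based
inclusive with a header note. Distance follows one convention everywhere:
the gap between the two genomic occurrences of the overlap,
`partner.start - seed.end` for hotspots (>= 0 because screening only looks
downstream) and its read-direction-signed analogue for chimeras.
Histograms bin |distance| into half-open 20-nt bins [0,20), [20,40), ...
over [0, 5000). The source equation for hotspot distance is written
seed-end minus partner-start, which is negative for a downstream partner;
distances are universally reported as magnitudes, so the sign convention
here is necessarily ours. Defining chimera distance on the overlap
occurrences (rather than on whole-segment bounds) makes a planted hotspot
with gap d round-trip to a detected chimera with distance exactly d.

## Hotspot screening

Every k-mer of a chromosome is a seed; every occurrence of its reverse
complement starting in [seed_end, seed_end + window) is one hotspot
(window 5000 nt). Each unordered pair is counted once, from its upstream
member. Pairs whose members would physically overlap (hairpin cores) are
excluded via `partner.start >= seed.end`. Seeds or partners containing N
are skipped. The seed slides to the chromosome end, with the search window
truncated there; nested sub-pairs of longer inverted repeats are counted
at every k independently, which is what produces the observed ~4-fold
decline of counts per added nucleotide.

The production implementation packs k-mers into base-4 integer codes and,
per chromosome, resolves every seed's in-window partners with two
vectorized bisections over a single sorted (code << shift | position)
array; counting never materializes pairs, so genome-scale counting is
memory-safe. For k large enough that the packed key would overflow int64
the code falls back to a per-k-mer grouping path. A deliberately
independent O(n-window) oracle (`brute_force_screen`, plain string
scanning) re-derives the same pairs on small inputs; their set equality
across random sequences, k = 3..15, is the module's core correctness test.

For very short overlaps whose genome-wide enumeration is prohibitive, the
count can be measured on one designated chromosome and scaled by the ratio
of effective (non-N) lengths - the same extrapolation the original
chromosome-10 analysis used.

### Distance uniformity and declustering

On an i.i.d. genome the expected hotspot intensity per seed is
window / 4^k and distances are uniform on [0, window). The per-pair counts
are not independent draws, however: a maximal inverted repeat of length
k + j contributes j + 1 nested k-pairs at nearly identical distances.
These clusters overdisperse 20-nt-bin counts by roughly
E[c^2]/E[c] = 5/3 (cluster sizes are geometric with ratio 1/4), so a raw
chi-square uniformity test rejects even though the distance distribution
is exactly uniform in expectation. The uniformity test therefore
declusters to maximal pairs (`hotspot_distances(..., maximal_only=True)`),
one per inverted repeat, which restores the test's independence
assumption; on a 5-Mb uniform genome the 250-bin chi-square then accepts
comfortably (p ~ 0.9).

## Synthetic data

The generator emulates the study conditions: i.i.d. bases at a target GC
(default 0.41, human-like), optional N runs, 101-nt error-free single-end
reads, overlap lengths uniform on 3-25 nt, junction distances uniform on
[1, 5000] nt, 1000 chimeric plus 1000 normal reads on a 1-Mb chromosome.
One seed drives named substreams (genome, planting, reads), so outputs are
byte-reproducible.

Planted hotspots are written as a random k-mer and its reverse complement
at the chosen gap; the two flanking bases of the partner occurrence are
then resampled so the pair cannot extend to k+1 by chance. Without this
the genome would genuinely contain a longer hotspot at the same locus for
about half the plants, and the recorded truth (overlap length, breakpoint)
would be wrong - maximality is part of what "planting a k-nt hotspot"
means. Occurrences of different hotspots (plus 2-nt guard flanks) are kept
disjoint; the stretches between occurrences remain shared genome, so 1000
hotspots with multi-knt gaps fit comfortably in 1 Mb. Chimeric reads place
the breakpoint so that the former read segment is at least 31 nt (covering
the 30-nt seed) and the post-junction suffix at least 20 nt; a 20-nt
suffix makes a spurious exact in-window match ~1e-8 likely per read, so
coordinate-exact recovery of all 1000 planted chimeras is the expected
outcome for any seed, not a tuned one. Gap-zero plants are allowed for
screening tests but not used for reads: with adjacent occurrences the
junction is slidable and the truth ill-defined.

What the simulation does not model: sequencing errors and base-quality
structure, MDA coverage unevenness and amplification bias, direct-repeat
(same-strand) chimeras, multi-segment (2+-level) chimeras, and paired-end
gap structure (mates are treated as independent single-end reads).
Passing the recovery tests therefore demonstrates the correctness of the
recognition logic in the exact-matching regime, not robustness of the
pipeline to noisy real-world reads.

## Preference statistics

Per-length mean GC is the unweighted mean over records (each chimera or
hotspot counts once); delta-GC is the chimera mean minus the hotspot mean
at the same length. Td per length applies the Wallace-Itakura rule to the
group's average composition, Td = L*(2 + 2*mean_gc), reported to
2 decimals (internal values unrounded). The rule is used verbatim even for
1-2-nt overlaps, where a denaturation temperature is physically
meaningless, and it is known to overestimate for long oligonucleotides;
no nearest-neighbour or salt correction is applied, deliberately. Rows of
the published reference table whose printed Td disagrees with the
recomputation by 0.01 (7, 8, 13, 18 nt) are rounding artifacts of
unprinted GC decimals and are excluded from exact-reproduction checks.
The chimera/hotspot ratio is an elementwise division with missing values
(not infinities) where the hotspot count is zero. Chromosome distributions
can be ploidy-adjusted (factor 2 for autosomes, 1 for X/Y in human-style
data; synthetic genomes default to 1) and come with a least-squares fit of
adjusted count against effective (non-N) chromosome length, degenerate
for single-chromosome genomes. Interval (gene) counting assigns a record
to every interval containing its former segment's start.

## The Td-selection experiment

To show qualitatively why the selection ratio peaks at 12-13 nt, the
package includes an end-to-end synthetic experiment: enumerate every
hotspot for k = 8..16 on a 5-Mb genome, weight each by
exp(-(Td - 30)^2 / (2 * 3^2)) computed from its own overlap Td, and sample
30,000 chimera events in proportion. The genome GC is set to 1/3 so that
the conditional GC of hotspot overlaps is 0.20 (on an i.i.d. genome a base
pair survives the reverse-complement constraint with probability
((1-g)^2 + g^2)/2, of which the GC share is g^2 / ((1-g)^2 + g^2)), making
the expected hotspot Td 2.4k degC - which crosses the 30 degC reaction
temperature exactly between k = 12 and 13. The resulting ratio curve peaks
at 12-13 nt and the GC preference (delta-GC) flips sign across the peak,
the two qualitative signatures of temperature-governed hotspot selection.
The k range starts at 8 because enumerating k < 8 hotspots on 5 Mb
(tens of millions of pairs) adds nothing to the qualitative claim.

## Problem sizes and numerical choices

Test and acceptance workloads use desk-scale inputs chosen to make the
statistics decisive: a 5-Mb genome for screening statistics (the decline
ratio at k = 8..9 still rests on ~100k pairs), a 1-Mb genome for the
1000+1000-read recovery experiment, and 2-50-knt sequences for
oracle-equivalence sweeps. Stochastic assertions use 5-sigma bands
(binomial/Poisson approximations) or alpha = 0.001 tests, so they hold for
any seed. Ties anywhere in recognition resolve deterministically
(documented above), and all outputs are invariant to read input order.

## Known limitations

* Exact matching only: one sequencing error in a seed, suffix or overlap
  hides or truncates a chimera; real-data sensitivity is therefore lower
  than the synthetic round-trip suggests.
* Hotspot screening treats both strands implicitly (a pair and its
  reverse complement are the same pair); it does not report strand-specific
  template usage.
* The Wallace rule ignores sequence order, salt and neighbour effects; Td
  values are comparative indices, not physical predictions.
* Extrapolated counts for short overlaps inherit any compositional bias of
  the designated chromosome.
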
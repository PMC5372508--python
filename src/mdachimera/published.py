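"""Published per-overlap-length summary of inverted-segment MDA chimeras.

Reference input for the Wallace-rule temperature tables: the per-length
chimera counts and mean overlap GC content reported by a large-scale human
(hg19) MDA resequencing analysis (36.7 million 1-level inverted chimeras).
Only the (length, count, mean GC) triples are stored; Td values are always
recomputed from them.
"""

from __future__ import annotations

import pandas as pd

# (overlap length nt, number of chimeras, mean overlap GC fraction)
CHIMERA_OVERLAP_SUMMARY: tuple[tuple[int, int, float], ...] = (
    (1, 11992, 0.3677),
    (2, 22292, 0.4440),
    (3, 71262, 0.4988),
    (4, 208729, 0.4531),
    (5, 336932, 0.4426),
    (6, 476409, 0.4284),
    (7, 547136, 0.4182),
    (8, 528555, 0.4053),
    (9, 459454, 0.3919),
    (10, 356470, 0.3782),
    (11, 253356, 0.3617),
    (12, 163502, 0.3435),
    (13, 97992, 0.3271),
    (14, 54711, 0.3108),
    (15, 28218, 0.2993),
    (16, 14630, 0.2859),
    (17, 7429, 0.2805),
    (18, 4189, 0.2979),
    (19, 2310, 0.3213),
    (20, 1661, 0.3399),
    (21, 1200, 0.3580),
    (22, 932, 0.3778),
    (23, 740, 0.4011),
    (24, 587, 0.3896),
    (25, 480, 0.4010),
)

# Overall mean overlap GC fractions of the same study's two populations.
MEAN_CHIMERA_OVERLAP_GC = 0.3902
MEAN_HOTSPOT_OVERLAP_GC = 0.3390


def published_overlap_table() -> pd.DataFrame:
    """The published summary as a DataFrame (overlap_length, n_chimeras, mean_gc)."""
    return pd.DataFrame(
        CHIMERA_OVERLAP_SUMMARY, columns=["overlap_length", "n_chimeras", "mean_gc"]
    )
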
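"""Wallace-rule denaturation temperatures for the published chimera table.

The published per-overlap-length summary of 36.7 million human MDA chimeras
gives, for each overlap length, the chimera count and the mean overlap GC
content. The Wallace-Itakura rule Td = 4(C+G) + 2(A+T) - equivalently
L*(2 + 2*gc) on the average composition - turns those into the estimated
denaturation temperature of the overlap duplex.
"""

from mdachimera import td_table
from mdachimera.published import published_overlap_table

table = td_table(published_overlap_table())
print(table.to_string(index=False))
# Td grows with overlap length; around 12-13 nt it crosses ~30 degC, the
# MDA reaction temperature - the lengths whose hotspots are preferentially
# selected as chimera templates.
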
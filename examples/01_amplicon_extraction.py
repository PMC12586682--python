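"""In-silico PCR and pairwise amplicon comparison.

Builds a synthetic species panel, embeds one amplicon in flanking sequence to
mimic a whole mitogenome, extracts the product with the universal 12S primer
pair, and counts nucleotide differences between close species pairs.
"""

from meltid.amplicon import in_silico_pcr, pairwise_differences
from meltid.fixtures import make_panel, make_template

panel = make_panel(10, seed=7)
template = make_template(panel[0], seed=7)

product = in_silico_pcr(template)
print(f"template length : {len(template)} bp")
print(f"product length  : {len(product)} bp (primer footprints included)")

d4 = pairwise_differences(panel[0], panel[1])
d1 = pairwise_differences(panel[1], panel[4])
print(f"designated close pair   : {d4} nucleotide differences")
print(f"single-nucleotide pair  : {d1} nucleotide difference")

# The product length is fixed by the assay design; the difference counts are
# the sequence-level separations that downstream melt curves must resolve.
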
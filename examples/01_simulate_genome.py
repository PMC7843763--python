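"""Build a synthetic rice-like genome annotation and write it to disk.

The generator packs non-overlapping multi-exon gene models on a few
chromosomes, sprinkles TEs according to superfamily weights, and adds an
unmethylated chloroplast contig used later as the bisulfite error control.
"""

from collections import Counter

import oryzanc as oz
import oryzanc.simulate as sim
from oryzanc.io import write_gff3, write_te_bed

cfg = oz.SimConfig(seed=42)
ann = sim.generate_annotation(cfg)

write_gff3(ann, "synthetic_annotation.gff3")
write_te_bed(ann.tes, "synthetic_te.bed")

print(f"chromosomes: {ann.chromosomes}")
print(f"genes: {len(ann.genes)} "
      f"({sum(g.is_te_gene for g in ann.genes.values())} TE-genes)")
print(f"TEs by superfamily: {Counter(t.superfamily for t in ann.tes)}")
print(f"control contig (no methylation): {ann.control_contig}")
# The TE superfamily counts follow the configured genome-wide weights;
# every downstream stage reads this annotation as its coordinate universe.
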
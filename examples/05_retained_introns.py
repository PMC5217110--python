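"""Spliced vs retained-intron isoforms: where the intron sits matters.

Isoform pairs differing by exactly one retained intron are found from the
annotation, the retained intron is classified by transcript region (5'UTR,
CDS, 3'UTR), and SI-vs-RI abundance and TEI are compared per region. A
retained intron in the 5'UTR depresses ribosome association of the RI
isoform; in the CDS or 3'UTR the effect is weak.
"""

from teiscope.expression import build_tei_table
from teiscope.isoforms import compare_si_ri, find_si_ri_pairs
from teiscope.sim import SimParams, generate_dataset

ds = generate_dataset(SimParams(seed=1, ri_fraction=0.3))
pairs = find_si_ri_pairs(ds.genes, ds.genome)
print(f"{len(pairs)} SI/RI isoform pairs found")
from collections import Counter

print("retained introns by region:", dict(Counter(p.region for p in pairs)))

iso_tei = build_tei_table(
    [m for m, _ in ds.isoform_expression.values()],
    [t for _, t in ds.isoform_expression.values()],
)
summary = compare_si_ri(pairs, iso_tei[iso_tei["tissue"] == "shoot"])
cols = ["region", "n_pairs", "si_median_tei", "ri_median_tei", "ks_p_bh_tei"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print()
print("Only the 5'UTR region shows a depressed RI median TEI with a")
print("significant KS test — the generator's RI penalty applies there only.")
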
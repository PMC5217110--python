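"""Translatome enrichment index for transposable elements active in rice.

TEI = TRAP-seq FPKM / mRNA-seq FPKM. A gene is transcribed when its
mRNA-seq FPKM >= 1 and translated when its TRAP-seq FPKM >= 1; TEI is NA
for untranscribed genes. The FPKM pairs below are the published per-tissue
measurements for elements with documented activity in the Nipponbare
genome.
"""

import math

from teiscope.expression import call_expressed, compute_tei

ELEMENTS = [
    ("Tos17", "callus", 15.03, 0.58),
    ("Lullaby", "callus", 13.01, 15.61),
    ("Osr10", "panicle", 0.01, 0.00),
    ("Osr37", "callus", 10.12, 4.83),
    ("Ping", "panicle", 16.50, 9.41),
    ("Pong", "callus", 6.40, 6.36),
]

print(f"{'element':<10}{'tissue':<10}{'mRNA':>8}{'TRAP':>8}{'TEI':>7}  status")
for name, tissue, mrna, trap in ELEMENTS:
    tei = compute_tei(mrna, trap)
    tei_str = "NA" if math.isnan(tei) else f"{tei:.2f}"
    if not call_expressed(mrna):
        status = "not expressed"
    elif call_expressed(trap):
        status = "translated"
    else:
        status = "transcribed only"
    print(f"{name:<10}{tissue:<10}{mrna:>8.2f}{trap:>8.2f}{tei_str:>7}  {status}")

print()
print("A TEI near 1 means the transcript pool is proportionally represented")
print("on ribosomes; Tos17's TEI of 0.04 means almost none of its abundant")
print("callus transcripts are ribosome-associated.")
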
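"""Codon usage tables and synonymous-usage comparison between TEI extremes.

Builds 64-codon count/frequency tables for gene sets (standard nuclear
genetic code), selects genes with extreme translatome enrichment
(TEI < 0.2 vs TEI >= 3.0), and compares synonymous codon usage between the
two classes family-by-family with chi-square tests, plus designated codon
pairs differing only at the first or only at the third position.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import write_tsv
from .stats import bh_adjust, chi2_contingency

logger = logging.getLogger("teiscope")

TEI_LOW = 0.2
TEI_HIGH = 3.0

BASES = "TCAG"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]

# Standard nuclear genetic code, TCAG order.
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = dict(zip(CODONS, _AA))
STOP_CODONS = {c for c, a in GENETIC_CODE.items() if a == "*"}

# amino acid -> synonymous codon family
FAMILIES: dict[str, list[str]] = {}
for codon, aa in GENETIC_CODE.items():
    FAMILIES.setdefault(aa, []).append(codon)

#: the 18 amino acids with more than one synonymous codon (stops excluded)
MULTI_CODON_FAMILIES = sorted(aa for aa, cs in FAMILIES.items() if aa != "*" and len(cs) > 1)

# synonymous codon pairs differing only at the first position
FIRST_POSITION_PAIRS = [("CTA", "TTA"), ("CTG", "TTG"), ("CGA", "AGA"), ("CGG", "AGG")]
# representative synonymous pairs differing only at the third position
THIRD_POSITION_PAIRS = [("CCG", "CCC"), ("CTG", "CTC"), ("GCG", "GCC"), ("ACG", "ACC")]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class CodonUsageTable:
    """Counts of all 64 codons for a gene set, with within-family frequencies."""

    set_label: str
    counts: dict[str, int]
    n_skipped: int = 0
    n_bad_frame: int = 0
    frequencies: dict[str, float] = field(init=False)
    n_codons_total: int = field(init=False)

    def __post_init__(self) -> None:
        assert set(self.counts) == set(CODONS), "table must have exactly 64 codon keys"
        self.n_codons_total = sum(self.counts.values())
        self.frequencies = {}
        for aa, codons in FAMILIES.items():
            total = sum(self.counts[c] for c in codons)
            for c in codons:
                self.frequencies[c] = self.counts[c] / total if total else 0.0


def codon_frequency(cds_sequences: dict[str, str] | list[str], set_label: str = "") -> CodonUsageTable:
    """Accumulate codon counts over in-frame CDS sequences.

    Sequences whose length is not a multiple of 3 are excluded and logged.
    Codons containing an ambiguous base (N) are skipped and tallied in
    `n_skipped`. RNA input (U) is accepted and normalised to DNA.
    """
    if isinstance(cds_sequences, dict):
        items = cds_sequences.items()
    else:
        items = ((str(i), s) for i, s in enumerate(cds_sequences))
    counts = {c: 0 for c in CODONS}
    skipped = 0
    bad = 0
    for name, seq in items:
        seq = _normalize(seq)
        if len(seq) % 3 != 0:
            logger.warning("sequence %s length %d not divisible by 3; excluded", name, len(seq))
            bad += 1
            continue
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                skipped += 1
    return CodonUsageTable(set_label=set_label, counts=counts, n_skipped=skipped, n_bad_frame=bad)


def gc3(cds_sequence: str) -> float:
    """GC fraction at third codon positions of an in-frame CDS.

    Third positions holding an ambiguous base are excluded from both the
    numerator and the denominator; raises on zero valid codons.
    """
    seq = _normalize(cds_sequence)
    thirds = [seq[i] for i in range(2, len(seq) - (len(seq) % 3), 3)]
    valid = [b for b in thirds if b in "ACGT"]
    if not valid:
        raise ValueError("gc3 undefined: no valid third-position bases")
    return sum(1 for b in valid if b in "GC") / len(valid)


def select_tei_extremes(
    tei: pd.Series,
    low_cutoff: float = TEI_LOW,
    high_cutoff: float = TEI_HIGH,
) -> tuple[set[str], set[str]]:
    """Split genes into the lowest (< 0.2) and highest (>= 3.0) TEI classes.

    The low boundary is exclusive and the high boundary inclusive; a gene
    with TEI exactly 0.2 falls in neither class.
    """
    tei = tei.dropna()
    low = set(tei.index[tei < low_cutoff])
    high = set(tei.index[tei >= high_cutoff])
    if not low or not high:
        raise ValueError(
            f"empty TEI class (low n={len(low)}, high n={len(high)}): provide a larger input"
        )
    return low, high


def compare_synonymous_usage(
    low: CodonUsageTable,
    high: CodonUsageTable,
    first_position_pairs: list[tuple[str, str]] | None = None,
    third_position_pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chi-square per synonymous family plus designated codon-pair ratios.

    For each of the 18 multi-codon amino-acid families, a chi-square test of
    the low-vs-high count contingency (2 x family-size); BH adjustment spans
    the family tests. For each designated codon pair, the within-class count
    ratio first/second codon is reported for both classes. Families with no
    observations in one class are skipped and flagged.
    """
    fams = []
    pvals = []
    for aa in MULTI_CODON_FAMILIES:
        # codons unobserved in both classes carry no information and would
        # zero out expected frequencies; drop them from the contingency
        codons = [c for c in FAMILIES[aa] if low.counts[c] + high.counts[c] > 0]
        row_low = [low.counts[c] for c in codons]
        row_high = [high.counts[c] for c in codons]
        if len(codons) < 2 or sum(row_low) == 0 or sum(row_high) == 0:
            fams.append({"family": aa, "chi2": float("nan"), "p_raw": float("nan"), "skipped": True})
            continue
        chi2, p, _ = chi2_contingency([row_low, row_high])
        fams.append({"family": aa, "chi2": chi2, "p_raw": p, "skipped": False})
        pvals.append(p)
    fam_df = pd.DataFrame(fams)
    adj = iter(bh_adjust(pvals))
    fam_df["p_bh"] = [next(adj) if not s else float("nan") for s in fam_df["skipped"]]

    pair_rows = []
    for kind, pairs in (
        ("first_position", first_position_pairs or FIRST_POSITION_PAIRS),
        ("third_position", third_position_pairs or THIRD_POSITION_PAIRS),
    ):
        for c1, c2 in pairs:
            pair_rows.append(
                {
                    "kind": kind,
                    "pair": f"{c1}/{c2}",
                    "ratio_low": low.counts[c1] / low.counts[c2] if low.counts[c2] else float("nan"),
                    "ratio_high": high.counts[c1] / high.counts[c2] if high.counts[c2] else float("nan"),
                }
            )
    return fam_df, pd.DataFrame(pair_rows)


def write_usage_table(table: CodonUsageTable, path) -> None:
    rows = [
        {
            "set": table.set_label,
            "codon": c,
            "amino_acid": GENETIC_CODE[c],
            "count": table.counts[c],
            "family_frequency": table.frequencies[c],
        }
        for c in CODONS
    ]
    write_tsv(pd.DataFrame(rows), path)
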
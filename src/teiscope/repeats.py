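"""Transposon-gene validation by repeat-library mask coverage.

Each candidate cDNA is compared against a repeat library; the fraction of
the cDNA covered by exact, ungapped matches of a minimum length (either
strand) is the masked fraction, and a cDNA with >= 50% of its length masked
is validated as a true transposon gene.

Matching is exact k-mer anchoring with maximal extension: every maximal
common substring of length >= min_match between the cDNA and any library
sequence (or its reverse complement) contributes a masked interval. All
seed hits on one alignment diagonal form contiguous runs, so maximal
matches are recovered exactly by merging consecutive seed positions per
diagonal — no heuristic extension step is needed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import Interval, interval_length, merge_intervals, read_fasta, revcomp, write_tsv

DEFAULT_MIN_MATCH = 50
MASK_FRACTION = 0.5


@dataclass
class MaskResult:
    gene_id: str
    cdna_length: int
    masked_intervals: list[Interval]  # 0-based half-open, merged
    masked_fraction: float
    is_transposon_validated: bool


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(seq) - k + 1):
        index[seq[j : j + k]].append(j)
    return index


def _match_intervals(cdna: str, target: str, k: int) -> list[Interval]:
    """Maximal exact-match intervals (length >= k) of cdna against target."""
    if len(target) < k or len(cdna) < k:
        return []
    index = _kmer_index(target, k)
    # seed positions per diagonal (i - j); consecutive i on a diagonal are one run
    diagonals: dict[int, list[int]] = defaultdict(list)
    for i in range(len(cdna) - k + 1):
        for j in index.get(cdna[i : i + k], ()):
            diagonals[i - j].append(i)
    intervals: list[Interval] = []
    for positions in diagonals.values():
        positions.sort()
        run_start = prev = positions[0]
        for i in positions[1:]:
            if i == prev + 1:
                prev = i
            else:
                intervals.append((run_start, prev + k))
                run_start = prev = i
        intervals.append((run_start, prev + k))
    return intervals


def mask_coverage(
    gene_id: str,
    cdna: str,
    library: dict[str, str],
    min_match: int = DEFAULT_MIN_MATCH,
) -> MaskResult:
    """Mask a cDNA with a repeat library and report covered fraction.

    Matches against each library sequence and its reverse complement are
    merged into a single interval union before the fraction is computed, so
    overlapping hits are never double-counted. An empty library yields
    fraction 0.
    """
    if not cdna:
        raise ValueError("empty cDNA")
    if min_match < 11:
        raise ValueError("min_match must be >= 11")
    cdna = cdna.upper()
    intervals: list[Interval] = []
    for seq in library.values():
        seq = seq.upper()
        intervals.extend(_match_intervals(cdna, seq, min_match))
        intervals.extend(_match_intervals(cdna, revcomp(seq), min_match))
    merged = merge_intervals(intervals)
    fraction = interval_length(merged) / len(cdna)
    return MaskResult(
        gene_id=gene_id,
        cdna_length=len(cdna),
        masked_intervals=merged,
        masked_fraction=fraction,
        is_transposon_validated=classify_transposon_fraction(fraction),
    )


def classify_transposon_fraction(masked_fraction: float) -> bool:
    """True when at least half of the cDNA is masked (boundary inclusive)."""
    return masked_fraction >= MASK_FRACTION


def classify_transposon(result: MaskResult) -> bool:
    return classify_transposon_fraction(result.masked_fraction)


def filter_transposons(
    cdna_fasta: str | Path,
    library_fasta: str | Path,
    min_match: int = DEFAULT_MIN_MATCH,
) -> pd.DataFrame:
    """Run the masker over a cDNA FASTA; one row per cDNA."""
    cdnas = read_fasta(cdna_fasta)
    library = read_fasta(library_fasta)
    rows = []
    for gene_id, seq in cdnas.items():
        r = mask_coverage(gene_id, seq, library, min_match=min_match)
        rows.append(
            {
                "gene_id": r.gene_id,
                "cdna_len": r.cdna_length,
                "masked_bp": interval_length(r.masked_intervals),
                "masked_fraction": r.masked_fraction,
                "validated": r.is_transposon_validated,
            }
        )
    return pd.DataFrame(rows)


def write_mask_table(df: pd.DataFrame, path: str | Path) -> None:
    write_tsv(df, path)
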
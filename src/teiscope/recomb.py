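"""Local recombination rate from a genetic-marker map, and gene correlations.

Rates (cM/Mb) are measured in nominal 1-Mb bins along each chromosome; a
bin containing no marker is merged with the following bin(s) until at least
one marker is enclosed, so marker deserts yield bins longer than 1 Mb. cM
positions at bin edges come from linear interpolation between the flanking
markers, which makes the per-chromosome map length exactly additive over
bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import write_tsv
from .stats import pearson_corr

logger = logging.getLogger("teiscope")

BIN_BP = 1_000_000


@dataclass
class RecombBin:
    chrom: str
    start_bp: int  # 0-based half-open
    end_bp: int
    rate: float  # cM/Mb
    n_markers: int


def bin_recombination(markers: pd.DataFrame, bin_bp: int = BIN_BP) -> list[RecombBin]:
    """Bin a marker map (columns chrom, bp, cM) into recombination-rate bins.

    Markers must be sorted by bp within each chromosome with non-decreasing
    cM (violations are flagged and clipped to monotone). Chromosomes with
    fewer than 2 markers are skipped with a warning. Bins tile the interval
    from the first to the last marker of each chromosome.
    """
    bins: list[RecombBin] = []
    for chrom, grp in markers.groupby("chrom", sort=True):
        grp = grp.sort_values("bp")
        bp = grp["bp"].to_numpy(float)
        cm = grp["cM"].to_numpy(float)
        if len(bp) < 2:
            logger.warning("chromosome %s has <2 markers; skipped", chrom)
            continue
        if (np.diff(cm) < 0).any():
            logger.warning("chromosome %s: non-monotone cM values; clipped to monotone", chrom)
            cm = np.maximum.accumulate(cm)
        first, last = bp[0], bp[-1]
        if last == first:
            logger.warning("chromosome %s: all markers at one position; skipped", chrom)
            continue
        edges = [first]
        pos = first
        while pos + bin_bp < last:
            pos += bin_bp
            edges.append(pos)
        edges.append(last)
        # merge marker-less bins forward until each encloses >= 1 marker;
        # the final span always encloses the last marker, so the loop always
        # closes its last bin
        merged_edges = [edges[0]]
        counts: list[int] = []
        pending = 0
        for idx, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            is_final = idx == len(edges) - 2
            if is_final:
                n = int(np.sum((bp >= lo) & (bp <= hi)))
            else:
                n = int(np.sum((bp >= lo) & (bp < hi)))
            pending += n
            if pending >= 1:
                merged_edges.append(hi)
                counts.append(pending)
                pending = 0
        cm_at = np.interp(merged_edges, bp, cm)
        for i in range(len(counts)):
            lo, hi = merged_edges[i], merged_edges[i + 1]
            span_mb = (hi - lo) / 1e6
            rate = (cm_at[i + 1] - cm_at[i]) / span_mb
            bins.append(RecombBin(chrom=str(chrom), start_bp=int(lo), end_bp=int(hi), rate=float(rate), n_markers=counts[i]))
    return bins


def bins_to_frame(bins: list[RecombBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": b.chrom, "start_bp": b.start_bp, "end_bp": b.end_bp, "rate": b.rate, "n_markers": b.n_markers}
            for b in bins
        ]
    )


def assign_gene_rates(bins: list[RecombBin], genes: pd.DataFrame) -> pd.DataFrame:
    """Attach each gene (columns chrom, midpoint) the rate of its bin.

    A gene is assigned to the bin whose half-open [start, end) interval
    contains its midpoint (the final bin of a chromosome is closed above).
    Genes falling outside all bins are excluded and counted in the log.
    """
    by_chrom: dict[str, list[RecombBin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    rates = []
    excluded = 0
    for _, row in genes.iterrows():
        rate = np.nan
        cbins = by_chrom.get(row["chrom"], [])
        for i, b in enumerate(cbins):
            last = i == len(cbins) - 1
            mid = row["midpoint"]
            if b.start_bp <= mid < b.end_bp or (last and mid == b.end_bp):
                rate = b.rate
                break
        if np.isnan(rate):
            excluded += 1
        rates.append(rate)
    if excluded:
        logger.info("%d genes fall outside all recombination bins; excluded", excluded)
    out = genes.copy()
    out["recomb_rate"] = rates
    return out


def correlate_bins_with_genes(
    bins: list[RecombBin],
    genes: pd.DataFrame,
) -> dict[str, tuple[float, float]]:
    """Gene-level Pearson correlation of bin recombination rate with CDS GC
    and with TEI.

    `genes` needs columns chrom, midpoint, cds_gc and tei. Returns
    {"rate_vs_gc": (r, p), "rate_vs_tei": (r, p)}; constant rates raise a
    zero-variance error from the correlation layer.
    """
    assigned = assign_gene_rates(bins, genes).dropna(subset=["recomb_rate"])
    results: dict[str, tuple[float, float]] = {}
    gc = assigned.dropna(subset=["cds_gc"])
    results["rate_vs_gc"] = pearson_corr(gc["recomb_rate"], gc["cds_gc"])
    tei = assigned.dropna(subset=["tei"])
    results["rate_vs_tei"] = pearson_corr(tei["recomb_rate"], tei["tei"])
    return results


def write_bins(bins: list[RecombBin], path) -> None:
    write_tsv(bins_to_frame(bins), path)
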
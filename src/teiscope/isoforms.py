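"""Spliced-intron vs retained-intron (SI/RI) isoform analysis.

Pairs isoforms of one gene that differ by exactly one retained intron,
classifies the retained intron by the transcript region it falls in
(5'UTR, CDS or 3'UTR of the spliced isoform), and compares expression and
translatome enrichment between the SI and RI members of each pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel, Interval, Transcript, extract_sequence, gc_fraction, merge_intervals
from .stats import bh_adjust, chi2_contingency, ks_two_sample

logger = logging.getLogger("teiscope")

REGIONS = ("5UTR", "CDS", "3UTR")


@dataclass
class IsoformPair:
    gene_id: str
    si_isoform_id: str
    ri_isoform_id: str
    retained_intron: Interval  # genomic, 0-based half-open
    region: str  # one of REGIONS
    intron_len: int
    intron_gc: float | None = None


def _region_spans(t: Transcript, strand: str) -> dict[str, Interval]:
    """Contiguous genomic span of each transcript region of the SI isoform.

    The transcript span is cut at the genomic CDS boundaries, so the three
    regions tile the whole pre-mRNA; introns (absent from exons) therefore
    always project onto at least one region.
    """
    if not t.cds:
        raise ValueError(f"isoform {t.transcript_id} has no annotated CDS")
    tx_s, tx_e = t.span()
    cds_s = min(s for s, _ in t.cds)
    cds_e = max(e for _, e in t.cds)
    upstream, downstream = ("5UTR", "3UTR") if strand == "+" else ("3UTR", "5UTR")
    spans: dict[str, Interval] = {"CDS": (cds_s, cds_e)}
    if tx_s < cds_s:
        spans[upstream] = (tx_s, cds_s)
    if cds_e < tx_e:
        spans[downstream] = (cds_e, tx_e)
    return spans


def classify_ri_region(intron: Interval, si: Transcript, strand: str) -> str:
    """Region of the spliced isoform with the largest overlap with the intron.

    Overlap is measured in genomic bases against the contiguous genomic span
    of each region; ties break toward CDS. Zero overlap with every region
    signals an inconsistent annotation and raises.
    """
    spans = _region_spans(si, strand)
    s, e = intron
    overlaps = {
        region: max(0, min(e, re) - max(s, rs)) for region, (rs, re) in spans.items()
    }
    best = max(overlaps.values())
    if best == 0:
        raise ValueError(f"intron {intron} overlaps no region of {si.transcript_id}")
    candidates = [r for r, o in overlaps.items() if o == best]
    return "CDS" if "CDS" in candidates else candidates[0]


def find_si_ri_pairs(genes: list[GeneModel], genome: dict[str, str] | None = None) -> list[IsoformPair]:
    """Find isoform pairs differing by exactly one retained intron.

    A pair (SI, RI) is emitted when the RI isoform's exonic region equals
    the SI isoform's plus exactly one of the SI isoform's introns. Isoform
    combinations differing by two or more introns are not paired (logged).
    Intron GC is computed on the genomic intron sequence when a genome is
    supplied.
    """
    pairs: list[IsoformPair] = []
    for g in genes:
        if len(g.transcripts) < 2:
            continue
        for i, a in enumerate(g.transcripts):
            for b in g.transcripts[i + 1 :]:
                pair = _pair_transcripts(g, a, b, genome)
                if pair is not None:
                    pairs.append(pair)
    return pairs


def _pair_transcripts(
    g: GeneModel, a: Transcript, b: Transcript, genome: dict[str, str] | None
) -> IsoformPair | None:
    ex_a, ex_b = merge_intervals(a.exons), merge_intervals(b.exons)
    if ex_a == ex_b:
        return None
    # the RI isoform is the one with the larger exonic footprint
    introns_a = set(a.introns())
    introns_b = set(b.introns())
    if introns_a > introns_b:
        si, ri = a, b
        diff = introns_a - introns_b
    elif introns_b > introns_a:
        si, ri = b, a
        diff = introns_b - introns_a
    else:
        return None
    if len(diff) != 1:
        logger.info(
            "gene %s: isoforms %s/%s differ by %d introns; not paired",
            g.gene_id, a.transcript_id, b.transcript_id, len(diff),
        )
        return None
    intron = next(iter(diff))
    # the retained intron must be exonic in the RI isoform
    if merge_intervals(ri.exons + [intron]) != merge_intervals(ri.exons):
        return None
    region = classify_ri_region(intron, si, g.strand)
    intron_gc = None
    if genome is not None:
        intron_gc = gc_fraction(extract_sequence(genome, g.chrom, [intron], g.strand))
    return IsoformPair(
        gene_id=g.gene_id,
        si_isoform_id=si.transcript_id,
        ri_isoform_id=ri.transcript_id,
        retained_intron=intron,
        region=region,
        intron_len=intron[1] - intron[0],
        intron_gc=intron_gc,
    )


def compare_si_ri(pairs: list[IsoformPair], tei_table: pd.DataFrame) -> pd.DataFrame:
    """Per-region SI-vs-RI comparison of abundance and TEI.

    `tei_table` must be isoform-resolved (gene_id column holding isoform
    ids); gene-level tables cannot be apportioned to isoforms and are
    rejected when isoform ids are missing. Reports per-region medians of
    mRNA FPKM, TRAP FPKM and TEI for SI and RI members, with KS tests on
    TRAP FPKM and on TEI (BH-adjusted across the three regions per metric).
    Regions with fewer than 2 pairs get summaries but no test.
    """
    iso_ids = {p.si_isoform_id for p in pairs} | {p.ri_isoform_id for p in pairs}
    present = iso_ids & set(tei_table["gene_id"])
    if not present:
        raise ValueError(
            "expression table contains none of the isoform ids; isoform-resolved tables are required"
        )
    idx = tei_table.set_index("gene_id")
    rows = []
    ks_jobs: list[tuple[int, str, np.ndarray, np.ndarray]] = []
    for region in REGIONS:
        rp = [p for p in pairs if p.region == region]
        si_ids = [p.si_isoform_id for p in rp if p.si_isoform_id in idx.index]
        ri_ids = [p.ri_isoform_id for p in rp if p.ri_isoform_id in idx.index]
        rec = {
            "region": region,
            "n_pairs": len(rp),
            "median_intron_len": float(np.median([p.intron_len for p in rp])) if rp else np.nan,
        }
        for label, ids in (("si", si_ids), ("ri", ri_ids)):
            sub = idx.loc[idx.index.intersection(ids)]
            for metric in ("mrna_fpkm", "trap_fpkm", "tei"):
                vals = sub[metric].dropna().to_numpy(float)
                rec[f"{label}_median_{metric}"] = float(np.median(vals)) if vals.size else np.nan
        for metric in ("trap_fpkm", "tei"):
            a = idx.loc[idx.index.intersection(si_ids), metric].dropna().to_numpy(float)
            b = idx.loc[idx.index.intersection(ri_ids), metric].dropna().to_numpy(float)
            if a.size >= 2 and b.size >= 2:
                ks_jobs.append((len(rows), metric, a, b))
            rec[f"ks_p_{metric}"] = np.nan
            rec[f"ks_p_bh_{metric}"] = np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)
    for metric in ("trap_fpkm", "tei"):
        jobs = [(i, a, b) for i, m, a, b in ks_jobs if m == metric]
        ps = []
        for i, a, b in jobs:
            _, p = ks_two_sample(a, b)
            out.loc[i, f"ks_p_{metric}"] = p
            ps.append(p)
        for (i, _, _), p_adj in zip(jobs, bh_adjust(ps)):
            out.loc[i, f"ks_p_bh_{metric}"] = p_adj
    return out


def go_category_enrichment(
    pair_genes: set[str],
    background: set[str],
    go_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-term chi-square enrichment of SI/RI genes vs the background.

    For each biological-process term, a 2x2 contingency of term membership
    against pair membership (pair genes vs the rest of the background) is
    tested with Pearson chi-square; raw and BH-adjusted p-values are
    reported and tables with an expected cell below 5 are flagged.
    """
    go = go_table[go_table["gene_id"].isin(background)]
    n_bg = len(background)
    n_pair = len(pair_genes & background)
    rows = []
    for (term_id, term_name), grp in go.groupby(["term_id", "term_name"], sort=True):
        term_genes = set(grp["gene_id"])
        a = len(term_genes & pair_genes)  # in pair, in term
        b = n_pair - a
        c = len(term_genes) - a  # out of pair, in term
        d = (n_bg - n_pair) - c
        table = np.array([[a, b], [c, d]], dtype=float)
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            continue
        chi2, p, _ = chi2_contingency(table)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "n_term": len(term_genes),
                "n_term_in_pairs": a,
                "chi2": chi2,
                "p_raw": p,
                "low_expected": bool(expected.min() < 5),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = bh_adjust(out["p_raw"].tolist())
        out = out.sort_values("p_raw").reset_index(drop=True)
    return out


def pairs_to_frame(pairs: list[IsoformPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "si_isoform_id": p.si_isoform_id,
                "ri_isoform_id": p.ri_isoform_id,
                "intron_start": p.retained_intron[0],
                "intron_end": p.retained_intron[1],
                "region": p.region,
                "intron_len": p.intron_len,
                "intron_gc": p.intron_gc,
            }
            for p in pairs
        ]
    )
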
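"""Translatome enrichment: expression calls, TEI, and translatome summaries.

The translatome enrichment index (TEI) of a gene in a tissue is the ratio of
its TRAP-seq FPKM (mRNA co-purified with tagged ribosomes) to its mRNA-seq
FPKM (steady-state transcript abundance). A gene is called transcribed when
its mRNA-seq FPKM >= 1 and translated when its TRAP-seq FPKM >= 1; TEI is
reported only for transcribed genes and is NA otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import NA, read_tsv, write_tsv

logger = logging.getLogger("teiscope")

FPKM_EXPRESSED = 1.0

MRNA = "mRNA-seq"
TRAP = "TRAP-seq"


@dataclass
class ExpressionTable:
    """Per-tissue gene-to-FPKM mapping for a single assay."""

    tissue: str
    assay: str  # MRNA or TRAP
    values: pd.Series  # index: gene_id, values: FPKM >= 0

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError(f"negative FPKM in {self.tissue}/{self.assay}")
        if self.values.index.duplicated().any():
            raise ValueError(f"duplicate gene ids in {self.tissue}/{self.assay}")

    def fpkm(self, gene_id: str) -> float:
        """FPKM for a gene; genes absent from the table count as 0."""
        return float(self.values.get(gene_id, 0.0))


def read_expression_tsv(path: str | Path, tissue: str, assay: str) -> ExpressionTable:
    df = read_tsv(path)
    if list(df.columns[:2]) != ["gene_id", "fpkm"]:
        raise ValueError(f"{path}: expected columns gene_id, fpkm")
    return ExpressionTable(tissue=tissue, assay=assay, values=df.set_index("gene_id")["fpkm"].astype(float))


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    df = table.values.rename("fpkm").rename_axis("gene_id").reset_index()
    write_tsv(df, path)


def call_expressed(fpkm: float, threshold: float = FPKM_EXPRESSED) -> bool:
    """True when FPKM meets the expression threshold (boundary inclusive)."""
    if fpkm < 0:
        raise ValueError(f"negative FPKM: {fpkm}")
    return fpkm >= threshold


def compute_tei(mrna_fpkm: float, trap_fpkm: float) -> float:
    """TRAP FPKM / mRNA FPKM, or NaN when the gene is not transcribed.

    TEI is undefined (NaN, written as NA) when mRNA FPKM < 1: a ratio over a
    sub-threshold denominator is dominated by sampling noise.
    """
    if mrna_fpkm < 0 or trap_fpkm < 0:
        raise ValueError("FPKM must be non-negative")
    if mrna_fpkm < FPKM_EXPRESSED:
        return math.nan
    return trap_fpkm / mrna_fpkm


def build_tei_table(
    mrna_tables: list[ExpressionTable],
    trap_tables: list[ExpressionTable],
) -> pd.DataFrame:
    """Join paired mRNA-seq/TRAP-seq tables into a long TEI table.

    One row per gene per tissue with columns gene_id, tissue, mrna_fpkm,
    trap_fpkm, tei, transcribed, translated. Genes present in only one assay
    get FPKM 0 in the other (logged once per pair). Full precision is kept;
    rounding happens only at the reporting layer.
    """
    by_tissue_m = {t.tissue: t for t in mrna_tables}
    by_tissue_t = {t.tissue: t for t in trap_tables}
    if set(by_tissue_m) != set(by_tissue_t):
        raise ValueError("each tissue needs both an mRNA-seq and a TRAP-seq table")
    rows = []
    for tissue in by_tissue_m:
        m, t = by_tissue_m[tissue].values, by_tissue_t[tissue].values
        only_m = m.index.difference(t.index)
        only_t = t.index.difference(m.index)
        if len(only_m) or len(only_t):
            logger.info(
                "tissue %s: %d genes missing from TRAP-seq, %d from mRNA-seq; treated as FPKM 0",
                tissue, len(only_m), len(only_t),
            )
        genes = m.index.union(t.index)
        mv = m.reindex(genes, fill_value=0.0).to_numpy(float)
        tv = t.reindex(genes, fill_value=0.0).to_numpy(float)
        tei = np.where(mv >= FPKM_EXPRESSED, np.divide(tv, np.where(mv == 0, np.nan, mv)), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "tissue": tissue,
                    "mrna_fpkm": mv,
                    "trap_fpkm": tv,
                    "tei": tei,
                    "transcribed": mv >= FPKM_EXPRESSED,
                    "translated": tv >= FPKM_EXPRESSED,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_tei_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["tei"] = out["tei"].round(2)
    write_tsv(out, path)


def percentage(count: int, denominator: int) -> float:
    """100 * count / denominator, rounded to 2 decimals; 0.00 on empty sets."""
    if denominator == 0:
        return 0.0
    return round(100.0 * count / denominator, 2)


def summarize_translatome(
    tei_table: pd.DataFrame,
    gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-gene-set counts of transcribed/translated genes, by tissue and union.

    For each named gene set and tissue, counts (with percentages of the set
    size) of transcribed and translated genes and the overlap (translated
    among transcribed, as a percentage of the transcribed count). The union
    column counts genes meeting each criterion in at least one tissue.
    """
    tissues = sorted(tei_table["tissue"].unique())
    rows = []
    for set_name, genes in gene_sets.items():
        sub = tei_table[tei_table["gene_id"].isin(genes)]
        n_set = len(genes)
        per_tissue: dict[str, dict[str, int]] = {}
        for tissue in tissues:
            st = sub[sub["tissue"] == tissue]
            n_tx = int(st["transcribed"].sum())
            n_tl = int(st["translated"].sum())
            n_ov = int((st["transcribed"] & st["translated"]).sum())
            per_tissue[tissue] = {"transcribed": n_tx, "translated": n_tl, "overlap": n_ov}
        u_tx = sub.loc[sub["transcribed"], "gene_id"].nunique()
        u_tl = sub.loc[sub["translated"], "gene_id"].nunique()
        u_ov = sub.loc[sub["transcribed"] & sub["translated"], "gene_id"].nunique()
        per_tissue["union"] = {"transcribed": u_tx, "translated": u_tl, "overlap": u_ov}
        for col, counts in per_tissue.items():
            rows.append(
                {
                    "gene_set": set_name,
                    "n_genes": n_set,
                    "column": col,
                    "transcribed": counts["transcribed"],
                    "transcribed_pct": percentage(counts["transcribed"], n_set),
                    "translated": counts["translated"],
                    "translated_pct": percentage(counts["translated"], n_set),
                    "overlap": counts["overlap"],
                    "overlap_pct_mrna": percentage(counts["overlap"], counts["transcribed"]),
                }
            )
    return pd.DataFrame(rows)


def expression_breadth(gene_id: str, mrna_tables: list[ExpressionTable], threshold: float = FPKM_EXPRESSED) -> int:
    """Number of samples in which the gene's mRNA FPKM meets the threshold."""
    return sum(1 for t in mrna_tables if t.fpkm(gene_id) >= threshold)


def expression_breadth_table(mrna_tables: list[ExpressionTable], threshold: float = FPKM_EXPRESSED) -> pd.Series:
    """Vectorised breadth over the union of gene ids across all samples."""
    genes = sorted(set().union(*(t.values.index for t in mrna_tables)))
    counts = np.zeros(len(genes), dtype=int)
    idx = pd.Index(genes)
    for t in mrna_tables:
        counts += (t.values.reindex(idx, fill_value=0.0).to_numpy(float) >= threshold).astype(int)
    return pd.Series(counts, index=idx, name="breadth")
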
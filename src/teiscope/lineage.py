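"""Evolutionary-lineage assignment and GO-term aggregation of TEI.

Genes are assigned to nested plant lineages from the species content of
their ortholog clusters (all angiosperms > monocot+dicot > monocot-
restricted > Poaceae-restricted > species-specific), and TEI is aggregated
per lineage and per GO biological-process term, including a two-dataset
comparison of per-term means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io import write_tsv

logger = logging.getLogger("teiscope")

LINEAGES = (
    "all_angiosperms",
    "monocot_dicot",
    "monocot_restricted",
    "poaceae_restricted",
    "species_specific",
    "unassigned",
)

GO_MIN_GENES = 40


@dataclass
class SpeciesGroups:
    """Clade membership of the proteomes used for ortholog clustering."""

    focal: str
    poaceae: set[str]
    other_monocots: set[str]
    dicots: set[str]
    basal_angiosperm: str

    def all_species(self) -> set[str]:
        return self.poaceae | self.other_monocots | self.dicots | {self.basal_angiosperm, self.focal}


def assign_lineage(
    gene_to_cluster: dict[str, str],
    cluster_species: dict[str, set[str]],
    groups: SpeciesGroups,
    genes: list[str] | None = None,
    transposon_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Assign each gene a lineage from its cluster's species content.

    Rules, applied from broadest clade down: a cluster spanning at least
    one monocot, one dicot and the basal angiosperm is conserved in all
    angiosperms; monocot+dicot without the basal angiosperm is
    monocot_dicot; monocots only, with at least one non-Poaceae monocot, is
    monocot_restricted; Poaceae only is poaceae_restricted; focal species
    only (or an unclustered gene) is species_specific. Transposon-validated
    genes are never assigned a lineage.
    """
    transposon_genes = transposon_genes or set()
    known = groups.all_species()
    monocots = groups.poaceae | groups.other_monocots | {groups.focal}
    if genes is None:
        genes = sorted(gene_to_cluster)
    rows = []
    for gene in genes:
        if gene in transposon_genes:
            rows.append({"gene_id": gene, "lineage": "unassigned"})
            continue
        cluster = gene_to_cluster.get(gene)
        if cluster is None:
            rows.append({"gene_id": gene, "lineage": "species_specific"})
            continue
        species = cluster_species[cluster]
        unknown = species - known
        if unknown:
            raise ValueError(f"species {sorted(unknown)} in cluster {cluster} missing from species groups")
        has_monocot = bool(species & monocots)
        has_dicot = bool(species & groups.dicots)
        has_basal = groups.basal_angiosperm in species
        if has_monocot and has_dicot and has_basal:
            lineage = "all_angiosperms"
        elif has_monocot and has_dicot:
            lineage = "monocot_dicot"
        elif species <= monocots and species & groups.other_monocots:
            lineage = "monocot_restricted"
        elif species <= (groups.poaceae | {groups.focal}) and species - {groups.focal}:
            lineage = "poaceae_restricted"
        elif species <= {groups.focal}:
            lineage = "species_specific"
        else:  # e.g. dicots + basal without monocots: outside the nested ladder
            lineage = "unassigned"
        rows.append({"gene_id": gene, "lineage": lineage})
    return pd.DataFrame(rows)


def tei_by_lineage(
    assignments: pd.DataFrame,
    tei_table: pd.DataFrame,
    grid: np.ndarray | None = None,
    bandwidth: str | float = "scott",
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-lineage TEI summary plus Gaussian-kernel densities on a fixed grid.

    Returns a summary frame (lineage, n, mean, median, fraction with
    TEI >= 1) and a {lineage: density} dict evaluated on `grid` (default:
    256 points spanning 0 to the 99th TEI percentile). Lineages with fewer
    than 2 TEI values are omitted with a log notice.
    """
    merged = assignments.merge(tei_table.dropna(subset=["tei"]), on="gene_id")
    if grid is None:
        hi = float(np.quantile(merged["tei"], 0.99)) if len(merged) else 1.0
        grid = np.linspace(0.0, max(hi, 1.0), 256)
    rows = []
    densities: dict[str, np.ndarray] = {}
    for lineage in LINEAGES:
        tei = merged.loc[merged["lineage"] == lineage, "tei"].to_numpy(float)
        if tei.size < 2:
            if tei.size:
                logger.info("lineage %s has <2 TEI values; omitted", lineage)
            continue
        rows.append(
            {
                "lineage": lineage,
                "n": tei.size,
                "mean_tei": float(tei.mean()),
                "median_tei": float(np.median(tei)),
                "fraction_tei_ge_1": float((tei >= 1).mean()),
            }
        )
        if np.std(tei) > 0:
            densities[lineage] = gaussian_kde(tei, bw_method=bandwidth)(grid)
        else:  # degenerate sample: point mass at the single value
            d = np.zeros_like(grid)
            d[int(np.argmin(np.abs(grid - tei[0])))] = 1.0
            densities[lineage] = d
    return pd.DataFrame(rows), densities


@dataclass
class GoTermSummary:
    term_id: str
    term_name: str
    n_genes: int
    mean_tei: float
    mean_mrna_fpkm: float
    mean_trap_fpkm: float
    mean_cds_len: float = np.nan
    mean_utr5_len: float = np.nan
    mean_cds_gc: float = np.nan


def go_term_tei(
    go_table: pd.DataFrame,
    tei_table: pd.DataFrame,
    features: pd.DataFrame | None = None,
    min_genes: int = GO_MIN_GENES,
) -> pd.DataFrame:
    """Mean TEI (and companion features) per GO term with >= min_genes genes.

    Output is sorted by mean TEI descending; ties break by n_genes
    descending then term_id. Use `.head(k)` / `.tail(k)` for the top/bottom
    views.
    """
    tei = tei_table.dropna(subset=["tei"])
    merged = go_table.merge(tei, on="gene_id")
    if features is not None:
        merged = merged.merge(features, on="gene_id", how="left")
    rows = []
    for (term_id, term_name), grp in merged.groupby(["term_id", "term_name"], sort=True):
        n = grp["gene_id"].nunique()
        if n < min_genes:
            continue
        row = {
            "term_id": term_id,
            "term_name": term_name,
            "n_genes": n,
            "mean_tei": float(grp["tei"].mean()),
            "mean_mrna_fpkm": float(grp["mrna_fpkm"].mean()),
            "mean_trap_fpkm": float(grp["trap_fpkm"].mean()),
        }
        if features is not None:
            for col in ("cds_len", "utr5_len", "cds_gc"):
                if col in grp:
                    row[f"mean_{col}"] = float(grp[col].mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["mean_tei", "n_genes", "term_id"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return out


def percent_variation(mean_a: float, mean_b: float) -> float:
    """100 * |mean_a - mean_b| / min(mean_a, mean_b); NaN if min <= 0."""
    lo = min(mean_a, mean_b)
    if lo <= 0:
        return float("nan")
    return 100.0 * abs(mean_a - mean_b) / lo


def cross_dataset_compare(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    k: int = 10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Term-by-term comparison of two GO summaries (e.g. two species).

    For every shared term, the difference of mean TEIs (a minus b) and the
    %variation (difference over the lower of the two means, times 100).
    Also reports the overlap of the top-k and bottom-k term sets of the two
    summaries. Callers are responsible for restricting both gene universes
    to matched (orthologous) sets beforehand.
    """
    a = summary_a.set_index("term_id")
    b = summary_b.set_index("term_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("summaries share no GO terms")
    rows = []
    for term in shared:
        ma, mb = float(a.loc[term, "mean_tei"]), float(b.loc[term, "mean_tei"])
        rows.append(
            {
                "term_id": term,
                "term_name": a.loc[term, "term_name"],
                "mean_tei_a": ma,
                "mean_tei_b": mb,
                "difference": ma - mb,
                "pct_variation": percent_variation(ma, mb),
            }
        )
    top_a, top_b = set(a.head(k).index), set(b.head(k).index)
    bot_a, bot_b = set(a.tail(k).index), set(b.tail(k).index)
    overlaps = {
        "top_k_overlap": len(top_a & top_b),
        "bottom_k_overlap": len(bot_a & bot_b),
        "k": k,
    }
    return pd.DataFrame(rows), overlaps


def write_lineage_table(assignments: pd.DataFrame, path) -> None:
    write_tsv(assignments, path)
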
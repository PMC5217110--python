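"""Gene-feature stratification of TEI distributions.

Genes are binned by a sequence or expression property (CDS length, CDS GC,
UTR lengths, expression breadth, expression abundance), TEI is summarised
per bin, and all bin pairs are compared with two-sample KS tests under a
per-scheme Benjamini-Hochberg family.

Bin conventions: left-closed, right-open, except the terminal bin which is
unbounded above. Default CDS-length edges are 500/800/1100/1400/1700 bp and
GC edges 50/60/70%; expression-abundance bins are per-dataset sextile cuts
within FPKM >= 1 (edges are data-dependent and recorded on the result).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import gc3
from .io import extract_sequence, gc_fraction, interval_length, write_tsv
from .stats import bh_adjust, ks_two_sample, pearson_corr, quadratic_trend  # noqa: F401 - re-exported surface

logger = logging.getLogger("teiscope")

CDS_LEN_EDGES = [500.0, 800.0, 1100.0, 1400.0, 1700.0]
CDS_GC_EDGES = [0.50, 0.60, 0.70]
UTR5_LEN_EDGES = [100.0, 200.0, 400.0]
UTR3_LEN_EDGES = [200.0, 400.0, 600.0]
BREADTH_EDGES = [8.0, 15.0]  # groups: 1-7, 8-14, 15 samples
MIN_UTR5 = 20
MIN_UTR3 = 110

SCHEMES = ("cds_length", "cds_gc", "utr5_length", "utr3_length", "breadth", "abundance")

_SCHEME_COLUMNS = {
    "cds_length": "cds_len",
    "cds_gc": "cds_gc",
    "utr5_length": "utr5_len",
    "utr3_length": "utr3_len",
    "breadth": "breadth",
    "abundance": "mean_mrna_fpkm",
}


def compute_gene_features(genes, genome: dict[str, str]) -> pd.DataFrame:
    """Per-gene feature table from representative gene models.

    Columns: gene_id, chrom, midpoint, cds_len, utr5_len, utr3_len, cds_gc,
    utr5_gc, utr3_gc, gc3. Lengths and GC are computed on the spliced
    representative isoform (strand-aware extraction).
    """
    rows = []
    for g in genes:
        t = g.representative
        cds_seq = extract_sequence(genome, g.chrom, t.cds, g.strand)
        utr5_seq = extract_sequence(genome, g.chrom, t.utr5, g.strand)
        utr3_seq = extract_sequence(genome, g.chrom, t.utr3, g.strand)
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "midpoint": g.midpoint(),
                "cds_len": interval_length(t.cds),
                "utr5_len": interval_length(t.utr5),
                "utr3_len": interval_length(t.utr3),
                "cds_gc": gc_fraction(cds_seq),
                "utr5_gc": gc_fraction(utr5_seq),
                "utr3_gc": gc_fraction(utr3_seq),
                "gc3": gc3(cds_seq) if len(cds_seq) >= 3 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StratifiedComparison:
    """Result of one stratification scheme on one gene set."""

    scheme: str
    edges: list[float]
    bins: list[tuple[str, list[str]]]  # (label, gene ids), ordered
    summary: pd.DataFrame  # bin, n, mean_tei, median_tei
    tests: pd.DataFrame  # bin_a, bin_b, D, p_raw, p_bh
    notes: dict = field(default_factory=dict)


def _bin_labels(edges: list[float], unit: str = "") -> list[str]:
    labels = [f"<{edges[0]:g}{unit}"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{lo:g}-{hi:g}{unit}")
    labels.append(f">={edges[-1]:g}{unit}")
    return labels


def _assign_bins(values: np.ndarray, edges: list[float]) -> np.ndarray:
    """Left-closed right-open binning; terminal bin closed above by +inf."""
    return np.searchsorted(np.asarray(edges, dtype=float), values, side="right")


def stratify(
    table: pd.DataFrame,
    scheme: str,
    edges: list[float] | None = None,
    exact_ks: bool = False,
) -> StratifiedComparison:
    """Bin genes by `scheme` and KS-compare TEI between all bin pairs.

    `table` must hold one row per gene with a defined `tei` column plus the
    scheme's feature column (see compute_gene_features / breadth /
    mean_mrna_fpkm). Empty bins are retained with n=0 but excluded from
    testing; BH adjustment spans the scheme's family of pairwise tests.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    col = _SCHEME_COLUMNS[scheme]
    if col not in table.columns:
        raise ValueError(f"scheme {scheme!r} needs column {col!r}")
    sub = table.dropna(subset=["tei", col]).copy()
    notes: dict = {}
    if edges is None:
        if scheme == "cds_length":
            edges = list(CDS_LEN_EDGES)
        elif scheme == "cds_gc":
            edges = list(CDS_GC_EDGES)
        elif scheme == "utr5_length":
            edges = list(UTR5_LEN_EDGES)
        elif scheme == "utr3_length":
            edges = list(UTR3_LEN_EDGES)
        elif scheme == "breadth":
            edges = list(BREADTH_EDGES)
        else:  # abundance: sextiles within FPKM >= 1, recomputed per dataset
            sub = sub[sub[col] >= 1.0]
            qs = np.quantile(sub[col].to_numpy(float), np.linspace(0, 1, 7)[1:-1])
            edges = sorted(set(float(q) for q in qs))
            notes["abundance_edges"] = edges
            logger.info("abundance scheme: per-dataset edges %s", edges)
    values = sub[col].to_numpy(float)
    idx = _assign_bins(values, edges)
    labels = _bin_labels(edges)
    bins: list[tuple[str, list[str]]] = []
    samples: list[np.ndarray] = []
    summary_rows = []
    for b, label in enumerate(labels):
        mask = idx == b
        gene_ids = sub.loc[mask, "gene_id"].tolist()
        tei = sub.loc[mask, "tei"].to_numpy(float)
        bins.append((label, gene_ids))
        samples.append(tei)
        summary_rows.append(
            {
                "bin": label,
                "n": int(mask.sum()),
                "mean_tei": float(tei.mean()) if tei.size else np.nan,
                "median_tei": float(np.median(tei)) if tei.size else np.nan,
            }
        )
    test_rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if samples[i].size < 2 or samples[j].size < 2:
                continue
            d, p = ks_two_sample(samples[i], samples[j], exact=exact_ks)
            test_rows.append({"bin_a": labels[i], "bin_b": labels[j], "D": d, "p_raw": p})
    tests = pd.DataFrame(test_rows, columns=["bin_a", "bin_b", "D", "p_raw"])
    tests["p_bh"] = bh_adjust(tests["p_raw"].tolist()) if len(tests) else []
    return StratifiedComparison(
        scheme=scheme,
        edges=list(edges),
        bins=bins,
        summary=pd.DataFrame(summary_rows),
        tests=tests,
        notes=notes,
    )


def utr_effect_analysis(
    table: pd.DataFrame,
    min_utr5: int = MIN_UTR5,
    min_utr3: int = MIN_UTR3,
    cds_edges: list[float] | None = None,
    utr5_edges: list[float] | None = None,
    utr3_edges: list[float] | None = None,
) -> pd.DataFrame:
    """TEI by UTR-length bin, conditioned on CDS-length group.

    Genes with a 5'UTR shorter than `min_utr5` or a 3'UTR shorter than
    `min_utr3` are excluded (boundaries inclusive: a 20-bp 5'UTR passes).
    Within each CDS-length group, TEI is summarised across 5'UTR-length bins
    and, separately, 3'UTR-length bins. Rows carry flags marking bins that
    sit entirely below the 200-bp and 400-bp 5'UTR thresholds.
    """
    cds_edges = list(CDS_LEN_EDGES) if cds_edges is None else list(cds_edges)
    utr5_edges = list(UTR5_LEN_EDGES) if utr5_edges is None else list(utr5_edges)
    utr3_edges = list(UTR3_LEN_EDGES) if utr3_edges is None else list(utr3_edges)
    sub = table.dropna(subset=["tei"])
    sub = sub[(sub["utr5_len"] >= min_utr5) & (sub["utr3_len"] >= min_utr3)].copy()
    cds_labels = _bin_labels(cds_edges, unit="bp")
    sub["cds_group"] = [cds_labels[i] for i in _assign_bins(sub["cds_len"].to_numpy(float), cds_edges)]
    rows = []
    for utr, edges in (("utr5", utr5_edges), ("utr3", utr3_edges)):
        labels = _bin_labels(edges, unit="bp")
        col = f"{utr}_len"
        bin_idx = _assign_bins(sub[col].to_numpy(float), edges)
        sub["_utr_bin"] = bin_idx
        for cds_group, grp in sub.groupby("cds_group", sort=False):
            for b, label in enumerate(labels):
                tei = grp.loc[grp["_utr_bin"] == b, "tei"].to_numpy(float)
                upper = edges[b] if b < len(edges) else np.inf
                rows.append(
                    {
                        "utr": utr,
                        "cds_group": cds_group,
                        "utr_bin": label,
                        "n": tei.size,
                        "mean_tei": float(tei.mean()) if tei.size else np.nan,
                        "median_tei": float(np.median(tei)) if tei.size else np.nan,
                        "below_200bp_5utr": bool(utr == "utr5" and upper <= 200),
                        "below_400bp_5utr": bool(utr == "utr5" and upper <= 400),
                    }
                )
    order = {lab: i for i, lab in enumerate(cds_labels)}
    out = pd.DataFrame(rows)
    return out.sort_values(["utr", "cds_group", "utr_bin"], key=lambda s: s.map(order).fillna(s)).reset_index(
        drop=True
    )


def trim_top_percent(values: np.ndarray, percent: float = 1.0) -> np.ndarray:
    """Drop the top `percent`% of values. Reporting/plotting only: the
    statistical tests always run on untrimmed samples."""
    values = np.sort(np.asarray(values, dtype=float))
    keep = int(np.ceil(len(values) * (1 - percent / 100.0)))
    return values[:keep]


def write_stratified(result: StratifiedComparison, summary_path, tests_path) -> None:
    write_tsv(result.summary, summary_path)
    write_tsv(result.tests, tests_path)
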
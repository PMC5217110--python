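"""End-to-end pipeline: simulate -> TEI -> filters -> stratified analyses.

run_all executes every stage on one dataset (synthetic by default, or
files named in the config), writes each stage's tables under the output
directory, and records a manifest with the seed, thresholds and per-stage
row counts. Rerunning with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codons import codon_frequency, compare_synonymous_usage, select_tei_extremes, write_usage_table
from .expression import build_tei_table, summarize_translatome, write_tei_table
from .io import extract_sequence, write_tsv
from .isoforms import compare_si_ri, find_si_ri_pairs, pairs_to_frame
from .lineage import assign_lineage, go_term_tei, tei_by_lineage, write_lineage_table
from .recomb import bin_recombination, correlate_bins_with_genes, write_bins
from .repeats import mask_coverage
from .sim import SimParams, generate_dataset, write_dataset
from .stratify import SCHEMES, compute_gene_features, stratify, utr_effect_analysis, write_stratified

logger = logging.getLogger("teiscope")


@dataclass
class PipelineConfig:
    """Thresholds and paths for one reproducible run.

    Every quoted threshold of the analysis lives here so the manifest can
    list them all: FPKM expression call (1), transposon mask fraction
    (0.5), TEI extreme cutoffs (0.2 / 3.0), UTR minima (20 / 110 bp) and
    the GO minimum gene count (40).
    """

    outdir: str = "teiscope_out"
    seed: int = 1
    fpkm_expressed: float = 1.0
    mask_fraction: float = 0.5
    tei_low: float = 0.2
    tei_high: float = 3.0
    min_utr5: int = 20
    min_utr3: int = 110
    go_min_genes: int = 40
    min_match: int = 50
    schemes: tuple[str, ...] = ("cds_length", "cds_gc", "utr5_length", "utr3_length", "abundance")
    sim: SimParams = field(default_factory=SimParams)
    reference_tissue: str = "shoot"

    def __post_init__(self) -> None:
        for name in ("fpkm_expressed", "mask_fraction", "tei_low", "tei_high", "min_utr5", "min_utr3", "go_min_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages on a synthetic dataset; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fpkm_expressed": config.fpkm_expressed,
            "mask_fraction": config.mask_fraction,
            "tei_low": config.tei_low,
            "tei_high": config.tei_high,
            "min_utr5": config.min_utr5,
            "min_utr3": config.min_utr3,
            "go_min_genes": config.go_min_genes,
            "min_match": config.min_match,
        },
        "stages": {},
    }

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = result
        logger.info("stage %s done: %s", name, result)

    params = dataclasses.replace(config.sim, seed=config.seed)
    state: dict = {}

    def do_simulate():
        ds = generate_dataset(params)
        write_dataset(ds, out / "simulated")
        state["ds"] = ds
        return {"n_genes": len(ds.genes), "tissues": list(params.tissues)}

    def do_tei():
        ds = state["ds"]
        mrna = [m for m, _ in ds.expression.values()]
        trap = [t for _, t in ds.expression.values()]
        tei = build_tei_table(mrna, trap)
        write_tei_table(tei, out / "tei.tsv")
        state["tei"] = tei
        summary = summarize_translatome(tei, {"all": set(ds.meta["gene_id"])})
        write_tsv(summary, out / "translatome_summary.tsv")
        return {"rows": len(tei)}

    def do_filter_te():
        ds = state["ds"]
        rows = []
        for gid, seq in ds.transposon_cdnas.items():
            r = mask_coverage(gid, seq, ds.repeat_library, min_match=config.min_match)
            rows.append(
                {
                    "gene_id": gid,
                    "cdna_len": r.cdna_length,
                    "masked_fraction": r.masked_fraction,
                    "validated": r.is_transposon_validated,
                }
            )
        df = pd.DataFrame(rows)
        write_tsv(df, out / "transposon_filter.tsv")
        state["te"] = df
        return {"n_cdnas": len(df), "n_validated": int(df["validated"].sum())}

    def do_stratify():
        ds = state["ds"]
        features = compute_gene_features(ds.genes, ds.genome)
        state["features"] = features
        tei = state["tei"]
        mean_abund = tei.groupby("gene_id")["mrna_fpkm"].mean().rename("mean_mrna_fpkm")
        ref = (
            tei[tei["tissue"] == config.reference_tissue]
            .merge(features, on="gene_id")
            .merge(mean_abund, on="gene_id")
        )
        state["ref"] = ref
        counts = {}
        for scheme in config.schemes:
            if scheme not in SCHEMES:
                continue
            res = stratify(ref, scheme)
            write_stratified(res, out / f"strat_{scheme}_summary.tsv", out / f"strat_{scheme}_tests.tsv")
            counts[scheme] = int(res.summary["n"].sum())
        utr = utr_effect_analysis(ref, min_utr5=config.min_utr5, min_utr3=config.min_utr3)
        write_tsv(utr, out / "utr_effects.tsv")
        return counts

    def do_isoforms():
        ds = state["ds"]
        pairs = find_si_ri_pairs(ds.genes, ds.genome)
        write_tsv(pairs_to_frame(pairs), out / "si_ri_pairs.tsv")
        mrna = [m for m, _ in ds.isoform_expression.values()]
        trap = [t for _, t in ds.isoform_expression.values()]
        iso_tei = build_tei_table(mrna, trap)
        summary = compare_si_ri(pairs, iso_tei[iso_tei["tissue"] == config.reference_tissue])
        write_tsv(summary, out / "si_ri_summary.tsv")
        return {"n_pairs": len(pairs)}

    def do_codons():
        ds = state["ds"]
        ref = state["ref"]
        tei = ref.set_index("gene_id")["tei"]
        low, high = select_tei_extremes(tei, config.tei_low, config.tei_high)
        seqs = {
            g.gene_id: extract_sequence(ds.genome, g.chrom, g.representative.cds, g.strand)
            for g in ds.genes
        }
        low_table = codon_frequency({g: seqs[g] for g in low if g in seqs}, "low_tei")
        high_table = codon_frequency({g: seqs[g] for g in high if g in seqs}, "high_tei")
        write_usage_table(low_table, out / "codon_usage_low.tsv")
        write_usage_table(high_table, out / "codon_usage_high.tsv")
        fam, pairs = compare_synonymous_usage(low_table, high_table)
        write_tsv(fam, out / "codon_families.tsv")
        write_tsv(pairs, out / "codon_pairs.tsv")
        return {"n_low": len(low), "n_high": len(high)}

    def do_lineage_go():
        ds = state["ds"]
        assignments = assign_lineage(ds.gene_to_cluster, ds.cluster_species, ds.species_groups,
                                     genes=list(ds.meta["gene_id"]))
        write_lineage_table(assignments, out / "lineages.tsv")
        ref = state["ref"]
        lineage_summary, _ = tei_by_lineage(assignments, ref)
        write_tsv(lineage_summary, out / "lineage_tei.tsv")
        go = go_term_tei(ds.go_table, ref, state["features"], min_genes=config.go_min_genes)
        write_tsv(go, out / "go_tei.tsv")
        return {"n_assigned": len(assignments), "n_go_terms": len(go)}

    def do_recomb():
        ds = state["ds"]
        bins = bin_recombination(ds.markers)
        write_bins(bins, out / "recomb_bins.tsv")
        ref = state["ref"]
        corr = correlate_bins_with_genes(bins, ref[["chrom", "midpoint", "cds_gc", "tei"]])
        report = pd.DataFrame(
            [{"comparison": k, "r": r, "p": p} for k, (r, p) in corr.items()]
        )
        write_tsv(report, out / "recomb_correlations.tsv")
        return {"n_bins": len(bins)}

    stage("simulate", do_simulate)
    stage("tei", do_tei)
    stage("filter_te", do_filter_te)
    stage("stratify", do_stratify)
    stage("isoforms", do_isoforms)
    stage("codons", do_codons)
    stage("lineage_go", do_lineage_go)
    stage("recomb", do_recomb)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
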
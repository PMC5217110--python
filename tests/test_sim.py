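"""Synthetic-data generator: determinism, construction constraints, and
distributional/parameter-recovery properties."""

import filecmp

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from teiscope.io import interval_length, merge_intervals
from teiscope.sim import (
    SimParams,
    generate_dataset,
    generate_gene_models,
    sample_feature_table,
    simulate_expression,
    write_dataset,
)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(n_genes=0)
        with pytest.raises(ValueError):
            SimParams(gc_mix=(0.4, 0.6, 1.5))
        with pytest.raises(ValueError):
            SimParams(noise_sd=-1)


class TestGeneModels:
    def test_single_gene_construction_constraints(self):
        genes, genome, meta = generate_gene_models(SimParams(n_genes=1, seed=2))
        assert len(genes) == 1
        t = genes[0].representative
        assert interval_length(t.cds) % 3 == 0
        assert interval_length(t.utr5) >= 1 and interval_length(t.utr3) >= 1

    def test_gene_count_conserved(self):
        n = 57
        genes, _, meta = generate_gene_models(SimParams(n_genes=n, seed=3))
        assert len(genes) == n and len(meta) == n

    def test_byte_identical_outputs_same_seed(self, tmp_path):
        params = SimParams(n_genes=40, seed=17)
        for d in ("a", "b"):
            write_dataset(generate_dataset(params), tmp_path / d)
        for name in ("annotation.gff3", "genome.fa", "mrna_shoot.tsv", "trap_callus.tsv",
                     "truth_tei.tsv", "te_cdnas.fa", "markers.tsv", "go.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_different_seeds_differ(self):
        a = generate_gene_models(SimParams(n_genes=10, seed=1))[2]
        b = generate_gene_models(SimParams(n_genes=10, seed=2))[2]
        assert not a["cds_len"].equals(b["cds_len"])

    def test_ri_isoform_shares_si_coordinates_except_intron(self, dataset):
        for g in dataset.genes:
            if len(g.transcripts) < 2:
                continue
            si, ri = g.transcripts
            introns = si.introns()
            assert len(introns) == 1
            assert merge_intervals(si.exons + introns) == merge_intervals(ri.exons)

    def test_degenerate_mixture_unimodal_moments(self):
        """With both GC modes at 0.5 the realised CDS GC matches a direct
        draw from the same one-mode mixture in mean and spread."""
        params = SimParams(n_genes=2000, gc_mix=(0.5, 0.5, 0.5), seed=19)
        meta = sample_feature_table(params, 2000, np.random.default_rng(19))
        rng = np.random.default_rng(20)
        brute = np.clip(rng.normal(0.5, params.gc_sd, 20000), 0.33, 0.86)
        assert meta["cds_gc"].mean() == pytest.approx(brute.mean(), abs=0.01)
        assert meta["cds_gc"].std() == pytest.approx(brute.std(), abs=0.01)

    def test_median_cds_length_matches_configuration(self):
        """At n=5000 the empirical median CDS length sits within 10% of the
        configured 1095 bp median (binomial concentration of the median)."""
        params = SimParams(seed=23)
        meta = sample_feature_table(params, 5000, np.random.default_rng(23))
        med = meta["cds_len"].median()
        assert 0.9 * 1095 <= med <= 1.1 * 1095

    def test_realised_gc3_exceeds_overall_gc(self, dataset):
        """Third-position GC placement: GC3 deviates from 0.5 about twice as
        far as overall GC does, per the configured 2:1 ratio."""
        from teiscope.stratify import compute_gene_features

        feats = compute_gene_features(dataset.genes[:200], dataset.genome)
        high = feats[feats["cds_gc"] > 0.60]
        assert (high["gc3"] > high["cds_gc"]).mean() > 0.9


class TestExpression:
    def test_log2_tei_linear_in_gc_without_noise(self):
        params = SimParams(
            n_genes=500, tei_coefs=(0.0, 2.0, 0.0, 0.0, 0.0), noise_sd=0.0,
            zero_inflation=0.0, tissues=("shoot",), seed=29,
        )
        meta = sample_feature_table(params, 500, np.random.default_rng(29))
        tables, truth = simulate_expression(meta, params, np.random.default_rng(30))
        t = truth.merge(meta, on="gene_id")
        tei = t["trap_fpkm"] / t["mrna_fpkm"]
        r = np.corrcoef(t["cds_gc"], np.log2(tei))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)
        # TEI itself is a monotone transform of GC (ties at the clip bounds)
        srt = t.sort_values("cds_gc")
        assert (np.diff(srt["trap_fpkm"] / srt["mrna_fpkm"]) >= -1e-9).all()

    def test_ols_recovers_gc_slope(self):
        params = SimParams(
            n_genes=2000, tei_coefs=(0.0, 2.0, 0.0, 0.0, 0.0), noise_sd=0.5,
            zero_inflation=0.0, tissues=("shoot",), seed=31,
        )
        meta = sample_feature_table(params, 2000, np.random.default_rng(31))
        _, truth = simulate_expression(meta, params, np.random.default_rng(32))
        t = truth.merge(meta, on="gene_id")
        y = np.log2(t["trap_fpkm"] / t["mrna_fpkm"])
        fit = sm.OLS(y, sm.add_constant(t["cds_gc"])).fit()
        assert abs(fit.params.iloc[1] - 2.0) < 0.2

    def test_all_coefficients_recovered_within_3_se(self):
        """Full design: every generative coefficient recovered by OLS within
        3 standard errors at n=2000, noise 0.5."""
        coefs = (0.0, 2.0, -0.3, -0.2, -1.0)
        params = SimParams(tei_coefs=coefs, noise_sd=0.5, ri_fraction=0.3, tissues=("shoot",), seed=37)
        meta = sample_feature_table(params, 2000, np.random.default_rng(37))
        meta.loc[: len(meta) // 3, "ri_region"] = "5UTR"
        _, truth = simulate_expression(meta, params, np.random.default_rng(38))
        t = truth.merge(meta, on="gene_id")
        t = t[t["mrna_fpkm"] >= 1]
        y = np.log2(t["trap_fpkm"] / t["mrna_fpkm"])
        X = sm.add_constant(
            np.column_stack(
                [t["cds_gc"], np.log2(t["cds_len"]), np.log2(t["utr5_len"].clip(lower=1)),
                 (t["ri_region"] == "5UTR").astype(float)]
            )
        )
        fit = sm.OLS(y, X).fit()
        for est, se, true in zip(fit.params, fit.bse, coefs):
            assert abs(est - true) < 3 * se

    def test_zero_inflated_genes_fall_below_threshold(self):
        params = SimParams(n_genes=1000, zero_inflation=0.3, tissues=("shoot",), seed=41)
        meta = sample_feature_table(params, 1000, np.random.default_rng(41))
        tables, _ = simulate_expression(meta, params, np.random.default_rng(42))
        frac_low = (tables["shoot"][0].values < 1.0).mean()
        assert 0.25 <= frac_low <= 0.40


class TestFixtures:
    def test_expression_gene_ids_exist_in_annotation(self, dataset):
        gene_ids = {g.gene_id for g in dataset.genes}
        for m, t in dataset.expression.values():
            assert set(m.values.index) <= gene_ids
            assert set(t.values.index) <= gene_ids

    def test_true_tei_positive_for_transcribed_genes(self, dataset):
        truth = dataset.truth
        pos = truth[truth["mrna_fpkm"] > 0]
        assert (np.exp2(pos["log2_tei_true"]) > 0).all()
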
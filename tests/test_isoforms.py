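"""SI/RI isoform pairing, region classification, and expression contrasts."""

import numpy as np
import pandas as pd
import pytest

from teiscope.expression import MRNA, TRAP, build_tei_table
from teiscope.io import GeneModel, Transcript
from teiscope.isoforms import (
    classify_ri_region,
    compare_si_ri,
    find_si_ri_pairs,
    go_category_enrichment,
)
from teiscope.sim import SimParams, sample_feature_table, simulate_isoform_expression

from conftest import make_ri_gene, make_single_exon_gene


class TestPairing:
    @pytest.mark.parametrize("region", ["5UTR", "CDS", "3UTR"])
    def test_single_ri_gene_pairs_with_correct_region(self, region):
        pairs = find_si_ri_pairs([make_ri_gene(region=region)])
        assert len(pairs) == 1
        p = pairs[0]
        assert p.region == region
        assert p.si_isoform_id.endswith(".1") and p.ri_isoform_id.endswith(".2")
        assert p.intron_len == 100

    def test_identical_isoforms_not_paired(self):
        g = make_single_exon_gene()
        twin = Transcript("G1.2", exons=list(g.transcripts[0].exons), utr5=list(g.transcripts[0].utr5),
                          cds=list(g.transcripts[0].cds), utr3=list(g.transcripts[0].utr3))
        g.transcripts.append(twin)
        assert find_si_ri_pairs([g]) == []

    def test_two_retained_introns_excluded(self):
        # SI has two introns; the other isoform retains both -> not a pair
        si = Transcript("G1.1", exons=[(0, 100), (150, 300), (350, 500)],
                        utr5=[(0, 60)], cds=[(60, 100), (150, 300), (350, 450)], utr3=[(450, 500)])
        ri = Transcript("G1.2", exons=[(0, 500)],
                        utr5=[(0, 60)], cds=[(60, 450)], utr3=[(450, 500)])
        g = GeneModel("G1", "chr1", "+", [si, ri])
        assert find_si_ri_pairs([g]) == []

    def test_pairing_symmetric_in_input_order(self):
        g = make_ri_gene(region="CDS")
        swapped = GeneModel(g.gene_id, g.chrom, g.strand, list(reversed(g.transcripts)))
        p1 = find_si_ri_pairs([g])[0]
        p2 = find_si_ri_pairs([swapped])[0]
        assert (p1.si_isoform_id, p1.ri_isoform_id) == (p2.si_isoform_id, p2.ri_isoform_id)
        assert p1.retained_intron == p2.retained_intron

    def test_simulated_genes_pair_with_generator_truth(self, dataset):
        pairs = find_si_ri_pairs(dataset.genes, dataset.genome)
        truth = dataset.meta.dropna(subset=["ri_region"]).set_index("gene_id")
        assert len(pairs) == len(truth)
        for p in pairs:
            assert p.region == truth.loc[p.gene_id, "ri_region"]
            assert p.intron_len == truth.loc[p.gene_id, "intron_len"]


class TestRegionClassification:
    def _si(self):
        # + strand: 5'UTR [0,100), CDS [200,500), 3'UTR [500,600); intron gap [100,200)
        return Transcript("t1", exons=[(0, 100), (200, 600)],
                          utr5=[(0, 100)], cds=[(200, 500)], utr3=[(500, 600)])

    def test_wholly_inside_regions(self):
        si = self._si()
        assert classify_ri_region((100, 200), si, "+") == "5UTR"
        assert classify_ri_region((300, 360), si, "+") == "CDS"
        assert classify_ri_region((520, 580), si, "+") == "3UTR"

    def test_majority_overlap_wins(self):
        # intron [140, 240): 60 bp in the 5'UTR side, 40 bp in CDS
        si = self._si()
        assert classify_ri_region((140, 240), si, "+") == "5UTR"

    def test_tie_breaks_toward_cds(self):
        si = self._si()
        assert classify_ri_region((150, 250), si, "+") == "CDS"

    def test_strand_flips_utr_sides(self):
        # same genomic layout on the minus strand: upstream-in-genome is 3'UTR
        si = self._si()
        assert classify_ri_region((100, 200), si, "-") == "3UTR"

    def test_overlap_fractions_sum_to_one(self):
        from teiscope.isoforms import _region_spans

        si = self._si()
        for intron in [(100, 200), (140, 240), (90, 590)]:
            spans = _region_spans(si, "+")
            total = sum(max(0, min(intron[1], e) - max(intron[0], s)) for s, e in spans.values())
            assert total == intron[1] - intron[0]


class TestCompareSiRi:
    def _pairs_and_tei(self, beta_ri, n=200, noise=0.5, seed=31):
        params = SimParams(
            tei_coefs=(1.0, 0.0, 0.0, 0.0, beta_ri),
            noise_sd=noise,
            tissues=("shoot",),
            seed=seed,
        )
        meta = sample_feature_table(params, n, np.random.default_rng(seed), ri_region="5UTR")
        tables = simulate_isoform_expression(meta, params, np.random.default_rng(seed + 1))
        tei = build_tei_table([tables["shoot"][0]], [tables["shoot"][1]])
        pairs = find_si_ri_pairs([make_ri_gene(region="5UTR", gene_id=g, start=0) for g in meta["gene_id"]])
        return pairs, tei

    def test_negative_ri_effect_detected(self):
        pairs, tei = self._pairs_and_tei(beta_ri=-2.0)
        out = compare_si_ri(pairs, tei)
        row = out[out["region"] == "5UTR"].iloc[0]
        assert row["ri_median_tei"] < row["si_median_tei"]
        assert row["ks_p_bh_tei"] < 0.01

    def test_identical_expression_gives_p_one(self):
        pairs, _ = self._pairs_and_tei(beta_ri=0.0)
        ids = [p.si_isoform_id for p in pairs] + [p.ri_isoform_id for p in pairs]
        tei = pd.DataFrame(
            {"gene_id": ids, "tissue": "shoot", "mrna_fpkm": 10.0, "trap_fpkm": 10.0,
             "tei": 1.0, "transcribed": True, "translated": True}
        )
        out = compare_si_ri(pairs, tei)
        row = out[out["region"] == "5UTR"].iloc[0]
        assert row["ks_p_tei"] == pytest.approx(1.0)
        assert row["si_median_tei"] == row["ri_median_tei"] == 1.0

    def test_intron_length_summary(self):
        pairs, tei = self._pairs_and_tei(beta_ri=0.0)
        out = compare_si_ri(pairs, tei)
        assert out[out["region"] == "5UTR"].iloc[0]["median_intron_len"] == 100

    def test_gene_level_table_rejected(self):
        pairs, _ = self._pairs_and_tei(beta_ri=0.0)
        gene_level = pd.DataFrame(
            {"gene_id": [p.gene_id for p in pairs], "tissue": "shoot",
             "mrna_fpkm": 1.0, "trap_fpkm": 1.0, "tei": 1.0,
             "transcribed": True, "translated": True}
        )
        with pytest.raises(ValueError, match="isoform"):
            compare_si_ri(pairs, gene_level)

    def test_ri_effect_sign_recovered_across_replicates(self):
        """With |beta_ri| = 1 at 200 pairs, the sign of the RI-in-5'UTR TEI
        effect is recovered in >= 95% of 100 replicates."""
        correct = 0
        for rep in range(100):
            pairs, tei = self._pairs_and_tei(beta_ri=-1.0, n=200, seed=1000 + rep)
            out = compare_si_ri(pairs, tei)
            row = out[out["region"] == "5UTR"].iloc[0]
            correct += row["ri_median_tei"] < row["si_median_tei"]
        assert correct >= 95


class TestGoEnrichment:
    def _go_table(self, rng, genes, n_terms=10):
        rows = []
        for g in genes:
            for t in rng.choice(n_terms, size=2, replace=False):
                rows.append({"gene_id": g, "term_id": f"T{t}", "term_name": f"proc {t}"})
        return pd.DataFrame(rows)

    def test_term_fully_in_pairs_is_most_enriched(self, rng):
        genes = [f"g{i}" for i in range(300)]
        go = self._go_table(rng, genes)
        target = set(go.loc[go["term_id"] == "T3", "gene_id"])
        out = go_category_enrichment(target, set(genes), go)
        assert out.iloc[0]["term_id"] == "T3"

    def test_uniform_pair_draw_rarely_significant(self):
        """A pair set drawn uniformly from the background should show no
        BH-significant term in nearly all replicates."""
        clean = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            genes = [f"g{i}" for i in range(400)]
            go = self._go_table(rng, genes)
            pair = set(rng.choice(genes, size=80, replace=False))
            out = go_category_enrichment(pair, set(genes), go)
            clean += (out["p_bh"] >= 0.05).all()
        # BH at 0.05 admits ~5% null rejections; >=4 of 20 would be p < 0.02
        assert clean >= n_rep - 3

    def test_chi2_equals_direct_formula(self):
        genes = [f"g{i}" for i in range(500)]
        go = pd.DataFrame(
            {"gene_id": genes[:100], "term_id": "T0", "term_name": "proc"}
        )
        pair = set(genes[:10]) | set(genes[100:190])  # 10 in-term of 100 pair genes
        out = go_category_enrichment(pair, set(genes), go)
        table = np.array([[10.0, 90.0], [90.0, 310.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert out.iloc[0]["chi2"] == pytest.approx(((table - expected) ** 2 / expected).sum())
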
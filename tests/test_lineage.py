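"""Lineage assignment rules and GO-term TEI aggregation."""

import numpy as np
import pandas as pd
import pytest

from teiscope.lineage import (
    SpeciesGroups,
    assign_lineage,
    cross_dataset_compare,
    go_term_tei,
    percent_variation,
    tei_by_lineage,
)
from teiscope.sim import DEFAULT_SPECIES_GROUPS


GROUPS = SpeciesGroups(
    focal="rice",
    poaceae={"sorghum", "brachypodium"},
    other_monocots={"banana"},
    dicots={"arabidopsis", "tomato"},
    basal_angiosperm="amborella",
)


def _assign(species_sets):
    gene_to_cluster = {f"g{i}": f"c{i}" for i in range(len(species_sets))}
    cluster_species = {f"c{i}": s for i, s in enumerate(species_sets)}
    out = assign_lineage(gene_to_cluster, cluster_species, GROUPS)
    return list(out["lineage"])


class TestAssignment:
    def test_focal_only_is_species_specific(self):
        assert _assign([{"rice"}]) == ["species_specific"]

    def test_unclustered_gene_is_species_specific(self):
        out = assign_lineage({}, {}, GROUPS, genes=["lonely"])
        assert list(out["lineage"]) == ["species_specific"]

    def test_poaceae_only(self):
        assert _assign([{"rice", "sorghum", "brachypodium"}]) == ["poaceae_restricted"]

    def test_monocot_restricted_needs_non_poaceae_monocot(self):
        assert _assign([{"rice", "sorghum", "banana"}]) == ["monocot_restricted"]

    def test_monocot_dicot_without_basal(self):
        assert _assign([{"rice", "arabidopsis"}]) == ["monocot_dicot"]

    def test_all_angiosperms_requires_basal_plus_both_clades(self):
        full = {"rice", "sorghum", "brachypodium", "banana", "arabidopsis", "tomato", "amborella"}
        assert _assign([full]) == ["all_angiosperms"]
        assert _assign([{"rice", "arabidopsis", "amborella"}]) == ["all_angiosperms"]

    def test_transposon_genes_unassigned(self):
        out = assign_lineage({"te1": "c0"}, {"c0": {"rice"}}, GROUPS, transposon_genes={"te1"})
        assert list(out["lineage"]) == ["unassigned"]

    def test_unknown_species_is_config_error(self):
        with pytest.raises(ValueError, match="missing from species groups"):
            _assign([{"rice", "alien_plant"}])

    def test_classes_mutually_exclusive_and_exhaustive(self, dataset):
        """On the simulated cluster fixtures, every clustered nontransposon
        gene gets exactly one lineage, and it matches the generator truth."""
        out = assign_lineage(
            dataset.gene_to_cluster, dataset.cluster_species, DEFAULT_SPECIES_GROUPS,
            genes=list(dataset.meta["gene_id"]),
        )
        assert len(out) == len(dataset.meta)
        merged = out.merge(dataset.lineage_truth, on="gene_id", suffixes=("", "_true"))
        assert (merged["lineage"] == merged["lineage_true"]).all()


class TestTeiByLineage:
    def _tei(self, values):
        return pd.DataFrame(
            {"gene_id": list(values), "tissue": "shoot",
             "mrna_fpkm": 10.0, "trap_fpkm": 10.0, "tei": list(values.values()),
             "transcribed": True, "translated": True}
        )

    def test_degenerate_lineage_point_mass(self):
        assigns = pd.DataFrame({"gene_id": ["a", "b"], "lineage": "poaceae_restricted"})
        summary, dens = tei_by_lineage(assigns, self._tei({"a": 1.0, "b": 1.0}))
        row = summary.iloc[0]
        assert row["fraction_tei_ge_1"] == 1.0
        grid_peak = np.argmax(dens["poaceae_restricted"])
        assert abs(np.linspace(0, 1.0, 256)[grid_peak] - 1.0) < 0.05

    def test_shifted_distributions_order_modes(self, rng):
        n = 300
        assigns = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(2 * n)],
             "lineage": ["all_angiosperms"] * n + ["species_specific"] * n}
        )
        tei_vals = np.concatenate([rng.normal(0.8, 0.1, n), rng.normal(2.0, 0.1, n)]).clip(0.01)
        tei = self._tei(dict(zip(assigns["gene_id"], tei_vals)))
        grid = np.linspace(0, 3, 300)
        summary, dens = tei_by_lineage(assigns, tei, grid=grid)
        mode_a = grid[np.argmax(dens["all_angiosperms"])]
        mode_s = grid[np.argmax(dens["species_specific"])]
        assert mode_a < mode_s

    def test_single_gene_lineage_omitted(self):
        assigns = pd.DataFrame({"gene_id": ["a", "b", "c"], "lineage": ["monocot_dicot", "monocot_dicot", "species_specific"]})
        summary, _ = tei_by_lineage(assigns, self._tei({"a": 1.0, "b": 2.0, "c": 1.5}))
        assert list(summary["lineage"]) == ["monocot_dicot"]


def _go(genes_per_term):
    rows = []
    for term, genes in genes_per_term.items():
        for g in genes:
            rows.append({"gene_id": g, "term_id": term, "term_name": f"n{term}"})
    return pd.DataFrame(rows)


def _tei_frame(tei_by_gene):
    return pd.DataFrame(
        {"gene_id": list(tei_by_gene), "tissue": "shoot", "mrna_fpkm": 10.0,
         "trap_fpkm": 10.0, "tei": list(tei_by_gene.values()),
         "transcribed": True, "translated": True}
    )


class TestGoTermTei:
    def test_minimum_gene_rule(self):
        go = _go({"T39": [f"a{i}" for i in range(39)], "T40": [f"b{i}" for i in range(40)]})
        tei = _tei_frame({g: 1.0 for g in go["gene_id"]})
        out = go_term_tei(go, tei, min_genes=40)
        assert list(out["term_id"]) == ["T40"]

    def test_term_mean(self):
        go = _go({"T": [f"g{i}" for i in range(50)]})
        tei = _tei_frame({g: 2.0 for g in go["gene_id"]})
        out = go_term_tei(go, tei, min_genes=40)
        assert out.iloc[0]["mean_tei"] == pytest.approx(2.0)

    def test_means_match_brute_force(self, rng):
        genes = [f"g{i}" for i in range(100)]
        go = _go({"A": genes[:60], "B": genes[40:]})
        tei_vals = {g: float(rng.uniform(0.1, 4)) for g in genes}
        out = go_term_tei(go, _tei_frame(tei_vals), min_genes=40).set_index("term_id")
        assert out.loc["A", "mean_tei"] == pytest.approx(np.mean([tei_vals[g] for g in genes[:60]]))
        assert out.loc["B", "mean_tei"] == pytest.approx(np.mean([tei_vals[g] for g in genes[40:]]))

    def test_raising_min_genes_never_adds_terms(self, rng):
        genes = [f"g{i}" for i in range(200)]
        go = _go({f"T{k}": list(rng.choice(genes, size=int(rng.integers(20, 120)), replace=False)) for k in range(6)})
        tei = _tei_frame({g: float(rng.uniform(0.1, 3)) for g in genes})
        prev = None
        for mg in (20, 40, 60, 80):
            terms = set(go_term_tei(go, tei, min_genes=mg)["term_id"])
            if prev is not None:
                assert terms <= prev
            prev = terms

    def test_high_gc_term_ranks_high_under_positive_gc_effect(self, dataset, tei_table):
        """The synthetic GO term enriched for high-GC genes lands in the top
        decile of per-term mean TEI when the GC coefficient is positive."""
        shoot = tei_table[tei_table["tissue"] == "shoot"]
        out = go_term_tei(dataset.go_table, shoot, min_genes=40)
        ranks = {t: i for i, t in enumerate(out["term_id"])}
        assert "GO:HIGHGC" in ranks
        assert ranks["GO:HIGHGC"] <= max(1, len(out) // 10)


class TestCrossDataset:
    def _summary(self, means):
        return pd.DataFrame(
            [{"term_id": t, "term_name": f"n{t}", "n_genes": 50, "mean_tei": m,
              "mean_mrna_fpkm": 1.0, "mean_trap_fpkm": 1.0} for t, m in means.items()]
        )

    def test_percent_variation_formula(self):
        assert percent_variation(2.0, 1.0) == pytest.approx(100.0)
        assert percent_variation(1.37, 0.82) == pytest.approx(100 * 0.55 / 0.82, abs=0.1)
        assert np.isnan(percent_variation(1.0, 0.0))

    def test_difference_of_reported_means(self):
        df, _ = cross_dataset_compare(self._summary({"T": 0.82}), self._summary({"T": 1.37}))
        assert df.iloc[0]["difference"] == pytest.approx(-0.55)

    def test_identical_summaries_full_overlap(self):
        s = self._summary({f"T{i}": 2.0 - i * 0.1 for i in range(12)})
        df, overlaps = cross_dataset_compare(s, s.copy())
        assert (df["difference"] == 0).all()
        assert overlaps["top_k_overlap"] == 10
        assert overlaps["bottom_k_overlap"] == 10

    def test_disjoint_terms_rejected(self):
        with pytest.raises(ValueError):
            cross_dataset_compare(self._summary({"A": 1.0}), self._summary({"B": 1.0}))
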
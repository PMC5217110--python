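"""Shared fixtures: synthetic datasets and small hand-built gene models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from teiscope.io import GeneModel, Transcript
from teiscope.sim import SimParams, generate_dataset


@pytest.fixture(scope="session")
def study_params() -> SimParams:
    """The default study conditions: n=2000 genes, 3 tissues, seed 1."""
    return SimParams(seed=1)


@pytest.fixture(scope="session")
def dataset(study_params):
    """One full synthetic dataset shared by read-only tests."""
    return generate_dataset(study_params)


@pytest.fixture(scope="session")
def tei_table(dataset):
    from teiscope.expression import build_tei_table

    mrna = [m for m, _ in dataset.expression.values()]
    trap = [t for _, t in dataset.expression.values()]
    return build_tei_table(mrna, trap)


@pytest.fixture(scope="session")
def shoot_table(dataset, tei_table):
    """Shoot-tissue TEI joined to realised gene features (ground truth meta)."""
    meta = dataset.meta.rename(columns={})
    sub = tei_table[tei_table["tissue"] == "shoot"]
    return sub.merge(meta, on="gene_id")


def make_single_exon_gene(gene_id="G1", chrom="chr1", strand="+", start=100):
    """5'UTR 50 bp, CDS 300 bp, 3'UTR 150 bp, one exon."""
    u5 = (start, start + 50)
    cds = (start + 50, start + 350)
    u3 = (start + 350, start + 500)
    t = Transcript(f"{gene_id}.1", exons=[(start, start + 500)], utr5=[u5], cds=[cds], utr3=[u3])
    return GeneModel(gene_id, chrom, strand, [t])


def make_ri_gene(region="CDS", gene_id="G1", chrom="chr1", strand="+", start=0, intron_len=100):
    """A gene whose second isoform retains one intron in `region`.

    Layout (+ strand): 5'UTR 60 bp, CDS 300 bp, 3'UTR 120 bp, with the
    intron inserted at the middle of the chosen region.
    """
    u5_len, cds_len, u3_len = 60, 300, 120
    cuts = {"5UTR": u5_len // 2, "CDS": u5_len + cds_len // 2, "3UTR": u5_len + cds_len + u3_len // 2}
    cut = start + cuts[region]
    i_s, i_e = cut, cut + intron_len
    total_end = start + u5_len + cds_len + u3_len + intron_len

    b_u5 = (start, start + u5_len)
    b_cds = (start + u5_len, start + u5_len + cds_len)
    b_u3 = (start + u5_len + cds_len, start + u5_len + cds_len + u3_len)

    def g_iv(iv):
        s, e = iv
        if e <= cut:
            return [(s, e)]
        if s >= cut:
            return [(s + intron_len, e + intron_len)]
        return [(s, i_s), (i_e, e + intron_len)]

    si = Transcript(
        f"{gene_id}.1",
        exons=[(start, i_s), (i_e, total_end)],
        utr5=g_iv(b_u5),
        cds=g_iv(b_cds),
        utr3=g_iv(b_u3),
    )

    def r_iv(iv, host):
        pieces = g_iv(iv)
        if host == region and len(pieces) == 2:
            return [(pieces[0][0], pieces[1][1])]
        return pieces

    ri = Transcript(
        f"{gene_id}.2",
        exons=[(start, total_end)],
        utr5=r_iv(b_u5, "5UTR"),
        cds=r_iv(b_cds, "CDS"),
        utr3=r_iv(b_u3, "3UTR"),
    )
    return GeneModel(gene_id, chrom, strand, [si, ri])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
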
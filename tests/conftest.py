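"""Shared fixtures: toy gene models and a small simulated dataset."""

from __future__ import annotations

import numpy as np
import pytest

from deju.annotation import (
    Exon,
    GeneModel,
    Transcript,
    build_junction_database,
    flatten_gene_exons,
)
from deju.read_sim import ExpressionConfig, SampleDesign
from deju.splice_sim import SimConfig, generate_transcriptome


@pytest.fixture
def toy_gene() -> GeneModel:
    """Three-exon gene G on chr1: (100,200), (300,400), (500,600)."""
    exons = (
        Exon("chr1", 100, 200),
        Exon("chr1", 300, 400),
        Exon("chr1", 500, 600),
    )
    tx = Transcript("G.ref", "G", exons)
    return flatten_gene_exons(GeneModel("G", "chr1", "+", transcripts=[tx]))


@pytest.fixture
def toy_annotation(toy_gene):
    genes = [toy_gene]
    return genes, build_junction_database(genes)


@pytest.fixture(scope="session")
def small_transcriptome():
    """40 genes, 8 true-DEU, deterministic."""
    return generate_transcriptome(SimConfig(n_genes=40, n_true_deu=8, seed=3))


@pytest.fixture(scope="session")
def small_design():
    return SampleDesign(n_per_group=2, library_size=20_000)


@pytest.fixture(scope="session")
def expression_config():
    return ExpressionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
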
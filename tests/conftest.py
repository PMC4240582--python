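"""Shared fixtures: session-scoped scenario runs (each simulates a 5 Mb toy
genome and runs the full calling pipeline once) and small reusable objects."""

from __future__ import annotations

import numpy as np
import pytest

from p53peaks.genome import GenomeAssembly, GenomicInterval, GeneModel
from p53peaks.pipeline import run_scenario

SESSION_SEED = 11


@pytest.fixture(scope="session")
def null_run():
    return run_scenario("null", seed=SESSION_SEED)


@pytest.fixture(scope="session")
def hct_run():
    return run_scenario("hct116_like", seed=SESSION_SEED)


@pytest.fixture(scope="session")
def imr_run():
    return run_scenario("imr90_like", seed=SESSION_SEED)


@pytest.fixture
def toy_assembly():
    return GenomeAssembly("toy1", {"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def plus_gene():
    """+ strand gene, TSS=10000, three exons, introns at known positions."""
    exons = (
        GenomicInterval("chr1", 10_000, 10_500),
        GenomicInterval("chr1", 17_000, 17_400),
        GenomicInterval("chr1", 19_000, 20_000),
    )
    return GeneModel(
        "geneP", GenomicInterval("chr1", 10_000, 20_000, "+"), "+", exons
    )


@pytest.fixture
def minus_gene():
    """− strand gene, txEnd=20000 so TSS=19999."""
    exons = (
        GenomicInterval("chr1", 10_000, 11_000),
        GenomicInterval("chr1", 12_000, 12_600),
        GenomicInterval("chr1", 19_500, 20_000),
    )
    return GeneModel(
        "geneM", GenomicInterval("chr1", 10_000, 20_000, "-"), "-", exons
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
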
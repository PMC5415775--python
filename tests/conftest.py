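"""Shared fixtures: a small reference + panel reused across the suite."""
import numpy as np
import pytest

from panelpipe.align import KmerIndex
from panelpipe.sim import (ReferenceConfig, ReferenceModel, build_reference,
                           design_panel)


@pytest.fixture(scope="session")
def reference() -> ReferenceModel:
    cfg = ReferenceConfig(chromosomes={
        "chr5": 1000, "chr8": 1000, "chr11": 1000, "chr18": 1000,
        "GENE1-seg": 1200, "GENE2-seg": 1200,
    })
    return build_reference(cfg, seed=1)


@pytest.fixture(scope="session")
def panel(reference):
    return design_panel(reference, {"GENE1": "GENE1-seg", "GENE2": "GENE2-seg"},
                        control_spec=14, amplicon_length=150, step=100)


@pytest.fixture(scope="session")
def kmer_index(reference) -> KmerIndex:
    return KmerIndex(reference)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
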
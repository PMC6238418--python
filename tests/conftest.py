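import numpy as np
import pytest

from promarch.annotation import GeneModel
from promarch.simdata import TruthConfig, simulate_genome


@pytest.fixture(scope="session")
def small_cfg() -> TruthConfig:
    return TruthConfig(genes_per_class=20, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(genome, genes, truth) for a 120-gene synthetic dataset."""
    return simulate_genome(small_cfg)


@pytest.fixture()
def plus_gene() -> GeneModel:
    return GeneModel("gp", "chr1", "+", 10000, 20000, ((10000, 12000), (15000, 20000)))


@pytest.fixture()
def minus_gene() -> GeneModel:
    return GeneModel("gm", "chr1", "-", 20000, 10000, ((10000, 12000), (15000, 20000)))


def uniform_track(length: int, value: float = 1.0, chrom: str = "chrS"):
    from promarch.coverage import TagTrack

    return TagTrack({chrom: np.full(length, value, dtype=float)})
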
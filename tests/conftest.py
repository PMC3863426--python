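import numpy as np
import pandas as pd
import pytest

from phylostrat_rt import SimulationConfig, get_timeline


@pytest.fixture(scope="session")
def human_timeline():
    return get_timeline("human")


@pytest.fixture(scope="session")
def mouse_timeline():
    return get_timeline("mouse")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A fast, fully-planted simulation world for unit tests."""
    return SimulationConfig(
        seed=7,
        n_genes=300,
        n_families=30,
        n_individuals=20,
        n_chromosomes=2,
        chromosome_length=20_000_000,
        probe_spacing=2_000,
    )


def make_genes(chroms, starts, ends, ids=None):
    """Tiny BED-like gene table helper."""
    ids = ids or [f"g{i}" for i in range(len(starts))]
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "gene_id": ids}
    )
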
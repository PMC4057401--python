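import numpy as np
import pytest

from aptaclass import folding, pool_io, synthetic_data


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_spec():
    """A small but structurally faithful generator configuration."""
    return synthetic_data.GeneratorSpec(n_rounds=10, pool_size=12, seed=3)


@pytest.fixture(scope="session")
def small_pool(small_spec):
    pool, truth = synthetic_data.generate_pools(small_spec)
    return pool, truth


@pytest.fixture(scope="session")
def small_structures(small_pool):
    pool, _ = small_pool
    return folding.fold_pool(pool)


def make_pool(entries):
    """entries: iterable of (round, clone, sequence)."""
    return pool_io.Pool([pool_io.SequenceRecord(r, str(c), s) for r, c, s in entries])


@pytest.fixture
def hairpin_40mer():
    # 11-nt 5' pad, 6-bp GC stem, 6-nt loop, stem', 11-nt 3' pad
    return "ATATATATATA" + "GGCGGC" + "AACAAC" + "GCCGCC" + "TATATATATAT"
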
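import numpy as np
import pytest

from gsabench import synth
from gsabench.datamodel import ExpressionDataset, GeneSetCollection


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_ds(rng):
    """12 genes x (4 cases + 4 controls), independent null expression."""
    expr = rng.normal(8.0, 2.0, size=(12, 8))
    return ExpressionDataset(
        expr=expr,
        feature_ids=[f"g{i:02d}" for i in range(12)],
        sample_ids=[f"s{i}" for i in range(8)],
        group=np.array([1, 1, 1, 1, 0, 0, 0, 0]),
        name="tiny",
    )


@pytest.fixture()
def paired_ds(rng):
    """10 genes x 5 paired case/control blocks."""
    expr = rng.normal(8.0, 2.0, size=(10, 10))
    return ExpressionDataset(
        expr=expr,
        feature_ids=[f"g{i:02d}" for i in range(10)],
        sample_ids=[f"s{i}" for i in range(10)],
        group=np.array([1] * 5 + [0] * 5),
        block=np.array(list(range(5)) * 2),
        name="tiny-paired",
    )


@pytest.fixture()
def small_collection():
    return GeneSetCollection(
        sets={
            "SA": ["g00", "g01", "g02", "g03"],
            "SB": ["g04", "g05", "g06"],
            "SC": ["g02", "g05", "g07", "g08", "g09"],
        }
    )


@pytest.fixture(scope="session")
def synth_small():
    """A modest synthetic benchmark dataset with a real effect, shared
    across tests that only need a realistic instance."""
    cfg = synth.SynthConfig(
        n_genes=300, n_sets=12, set_size_range=(8, 30), target_size=15,
        n_per_group=6, rho=0.1, effect_size=1.0, de_fraction=0.5, seed=7,
    )
    collection, target_id, pairs = synth.generate_benchmark(cfg, 1)
    ds, truth = pairs[0]
    return cfg, collection, target_id, ds, truth
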
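"""Shared fixtures: the planted-motif benchmark and a model trained on it.

The benchmark follows the package's standard synthetic study conditions:
2,000 training pairs and 500 test pairs of 500-bp enhancers, balanced labels,
distance-matched negatives, and a compact architecture (16 kernels of width 8,
pool window 5, 16 BLSTM units per direction). Training the session model takes
about a minute; it is shared by every test that needs a fitted network.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from encontact.model import ModelSpec, build_model
from encontact.sequence_io import one_hot_encode
from encontact.synthetic import SyntheticConfig, plant_pair_dataset

#: Architecture/training settings of the synthetic benchmark model.
BENCH_SPEC = dict(
    n_kernels=16,
    kernel_len=8,
    pool_window=5,
    blstm_units=16,
    dense_units=32,
    dropout_rate=0.15,
    learning_rate=3e-3,
    max_epochs=15,
    patience=4,
)

BENCH_SEED = 7
N_TRAIN, N_TEST = 2000, 500


@pytest.fixture(scope="session")
def benchmark():
    """Planted-motif dataset with a fixed shuffled train/test split."""
    cfg = SyntheticConfig(seed=BENCH_SEED, L=500, n_pos=1250, n_neg=1250)
    ds = plant_pair_dataset(cfg)
    seqs = {e.id: one_hot_encode(e.sequence) for e in ds.enhancers}
    rng = np.random.default_rng(BENCH_SEED)
    pairs = [ds.pairs[i] for i in rng.permutation(len(ds.pairs))]
    return SimpleNamespace(
        cfg=cfg,
        dataset=ds,
        sequences=seqs,
        train=pairs[:N_TRAIN],
        test=pairs[N_TRAIN : N_TRAIN + N_TEST],
        test_labels=[p.label for p in pairs[N_TRAIN : N_TRAIN + N_TEST]],
    )


@pytest.fixture(scope="session")
def trained_model(benchmark):
    """One model fitted on the benchmark training split (seed 0)."""
    spec = ModelSpec(seed=0, **BENCH_SPEC)
    return build_model(spec).fit(benchmark.train, benchmark.sequences)


@pytest.fixture(scope="session")
def tiny_planted():
    """A much smaller planted dataset for fast unit tests."""
    cfg = SyntheticConfig(seed=3, L=200, n_enhancers=100, chrom_len=200_000,
                          n_pos=150, n_neg=150)
    ds = plant_pair_dataset(cfg)
    seqs = {e.id: one_hot_encode(e.sequence) for e in ds.enhancers}
    return SimpleNamespace(cfg=cfg, dataset=ds, sequences=seqs)
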
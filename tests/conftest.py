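import numpy as np
import pandas as pd
import pytest

from toxsig.containers import CountMatrix
from toxsig.simulate import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A compact two-batch, three-class experiment with ground truth."""
    cfg = SimConfig(
        n_genes=300,
        n_compounds_per_class=2,
        n_replicates=3,
        seed=11,
    )
    cm, meta, annot, truth = generate_experiment(cfg)
    return cfg, cm, meta, annot, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def nb_counts(rng, mu, alpha, n_cols):
    """NB count matrix with per-gene means mu, common dispersion alpha."""
    cols = [
        rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
        for _ in range(n_cols)
    ]
    return np.column_stack(cols)


def make_cm(arr, prefix_g="g", prefix_s="s"):
    G, S = arr.shape
    return CountMatrix(
        pd.DataFrame(
            arr,
            index=[f"{prefix_g}{i}" for i in range(G)],
            columns=[f"{prefix_s}{j}" for j in range(S)],
        )
    )
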
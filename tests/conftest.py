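import numpy as np
import pandas as pd
import pytest

from regulasso import SimConfig, generate_dataset
from regulasso.yinyang import tumor_fold_changes

TINY = SimConfig(
    n_tumors_per_subtype=4,
    n_normals=8,
    n_genes=80,
    n_tfs=6,
    n_mirnas=8,
    n_active_per_subtype=2,
    effect_size=1.0,
    noise_sd=0.3,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny():
    """Small dataset + truth for unit tests (16 tumors, 80 genes)."""
    return generate_dataset(TINY)


@pytest.fixture(scope="session")
def tiny_responses(tiny):
    dataset, _ = tiny
    genes = sorted(dataset.genes)
    return genes, tumor_fold_changes(
        dataset.tumor_expression, dataset.normal_expression, genes
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_lasso_instance(rng, n=50, p=10, noise=0.5):
    """A random regression instance with a few active features."""
    X = rng.standard_normal((n, p))
    w = np.zeros(p)
    active = rng.choice(p, size=max(1, p // 3), replace=False)
    w[active] = rng.normal(0, 1, size=len(active))
    y = X @ w + noise * rng.standard_normal(n)
    design = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)])
    return design, pd.Series(y)
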
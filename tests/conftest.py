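import numpy as np
import pandas as pd
import pytest

from gxede import ExpressionMatrix, SimulationConfig, simulate_dataset


def make_matrix(values, cells, gene_ids=None, scale="log2"):
    """Build an ExpressionMatrix from a row-major list and per-sample cells.

    ``cells`` is a list of (genotype, environment) pairs, one per column.
    """
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = [f"s{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "genotype": [c[0] for c in cells],
            "environment": [c[1] for c in cells],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        sample_meta=meta,
        scale=scale,
    )


def small_sim_config(n_genes, seed, effect_size=2.0, planted_per_category=0):
    """A SimulationConfig safe for tiny gene counts (defaults plant nothing)."""
    from gxede import CATEGORIES

    config = SimulationConfig(n_genes=n_genes, seed=seed, effect_size=effect_size)
    config.category_counts = {c: planted_per_category for c in CATEGORIES}
    return config


#: Two samples in every design cell, in a fixed column order.
CELLS_2x2 = [
    ("WT", "ground"), ("WT", "ground"),
    ("WT", "flight"), ("WT", "flight"),
    ("KO", "ground"), ("KO", "ground"),
    ("KO", "flight"), ("KO", "flight"),
]


@pytest.fixture
def worked_example_matrix():
    """One gene with cell means (3, 7, 2, 6) and pooled variance 2 on 4 df."""
    return make_matrix([[2, 4, 6, 8, 1, 3, 5, 7]], CELLS_2x2)


@pytest.fixture(scope="session")
def small_simulation():
    """A modest planted dataset shared across read-only tests."""
    config = SimulationConfig(n_genes=400, seed=11, effect_size=4.0)
    config.category_counts = {c: 10 for c in config.category_counts}
    matrix, truth = simulate_dataset(config)
    return config, matrix, truth
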
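import numpy as np
import pandas as pd
import pytest

import fermtx as fx


@pytest.fixture
def tiny_counts():
    """3 genes x 2 samples, written as expected by the plain TSV reader."""
    return pd.DataFrame(
        {"s1": [2, 3, 10], "s2": [4, 6, 20]},
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset reused by read-only tests."""
    config = fx.GeneratorConfig(n_genes=800, n_de_per_group=20)
    return fx.simulate_dataset(config, seed=11)


def random_de_table(rng, n_genes=30):
    """Random small DE table with internally consistent direction labels."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    lfc = rng.normal(0, 2.0, n_genes)
    padj = rng.uniform(0, 1, n_genes) ** 2
    direction = np.where(
        (padj < 0.05) & (np.abs(lfc) > 1.0), np.where(lfc > 0, "up", "down"), "ns"
    )
    return pd.DataFrame(
        {"log2FC": lfc, "padj": padj, "direction": direction},
        index=pd.Index(genes, name="gene_id"),
    )
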
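import numpy as np
import pandas as pd
import pytest

from edgepert import BackgroundNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_net():
    return BackgroundNetwork.from_pairs(
        [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D"), ("B", "D")]
    )


def random_network(rng, n_genes=40, n_edges=120):
    """Random simple network over synthetic gene symbols."""
    pairs = set()
    genes = [f"G{i:03d}" for i in range(n_genes)]
    while len(pairs) < n_edges:
        a, b = rng.choice(n_genes, size=2, replace=False)
        pairs.add((genes[min(a, b)], genes[max(a, b)]))
    return BackgroundNetwork.from_pairs(sorted(pairs))


def random_expression(rng, genes, n_samples, prefix="S"):
    """Nonnegative expression frame over the given genes."""
    values = rng.gamma(2.0, 50.0, (len(genes), n_samples))
    cols = [f"{prefix}{i:03d}" for i in range(n_samples)]
    return pd.DataFrame(values, index=list(genes), columns=cols)
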
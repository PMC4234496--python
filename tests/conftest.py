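import networkx as nx
import numpy as np
import pytest

from egonet import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_network():
    """Six genes: a tight square A-B-C-D plus a pendant path E-F off D."""
    return nx.Graph(
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("D", "E"), ("E", "F")]
    )


def make_dataset(
    n_genes=6,
    n_samples=40,
    signal_genes=(0, 1),
    effect=1.5,
    seed=0,
    gene_names=None,
):
    """Standard-normal expression with a mean shift on the signal genes."""
    rng = np.random.default_rng(seed)
    genes = gene_names or [chr(ord("A") + i) for i in range(n_genes)]
    labels = np.array([0, 1] * (n_samples // 2))
    values = rng.standard_normal((n_genes, n_samples))
    for g in signal_genes:
        values[g, labels == 1] += effect
    return ExpressionDataset(
        genes=list(genes),
        samples=[f"S{i}" for i in range(n_samples)],
        values=values,
        labels=labels,
    )


@pytest.fixture
def toy_dataset():
    """Expression over the toy network's genes; A and B carry the signal."""
    return make_dataset(n_genes=6, n_samples=40, signal_genes=(0, 1), seed=0)
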
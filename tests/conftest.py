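"""Shared fixtures: tiny hand-built graphs and scaled-down scenarios."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from monet.data_io import (AttributedGraphDataset, GeneNetwork, LabelCatalog,
                           OmicsFeatureTable, assemble_dataset)
from monet.synthetic import (SyntheticConfig, generate_features,
                             generate_labels, generate_network_ensemble)
from monet.training import ModelConfig

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_network(nodes, edge_pairs, name="net"):
    return GeneNetwork(nodes=tuple(sorted(nodes)),
                       edges=frozenset(frozenset(e) for e in edge_pairs),
                       name=name)


@pytest.fixture
def path_network():
    """A - B - C path."""
    return make_network("ABC", [("A", "B"), ("B", "C")])


@pytest.fixture
def separable_dataset():
    """Two disconnected 10-cliques with opposite constant features.

    Clique 1 genes are positives with features +1, clique 2 negatives with
    features -1; linearly separable, so any sane configuration must reach
    perfect train and test accuracy.
    """
    genes_a = [f"A{i:02d}" for i in range(10)]
    genes_b = [f"B{i:02d}" for i in range(10)]
    edges = [(a, b) for i, a in enumerate(genes_a) for b in genes_a[i + 1:]]
    edges += [(a, b) for i, a in enumerate(genes_b) for b in genes_b[i + 1:]]
    network = make_network(genes_a + genes_b, edges, name="cliques")
    d = 4
    values = np.vstack([np.ones((10, d)), -np.ones((10, d))])
    table = OmicsFeatureTable(
        genes=tuple(genes_a + genes_b),
        columns=tuple(f"MF_C{j}" for j in range(d)),
        values=values)
    labels = LabelCatalog(positives=frozenset(genes_a),
                          negatives=frozenset(genes_b))
    return assemble_dataset(network, table, labels)


@pytest.fixture(scope="session")
def small_scenario():
    """A scaled-down planted-driver scenario for fast training tests."""
    config = SyntheticConfig(
        n_genes=120, n_drivers=24, p_in=0.3, p_out=0.02,
        omics_effect={"MF": 2.0, "METH": 0.0, "GE": 2.0, "CNA": 0.0},
        n_networks=3, edge_rewire_fraction=0.2, seed=7)
    networks = generate_network_ensemble(config)
    features = generate_features(config)
    labels = generate_labels(config)
    datasets = [assemble_dataset(n, features, labels) for n in networks]
    return config, datasets, labels


@pytest.fixture
def fast_config():
    return ModelConfig(cv_folds=2, max_epochs=120, patience=15, seed=3)


def random_graph(rng, n, p=0.3):
    """Random undirected graph as (GeneNetwork, dense adjacency)."""
    width = len(str(n))
    nodes = tuple(f"n{i:0{width}d}" for i in range(n))
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1
    edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
             if adj[i, j]]
    return make_network(nodes, edges), adj
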
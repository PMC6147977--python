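"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pytest

from phagekit.datatypes import ODTimeSeries, Treatment
from phagekit.pangenome import PhageGenomeSet
from phagekit.phylo import UnrootedTree


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def standard_grid():
    """The standard assay grid: 49 points, 20-min spacing, 16 h."""
    return np.arange(49) / 3.0


def make_series(od, treatment=None, replicate=0):
    od = np.asarray(od, dtype=float)
    times = np.arange(len(od)) / 3.0
    return ODTimeSeries(
        treatment=treatment or Treatment(strain_id="AB01"),
        replicate=replicate,
        times=times,
        od=od,
    )


@pytest.fixture()
def five_leaf_tree():
    return UnrootedTree.from_newick(
        "((A:1.0,B:2.0):0.5,(C:1.5,D:0.7):0.3,E:2.2);"
    )


def random_additive_tree(n_leaves, rng):
    """Random unrooted binary topology with uniform(0.1, 1) branch lengths."""
    from phagekit.simulate import random_topology

    labels = [f"T{i}" for i in range(n_leaves)]
    order = [labels[i] for i in rng.permutation(n_leaves)]
    topo = random_topology(order, rng)
    tree = topo.dendropy_tree
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.1, 1.0))
    return UnrootedTree.from_newick(tree.as_string(schema="newick")), labels


def two_proteomes(identical=True, rng=None, n_genes=10, length=120):
    """Two genomes with either identical or unrelated proteomes."""
    rng = rng or np.random.default_rng(0)
    from phagekit.simulate import _random_protein

    genes_a = [(f"g{i}", _random_protein(rng, length)) for i in range(n_genes)]
    if identical:
        genes_b = list(genes_a)
    else:
        genes_b = [(f"g{i}", _random_protein(rng, length))
                   for i in range(n_genes)]
    return PhageGenomeSet(genomes={"A": genes_a, "B": genes_b})
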
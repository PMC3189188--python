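import itertools

import numpy as np
import pytest

from rnol.models import jtt_model
from rnol.tree import PhyloTree

import networkx as nx


@pytest.fixture(scope="session")
def jtt():
    return jtt_model()


def random_tree(rng: np.random.Generator, n_leaves: int,
                with_lengths: bool = True,
                with_supports: bool = False,
                rooted: bool = False) -> PhyloTree:
    """Random resolved tree by stepwise leaf addition (test helper)."""
    labels = ["t%02d" % i for i in range(n_leaves)]
    g = nx.Graph()
    g.add_node(0, taxon=labels[0])
    g.add_node(1, taxon=labels[1])
    g.add_edge(0, 1)
    next_id = 2
    for k in range(2, n_leaves):
        edges = list(g.edges)
        u, v = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
        mid, leaf = next_id, next_id + 1
        next_id += 2
        g.add_node(mid)
        g.add_node(leaf, taxon=labels[k])
        g.add_edge(u, mid)
        g.add_edge(mid, v)
        g.add_edge(mid, leaf)
    if with_lengths:
        for _, _, d in g.edges(data=True):
            d["length"] = round(float(rng.uniform(0.01, 1.0)), 6)
    root = next(nd for nd in g.nodes if g.degree(nd) > 1)
    tree = PhyloTree(g, root, rooted=rooted)
    if with_supports:
        for child, parent in tree._edges_postorder():
            below = tree._leafset_below(child, parent)
            if len(below) >= 2 and len(tree.taxa - below) >= 2:
                g.edges[child, parent]["support"] = round(
                    float(rng.uniform(0.0, 1.0)), 2)
        tree._bipartitions = None
    return tree
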
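import random

import dendropy
import pytest

from dtlrec import LabeledTree, Node, write_newick


def random_topology(labels, rng: random.Random, lengths: bool = True) -> LabeledTree:
    """Random binary tree over the given leaf labels (uniform joins)."""
    nodes = [Node(l, rng.uniform(0.05, 2.0) if lengths else None) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node("", rng.uniform(0.05, 2.0) if lengths else None)
        parent.children = [a, b]
        nodes.append(parent)
    nodes[0].length = None
    return LabeledTree(nodes[0])


def random_instance(rng: random.Random, max_leaves: int = 6):
    """Random (gene, species, leafmap) reconciliation instance."""
    ns = rng.randint(3, max_leaves)
    ng = rng.randint(2, max_leaves)
    species = random_topology([f"S{i}" for i in range(ns)], rng)
    gene_labels = [f"g{i}" for i in range(ng)]
    gene = random_topology(gene_labels, rng)
    leafmap = {g: f"S{rng.randrange(ns)}" for g in gene_labels}
    return gene, species, leafmap


def rf_distance(t1: LabeledTree, t2: LabeledTree) -> int:
    """Unrooted Robinson-Foulds distance via dendropy (independent oracle)."""
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


@pytest.fixture
def rng():
    return random.Random(20260927)
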
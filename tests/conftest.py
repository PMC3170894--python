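import dendropy
import numpy as np
import pytest

from haloadapt.phylo import DistanceMatrix


def random_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random unrooted topology with positive branch lengths, built by
    repeated random joins (independent of the package's NJ code)."""
    labels = [f"t{i+1}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    for nd in nodes:
        nd.edge.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.uniform(0.1, 1.0))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths via dendropy's distance matrix (oracle)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
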
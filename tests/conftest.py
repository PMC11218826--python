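import numpy as np
import pytest

from nlrmacro.simulate import SimConfig


@pytest.fixture
def small_cfg():
    """Desk-scale configuration shared by recovery tests."""
    return SimConfig(seed=11, n_species=2, proteins_per_species=40,
                     n_structures=60, n_orthogroups=150)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_trees(n_trees: int, max_tips: int = 25, seed: int = 0):
    """Random bifurcating trees with branch lengths spanning both
    trimming cutoffs; yields newick strings."""
    import dendropy

    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        n = int(rng.integers(4, max_tips + 1))
        labels = [f"t{i}" for i in range(n)]
        tns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)

        def leaf(lbl):
            node = dendropy.Node()
            node.taxon = tns.new_taxon(label=lbl)
            return node

        tree.seed_node.add_child(leaf(labels[0]))
        tree.seed_node.add_child(leaf(labels[1]))
        for lbl in labels[2:]:
            nodes = [x for x in tree.preorder_node_iter() if x is not tree.seed_node]
            target = nodes[rng.integers(len(nodes))]
            parent = target.parent_node
            parent.remove_child(target)
            mid = dendropy.Node()
            parent.add_child(mid)
            mid.add_child(target)
            mid.add_child(leaf(lbl))
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                # mix of tiny, moderate and cutoff-crossing lengths
                u = rng.random()
                if u < 0.15:
                    node.edge.length = float(rng.uniform(0.0, 0.05))
                elif u < 0.85:
                    node.edge.length = float(rng.exponential(0.3))
                else:
                    node.edge.length = float(rng.uniform(0.5, 1.6))
        yield tree.as_string(schema="newick", unquoted_underscores=True).strip()
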
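import numpy as np
import pytest

from gcmig.simulate import SimParams, simulate_tonsil


@pytest.fixture(scope="session")
def default_sim():
    """A moderately sized simulation shared by read-only tests."""
    params = SimParams(n_lineages=60, sample_prob=0.5, n_follicles=15,
                       carrying_capacity=200)
    return simulate_tonsil(params, seed=424242)


@pytest.fixture(scope="session")
def labelled_trees(default_sim):
    """True-genealogy trees with parsimony labels and extracted events."""
    from gcmig.phylo import build_tree, extract_migrations, parsimony_labels

    trees, events = [], {}
    for lid, genealogy in default_sim.truth.genealogies.items():
        tree = build_tree(mode="true", genealogy=genealogy, lineage_id=lid)
        if tree is None:
            continue
        parsimony_labels(tree)
        events[lid] = extract_migrations(tree)
        trees.append(tree)
    return trees, events


def random_binary_tree(rng, n_leaves, n_labels, max_length=0.05):
    """Random rooted binary tree with labelled leaves (test utility)."""
    from gcmig.tree import LineageTree, Node

    nodes = [Node(name=f"t{i}", length=float(rng.uniform(0, max_length)),
                  label=int(rng.integers(0, n_labels)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(0, max_length)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return LineageTree(root)


def exhaustive_min_changes(tree):
    """Brute-force minimum label changes over all internal assignments.

    Independent oracle for the parsimony count: enumerates every assignment
    of leaf-observed labels to internal nodes and counts label-changing
    branches, vectorized over assignments.
    """
    leaves = tree.leaves()
    states = sorted({leaf.label for leaf in leaves})
    internal = [n for n in tree.preorder() if not n.is_leaf]
    k, m = len(states), len(internal)
    idx_of = {node: i for i, node in enumerate(internal)}
    state_idx = {s: i for i, s in enumerate(states)}
    n_assign = k ** m
    assign = np.empty((n_assign, m), dtype=np.int64)
    reps = 1
    for col in range(m):
        pattern = np.repeat(np.arange(k), n_assign // (reps * k))
        assign[:, col] = np.tile(pattern, reps)
        reps *= k
    cost = np.zeros(n_assign, dtype=np.int64)
    for node in tree.preorder():
        if node.parent is None:
            continue
        pcol = assign[:, idx_of[node.parent]]
        if node.is_leaf:
            cost += pcol != state_idx[node.label]
        else:
            cost += pcol != assign[:, idx_of[node]]
    return int(cost.min())
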
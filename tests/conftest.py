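import random

import pytest

from phyloconflict.treemodel import Node, Tree


def random_tree(
    rng: random.Random,
    n_leaves: int,
    with_lengths: bool = True,
    with_supports: bool = True,
    labels=None,
) -> Tree:
    """Random binary tree built by sequential leaf attachment.

    Test-local generator, independent of the package's MSC simulator.
    """
    labels = labels or [f"t{i}" for i in range(n_leaves)]
    nodes = [Node(label=lab) for lab in labels[:2]]
    root = Node()
    for n in nodes:
        root.add_child(n)
    edges = list(nodes)
    for lab in labels[2:n_leaves]:
        target = rng.choice(edges)
        parent = target.parent
        new_internal = Node()
        idx = parent.children.index(target)
        parent.children[idx] = new_internal
        new_internal.parent = parent
        new_internal.add_child(target)
        leaf = new_internal.add_child(Node(label=lab))
        edges.extend([new_internal, leaf])
    tree = Tree(root, rooted=True)
    for node in tree.preorder():
        if node is tree.root:
            continue
        if with_lengths:
            node.length = round(rng.uniform(0.01, 2.0), 6)
        if with_supports and not node.is_leaf:
            node.support = float(rng.randint(0, 100))
    return tree


@pytest.fixture
def rng():
    return random.Random(20240901)
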
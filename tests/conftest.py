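import itertools
import math

import numpy as np
import pytest

from corona_evo.ancestral import CostModel
from corona_evo.trees import Tree, TreeNode, eukaryote_fixture_tree


@pytest.fixture
def fixture_tree():
    return eukaryote_fixture_tree()


def random_tree(rng: np.random.Generator, n_leaves: int) -> Tree:
    """Random rooted tree (polytomies allowed) over leaves L1..Ln."""
    nodes = [TreeNode(f"L{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        k = int(rng.integers(2, min(len(nodes), 4) + 1))
        idx = rng.choice(len(nodes), size=k, replace=False)
        parent = TreeNode("")
        for i in sorted(idx, reverse=True):
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    return Tree(nodes[0])


def brute_force_min_cost(tree: Tree, leaf_states: dict, costs: CostModel) -> float:
    """Independent oracle: exhaustive enumeration over all labelings.

    Internal nodes and unknown ('?') leaves range over {0, 1}; the minimum
    total transition cost (plus a stem gain under the forced-0 root prior)
    is returned.
    """
    internal = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves()
    unknown = [l for l in leaves if str(leaf_states[l.name]) == "?"]
    fixed = {
        l.name: int(str(leaf_states[l.name]))
        for l in leaves
        if str(leaf_states[l.name]) != "?"
    }
    best = math.inf
    free_nodes = internal + unknown
    for assignment in itertools.product((0, 1), repeat=len(free_nodes)):
        states = dict(fixed)
        states.update({n.name: s for n, s in zip(free_nodes, assignment)})
        total = sum(
            costs.transition(states[p.name], states[c.name]) for p, c in tree.edges()
        )
        if costs.root_prior == "forced-0" and states[tree.root.name] == 1:
            total += costs.cost_gain
        best = min(best, total)
    return best
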
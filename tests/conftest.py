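import numpy as np
import pytest

from cicadasong import parse_newick, simulate_tree


@pytest.fixture
def basic_tree():
    """((A:1,B:1):1,C:2); — ultrametric, height 2."""
    return parse_newick("((A:1,B:1):1,C:2);")


def make_random_tree(n_tips: int, seed: int):
    return simulate_tree(n_tips, birth_rate=1.0, seed=seed)


def pairwise_distance(tree, i: int, j: int) -> float:
    """Path-sum oracle: tip-to-tip distance by walking parent pointers."""
    anc_i, d = {}, 0.0
    v = i
    while v >= 0:
        anc_i[v] = d
        d += tree.length[v]
        v = tree.parent[v]
    v, d = j, 0.0
    while v not in anc_i:
        d += tree.length[v]
        v = tree.parent[v]
    return d + anc_i[v]


def mrca_depth(tree, i: int, j: int) -> float:
    """Shared root-to-MRCA path length by explicit ancestor walks."""
    path_i = []
    v = i
    while v >= 0:
        path_i.append(v)
        v = tree.parent[v]
    set_i = set(path_i)
    v = j
    while v not in set_i:
        v = tree.parent[v]
    mrca = v
    depth = 0.0
    while tree.parent[mrca] >= 0:
        depth += tree.length[mrca]
        mrca = tree.parent[mrca]
    return depth
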
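"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive quantities by direct enumeration, deliberately
avoiding the library code paths they are used to check.
"""

import itertools

import numpy as np
import pytest

from fphc.bn_model import DiscreteBayesNet, NetworkStructure


def make_bn(nodes, edges, cards, cpts, labels=None):
    """Convenience constructor from plain dicts/lists."""
    return DiscreteBayesNet(
        NetworkStructure(list(nodes), set(edges)),
        dict(cards),
        {k: np.asarray(v, dtype=float) for k, v in cpts.items()},
        labels,
    )


@pytest.fixture
def chain_bn():
    """T -> A -> B, binary, uniform root, 0.9 copy fidelity per link."""
    return make_bn(
        ["T", "A", "B"],
        {("T", "A"), ("A", "B")},
        {"T": 2, "A": 2, "B": 2},
        {
            "T": [0.5, 0.5],
            "A": [[0.9, 0.1], [0.1, 0.9]],
            "B": [[0.9, 0.1], [0.1, 0.9]],
        },
    )


def brute_force_joint(bn):
    """Joint table by looping over every state combination and multiplying
    CPT lookups one by one (independent of exact_joint's broadcasting)."""
    nodes = bn.structure.nodes
    shape = tuple(bn.cardinalities[v] for v in nodes)
    out = np.zeros(shape)
    for states in itertools.product(*[range(c) for c in shape]):
        assign = dict(zip(nodes, states))
        p = 1.0
        for v in nodes:
            pa = bn.structure.parents(v)
            idx = tuple(assign[x] for x in pa) + (assign[v],)
            p *= bn.cpts[v][idx]
        out[states] = p
    return out


def brute_force_pair_mi(joint, nodes, a, b):
    """MI of two nodes from a joint table, written out term by term."""
    ia, ib = nodes.index(a), nodes.index(b)
    axes = tuple(k for k in range(len(nodes)) if k not in (ia, ib))
    pab = joint.sum(axis=axes)
    if ia > ib:
        pab = pab.T
    pa = pab.sum(axis=1)
    pb = pab.sum(axis=0)
    mi = 0.0
    for x in range(pab.shape[0]):
        for y in range(pab.shape[1]):
            if pab[x, y] > 0:
                mi += pab[x, y] * np.log(pab[x, y] / (pa[x] * pb[y]))
    return mi


def all_dags(nodes):
    """Every DAG over the given nodes, as edge sets (exhaustive enumeration)."""
    pairs = list(itertools.permutations(nodes, 2))
    dags = []
    for mask in range(2 ** len(pairs)):
        edges = {pairs[i] for i in range(len(pairs)) if mask >> i & 1}
        if any((b, a) in edges for a, b in edges):
            continue
        g = NetworkStructure(list(nodes), edges)
        from fphc.bn_model import is_acyclic

        if is_acyclic(g):
            dags.append(edges)
    return dags
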
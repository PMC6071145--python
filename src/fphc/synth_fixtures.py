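"""Benchmark-network and dataset generators.

The generators emulate the benchmark design the method is validated on:
discrete Bayesian networks with known structure (tree skeletons, the
duplicate-path motifs, random sparse DAGs), random Dirichlet CPTs whose
concentration controls dependence strength, and ancestral samples at sizes
from 50 to 50,000.  Variables default to 3 states, the usual
under/normal/over-expressed coding for discretized expression data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bn_model import DiscreteBayesNet, NetworkStructure, SampleMatrix

__all__ = [
    "random_tree",
    "random_dag",
    "random_cpts",
    "motif_fixtures",
    "discretize",
    "DEFAULT_CARDINALITY",
]

#: Three states per variable: under- / normally / over-expressed.
DEFAULT_CARDINALITY = 3


def _names(n: int) -> list[str]:
    return [f"X{i + 1}" for i in range(n)]


def random_tree(n: int, seed: int) -> NetworkStructure:
    """A connected DAG whose skeleton is a random recursive tree.

    Node 1 is the root; each later node picks one parent uniformly among the
    earlier nodes, so every node has in-degree <= 1 (no colliders, n-1 edges).
    """
    if n < 2:
        raise ValueError("a tree needs at least 2 nodes")
    rng = np.random.default_rng(seed)
    names = _names(n)
    edges = {(names[int(rng.integers(0, i))], names[i]) for i in range(1, n)}
    return NetworkStructure(names, edges)


def random_dag(n: int, max_parents: int, edge_prob: float, seed: int) -> NetworkStructure:
    """A random sparse DAG over a shuffled topological order.

    Each node draws each predecessor as a parent independently with
    ``edge_prob``; if more than ``max_parents`` are drawn, a uniform subset of
    that size is kept.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = _names(n)
    order = list(rng.permutation(names))
    edges: set[tuple[str, str]] = set()
    for i, child in enumerate(order):
        preds = order[:i]
        drawn = [p for p in preds if rng.random() < edge_prob]
        if len(drawn) > max_parents:
            keep = rng.choice(len(drawn), size=max_parents, replace=False)
            drawn = [drawn[k] for k in sorted(keep)]
        edges.update((p, child) for p in drawn)
    return NetworkStructure(names, edges)


def motif_fixtures() -> dict[str, NetworkStructure]:
    """The duplicate-path motifs and the target-relation cases, by name.

    ``feedback`` contains a directed cycle: it exists for cycle-detection and
    documentation only and cannot parameterize a Bayesian network.
    """
    return {
        # duplicate-path motifs
        "feed_forward": NetworkStructure(
            ["T", "A", "B"], {("T", "A"), ("T", "B"), ("A", "B")}
        ),
        "feedback": NetworkStructure(
            ["T", "A", "B"], {("T", "A"), ("A", "B"), ("B", "T")}
        ),
        "parallel_channel": NetworkStructure(
            ["T", "A", "B", "C"],
            {("T", "A"), ("T", "B"), ("A", "C"), ("B", "C")},
        ),
        "duplicate_parents": NetworkStructure(
            ["P1", "P2", "T", "S"],
            {("P1", "T"), ("P1", "S"), ("P2", "T"), ("P2", "S")},
        ),
        # target-relation cases
        "direct": NetworkStructure(["T", "A"], {("T", "A")}),
        "indirect": NetworkStructure(["T", "A", "B"], {("T", "A"), ("A", "B")}),
        "v_structure": NetworkStructure(["T", "Y", "Z"], {("T", "Z"), ("Y", "Z")}),
        "common_cause": NetworkStructure(["P", "T", "S"], {("P", "T"), ("P", "S")}),
    }


def random_cpts(
    structure: NetworkStructure,
    cardinalities: dict[str, int] | int = DEFAULT_CARDINALITY,
    concentration: float = 0.25,
    seed: int = 0,
) -> DiscreteBayesNet:
    """Attach random CPTs: each row ~ symmetric Dirichlet(concentration).

    Low concentration yields near-deterministic rows (strong dependencies and
    high edge MI); high concentration yields near-uniform rows (weak edges).
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if isinstance(cardinalities, int):
        cardinalities = {v: cardinalities for v in structure.nodes}
    rng = np.random.default_rng(seed)
    cpts: dict[str, np.ndarray] = {}
    for v in structure.nodes:
        r = cardinalities[v]
        pa = structure.parents(v)
        q = int(np.prod([cardinalities[p] for p in pa])) if pa else 1
        rows = rng.dirichlet(np.full(r, concentration), size=q)
        shape = tuple(cardinalities[p] for p in pa) + (r,)
        cpts[v] = rows.reshape(shape)
    return DiscreteBayesNet(structure.copy(), dict(cardinalities), cpts)


def discretize(matrix, bins: int = 3, method: str = "quantile") -> SampleMatrix:
    """Discretize a continuous sample-by-gene matrix column by column.

    ``quantile`` balances bin counts (within ±1 for distinct values); ``width``
    uses equal-width intervals over each column's range.  A constant column in
    quantile mode collapses to a single code with a warning.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if method not in ("quantile", "width"):
        raise ValueError(f"unknown method {method!r}")
    df = pd.DataFrame(matrix)
    var_names = [str(c) for c in df.columns]
    codes = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        x = df[col].to_numpy(dtype=float)
        if method == "quantile":
            if np.unique(x).size < 2:
                import warnings

                warnings.warn(
                    f"column {col!r} is constant: single-bin column", stacklevel=2
                )
                codes[:, j] = 0
                continue
            codes[:, j] = pd.qcut(x, bins, labels=False, duplicates="drop")
        else:
            codes[:, j] = pd.cut(x, bins, labels=False, include_lowest=True)
    return SampleMatrix(codes, var_names)
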
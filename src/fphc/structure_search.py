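"""BDeu-scored greedy hill climbing over DAGs, optionally restricted to
FPNS neighbor sets.

The score is the Bayesian Dirichlet equivalent uniform (BDeu) marginal
log-likelihood with equivalent sample size *ess* (default 1).  For child X_i
with r_i states and q_i parent configurations,

    score_i = sum_j [ lnG(a_j) - lnG(a_j + N_j) ]
            + sum_{j,k} [ lnG(a_jk + N_jk) - lnG(a_jk) ]

with a_jk = ess / (q_i r_i), a_j = ess / q_i, N_jk the count of (config j,
state k) and N_j its row sum; lnG is the log-gamma function.  The total score
decomposes as the sum of local scores, so move deltas touch at most two nodes.

The search starts from the empty graph and repeatedly applies the single best
add-edge / delete-edge / reverse-edge operator until no operator improves the
score by more than a small tolerance.  With a neighbor-set mask, add (and
hence reverse) operators are limited to masked pairs; the mask is undirected
because the selection phase cannot tell parents from children.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .bn_model import NetworkStructure, SampleMatrix, is_acyclic
from .fpns import NeighborSets

__all__ = [
    "BDeuScorer",
    "SearchResult",
    "bdeu_local",
    "total_score",
    "legal_moves",
    "hill_climb",
]

SCORE_TOL = 1e-9


class BDeuScorer:
    """Cached BDeu local scores for one dataset.

    Cardinalities are fixed per column up front (from state labels when the
    dataset carries them, otherwise from the observed codes, never below 2) so
    every parent set sees the same q_i and r_i.
    """

    def __init__(self, data: SampleMatrix, ess: float = 1.0):
        if ess <= 0:
            raise ValueError("ess must be positive")
        if data.n_samples < 1:
            raise ValueError("empty data")
        self.data = data
        self.ess = float(ess)
        self.cards: dict[str, int] = {}
        for j, v in enumerate(data.var_names):
            if data.state_labels and v in data.state_labels:
                card = len(data.state_labels[v])
            else:
                card = int(data.values[:, j].max()) + 1
            self.cards[v] = max(card, 2)
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def local(self, child: str, parents: frozenset[str] | set[str]) -> float:
        parents = frozenset(parents)
        if child in parents:
            raise ValueError(f"child {child!r} cannot be its own parent")
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        names = self.data.var_names
        for v in parents | {child}:
            if v not in names:
                raise KeyError(f"column {v!r} not in data")
        r = self.cards[child]
        pa = sorted(parents, key=names.index)
        q = 1
        for p in pa:
            q *= self.cards[p]
        a_jk = self.ess / (q * r)
        a_j = self.ess / q
        child_col = self.data.column(child)
        if pa:
            code = np.zeros(self.data.n_samples, dtype=np.int64)
            for p in pa:
                code = code * self.cards[p] + self.data.column(p)
        else:
            code = np.zeros(self.data.n_samples, dtype=np.int64)
        counts = np.zeros((q, r))
        np.add.at(counts, (code, child_col), 1.0)
        nj = counts.sum(axis=1)
        # unoccupied configurations contribute lnG(a)-lnG(a) = 0
        occ = nj > 0
        score = float(
            np.sum(gammaln(a_j) - gammaln(a_j + nj[occ]))
            + np.sum(gammaln(a_jk + counts[occ]) - gammaln(a_jk))
        )
        self._cache[key] = score
        return score

    def total(self, dag: NetworkStructure) -> float:
        if not is_acyclic(dag):
            raise ValueError("total score requires an acyclic graph")
        return sum(self.local(v, frozenset(dag.parents(v))) for v in dag.nodes)


def bdeu_local(
    data: SampleMatrix, child: str, parents: set[str], ess: float = 1.0
) -> float:
    """BDeu local log score of one child given a parent set (uncached wrapper)."""
    return BDeuScorer(data, ess).local(child, frozenset(parents))


def total_score(data: SampleMatrix, dag: NetworkStructure, ess: float = 1.0) -> float:
    """Decomposable network score: sum of BDeu local scores over all nodes."""
    return BDeuScorer(data, ess).total(dag)


@dataclass
class SearchResult:
    """Final DAG of a hill-climbing run plus its audit trail."""

    dag: NetworkStructure
    total_score: float
    move_trace: list[tuple[str, tuple[str, str], float]]
    iterations: int
    converged: bool = True


def _allowed_pairs(
    nodes: list[str], allowed: NeighborSets | set | None, rule: str
) -> set[frozenset[str]]:
    if allowed is None:
        return {frozenset(p) for p in itertools.combinations(nodes, 2)}
    if isinstance(allowed, NeighborSets):
        return allowed.symmetrize(rule)
    return {frozenset(p) for p in allowed}


def _creates_cycle(edges: set[tuple[str, str]], a: str, b: str) -> bool:
    """Would adding a->b to `edges` create a directed cycle (path b ~> a)?"""
    children: dict[str, list[str]] = {}
    for x, y in edges:
        children.setdefault(x, []).append(y)
    stack, seen = [b], set()
    while stack:
        v = stack.pop()
        if v == a:
            return True
        if v in seen:
            continue
        seen.add(v)
        stack.extend(children.get(v, []))
    return False


def legal_moves(
    dag: NetworkStructure,
    allowed: NeighborSets | set | None = None,
    rule: str = "union",
) -> list[tuple[str, str, str]]:
    """All legal (operator, from, to) moves on a DAG.

    Adds are limited to allowed, absent, acyclicity-preserving ordered pairs;
    deletes cover every existing edge; reversals require the flipped edge to
    keep the graph acyclic.  Output is in deterministic (operator, edge) order.
    """
    if not is_acyclic(dag):
        raise ValueError("moves are defined on acyclic graphs only")
    pairs = _allowed_pairs(dag.nodes, allowed, rule)
    adjacent = {frozenset(e) for e in dag.edges}
    moves: list[tuple[str, str, str]] = []
    for a, b in sorted(itertools.permutations(dag.nodes, 2)):
        if (
            frozenset((a, b)) in pairs
            and frozenset((a, b)) not in adjacent
            and not _creates_cycle(dag.edges, a, b)
        ):
            moves.append(("add", a, b))
    for a, b in sorted(dag.edges):
        moves.append(("delete", a, b))
    for a, b in sorted(dag.edges):
        if not _creates_cycle(dag.edges - {(a, b)}, b, a):
            moves.append(("reverse", a, b))
    return moves


def hill_climb(
    data: SampleMatrix,
    allowed: NeighborSets | set | None = None,
    ess: float = 1.0,
    max_iter: int = 10_000,
    rule: str = "union",
    tol: float = SCORE_TOL,
) -> SearchResult:
    """Greedy BDeu hill climbing from the empty graph.

    At each iteration every legal move is scored via local-score deltas and the
    best strictly-improving one (delta > ``tol``) is applied; ties go to the
    first move in (operator, edge) lexicographic order.  ``allowed=None`` is
    the unrestricted baseline (plain hill climbing).  Hitting ``max_iter``
    flags the result as non-converged instead of raising.
    """
    scorer = BDeuScorer(data, ess)
    nodes = list(data.var_names)
    dag = NetworkStructure(nodes, set())
    local = {v: scorer.local(v, frozenset()) for v in nodes}
    trace: list[tuple[str, tuple[str, str], float]] = []
    iterations = 0
    converged = False
    while iterations < max_iter:
        iterations += 1
        best: tuple[float, tuple[str, str, str]] | None = None
        for op, a, b in legal_moves(dag, allowed, rule):
            if op == "add":
                new_b = scorer.local(b, frozenset(dag.parents(b)) | {a})
                delta = new_b - local[b]
                changed = {b: new_b}
            elif op == "delete":
                new_b = scorer.local(b, frozenset(dag.parents(b)) - {a})
                delta = new_b - local[b]
                changed = {b: new_b}
            else:  # reverse a->b  =>  b->a
                new_b = scorer.local(b, frozenset(dag.parents(b)) - {a})
                new_a = scorer.local(a, frozenset(dag.parents(a)) | {b})
                delta = (new_b - local[b]) + (new_a - local[a])
                changed = {b: new_b, a: new_a}
            if delta > tol and (best is None or delta > best[0] + tol):
                best = (delta, (op, a, b), changed)  # type: ignore[assignment]
        if best is None:
            converged = True
            break
        delta, (op, a, b), changed = best  # type: ignore[misc]
        if op == "add":
            dag.edges.add((a, b))
        elif op == "delete":
            dag.edges.discard((a, b))
        else:
            dag.edges.discard((a, b))
            dag.edges.add((b, a))
        local.update(changed)
        trace.append((op, (a, b), float(delta)))
    return SearchResult(
        dag=dag,
        total_score=float(sum(local.values())),
        move_trace=trace,
        iterations=iterations,
        converged=converged,
    )
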
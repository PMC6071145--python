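"""Flooding-Pruning Neighbor Selection (FPNS).

For each target node T the algorithm selects a candidate neighbor set N_T in
two deterministic phases:

*Flooding* — the m = n-1 pairwise MI values between T and every other node are
sorted ascending; a single breakpoint is located by a Gaussian likelihood-ratio
scan (two segments, MLE mean/variance each, versus one segment), and every node
to the right of the breakpoint becomes a *related node* of T.  The intuition:
MI between T and nodes it cannot reach (d-separated by a collider, or in
another connected component) is pure estimation noise near zero, while related
nodes carry signal, so the sorted vector shows a change point.

*Pruning* — related nodes are ranked by the *DPI Level*: processing R_T in
descending MI order, the highest-MI node gets level 1, and each subsequent node
X_i gets ``1 + max(level of X_a)`` over the preceding nodes X_a that satisfy
the data processing inequality ``MI(T;X_i) <= min(MI(T;X_a), MI(X_a;X_i))``
(level 1 if none does).  Level counts DPI "hops", so direct neighbors sit at
level 1 on tree-like paths.  Nodes with level above the pruning depth θ are
cut.

The θ policy is either a fixed integer or the "mode" rule: the most frequent
DPI Level in R_T, but never below 2.

Everything here is deterministic: no RNG, and every sort and argmax has an
explicit tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bn_model import SampleMatrix
from .mi_core import MIMatrix, MIVector, mi_matrix

__all__ = [
    "BreakpointResult",
    "RelatedSet",
    "DPIRanking",
    "NeighborSets",
    "normal_segment_loglik",
    "q_statistic",
    "detect_breakpoint",
    "mi_vector",
    "flood",
    "related_all",
    "dpi_levels",
    "choose_theta",
    "prune",
    "fpns_from_mi",
    "fpns_all",
]

#: Variance floor for degenerate (constant or single-point) segments.
VARIANCE_FLOOR = 1e-12


@dataclass
class BreakpointResult:
    """Outcome of the breakpoint scan over an ascending MI vector."""

    k: int
    q_values: np.ndarray  # Q at each candidate position 1..m-1 (index i -> k=i+1)
    delta: tuple[float, float]  # whole-vector MLE (mean, variance)
    delta1: tuple[float, float]  # left-segment MLE at the chosen k
    delta2: tuple[float, float]  # right-segment MLE at the chosen k


@dataclass
class RelatedSet:
    """Related nodes R_T of a target, ordered by MI descending."""

    target: str
    members: list[str]
    mi_values: list[float]

    def __post_init__(self) -> None:
        if self.target in self.members:
            raise ValueError("target cannot be its own related node")
        if len(self.members) != len(self.mi_values):
            raise ValueError("members and MI values misaligned")
        if any(
            self.mi_values[i] < self.mi_values[i + 1] - 1e-12
            for i in range(len(self.mi_values) - 1)
        ):
            raise ValueError("related-set MI values must be non-increasing")


@dataclass
class DPIRanking:
    """DPI Level per related node, in R_T (descending-MI) order."""

    target: str
    levels: dict[str, int]

    def level_values(self) -> list[int]:
        return list(self.levels.values())


@dataclass
class NeighborSets:
    """Candidate neighbor set N_T per node, with the θ used and the policy name."""

    neighbors: dict[str, list[str]]
    theta_used: dict[str, int]
    policy: str
    failures: dict[str, str] = field(default_factory=dict)

    def nodes(self) -> list[str]:
        return list(self.neighbors)

    def symmetrize(self, rule: str = "union") -> set[frozenset[str]]:
        """Undirected allowed pairs.

        ``union``: pair {i, j} allowed if j ∈ N_i or i ∈ N_j (default; favors
        recall).  ``intersection``: allowed only if both directions agree.
        """
        if rule not in ("union", "intersection"):
            raise ValueError(f"unknown symmetrization rule {rule!r}")
        pairs: set[frozenset[str]] = set()
        for t, members in self.neighbors.items():
            for m in members:
                if rule == "union" or t in self.neighbors.get(m, []):
                    pairs.add(frozenset((t, m)))
        return pairs

    def to_json(self, path) -> None:
        obj = {
            "policy": self.policy,
            "theta_used": self.theta_used,
            "neighbors": self.neighbors,
            "failures": self.failures,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
            fh.write("\n")

    def to_edge_tsv(self, path, rule: str = "union") -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for pair in sorted(self.symmetrize(rule), key=sorted):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\n")


def normal_segment_loglik(values: np.ndarray) -> float:
    """Gaussian log-likelihood of a segment at its MLE mean and variance.

    The MLE variance is floored at 1e-12 so single-point and constant segments
    stay finite (and strongly favored, which is what lets a run of exact-zero
    MI values form its own segment).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty segment")
    mu = float(values.mean())
    var = max(float(values.var()), VARIANCE_FLOOR)
    n = values.size
    return float(
        -0.5 * n * np.log(2.0 * np.pi * var)
        - 0.5 * np.sum((values - mu) ** 2) / var
    )


def q_statistic(M: np.ndarray, k: int) -> float:
    """Likelihood-ratio statistic for a breakpoint after position ``k`` (1-based).

    ``Q = 2 [ (loglik of M[1:k]) + (loglik of M[k+1:m]) - (loglik of M) ]``;
    non-negative because the two-segment model nests the one-segment model.
    """
    M = np.asarray(M, dtype=float)
    m = M.size
    if not 1 <= k <= m - 1:
        raise ValueError(f"k={k} out of range [1, {m - 1}]")
    ml_k = normal_segment_loglik(M[:k]) + normal_segment_loglik(M[k:])
    return 2.0 * (ml_k - normal_segment_loglik(M))


def detect_breakpoint(M: np.ndarray) -> BreakpointResult:
    """Locate the breakpoint ``k = argmax Q`` over an ascending MI vector.

    The scan covers k ∈ [1, m-1] so the right segment (the related nodes) is
    never empty; ties go to the smallest k, which keeps the related set large.
    No significance threshold is applied — a breakpoint is always declared.
    """
    M = np.asarray(M, dtype=float)
    m = M.size
    if m < 3:
        raise ValueError(
            "breakpoint detection needs at least 3 values; with fewer nodes, "
            "treat all of them as related"
        )
    qs = np.array([q_statistic(M, k) for k in range(1, m)])
    k = int(np.argmax(qs)) + 1  # first maximum -> smallest k
    mle = lambda seg: (float(np.mean(seg)), max(float(np.var(seg)), VARIANCE_FLOOR))
    return BreakpointResult(
        k=k, q_values=qs, delta=mle(M), delta1=mle(M[:k]), delta2=mle(M[k:])
    )


def mi_vector(target: str, mi: MIMatrix, ascending: bool = True) -> MIVector:
    """MI of the target against every other variable, sorted with index tie-break."""
    names = mi.var_names
    if target not in names:
        raise KeyError(f"target {target!r} not in MI matrix")
    entries = [(v, mi.get(target, v)) for v in names if v != target]
    idx = {v: i for i, v in enumerate(names)}
    entries.sort(key=lambda e: (e[1], idx[e[0]]) if ascending else (-e[1], idx[e[0]]))
    return MIVector(target, entries, ascending=ascending)


def flood(target: str, mi: MIMatrix) -> RelatedSet:
    """Flooding phase: related nodes are those right of the MI breakpoint."""
    vec = mi_vector(target, mi, ascending=True)
    bp = detect_breakpoint(vec.values())
    related = vec.entries[bp.k :]
    idx = {v: i for i, v in enumerate(mi.var_names)}
    related.sort(key=lambda e: (-e[1], idx[e[0]]))
    return RelatedSet(target, [v for v, _ in related], [x for _, x in related])


def related_all(target: str, mi: MIMatrix) -> RelatedSet:
    """A RelatedSet containing every other node (no flooding cut).

    Equivalent to skipping breakpoint detection; useful for ranking diagnostics
    and for exercising the pruning phase on a full candidate set.
    """
    vec = mi_vector(target, mi, ascending=False)
    return RelatedSet(target, [v for v, _ in vec.entries], [x for _, x in vec.entries])


def dpi_levels(target: str, related: RelatedSet, mi: MIMatrix) -> DPIRanking:
    """Pruning-phase ranking: DPI Level of each related node.

    Members are processed in descending-MI order.  The first gets level 1; each
    later X_i is tested against every preceding X_a with the data processing
    inequality ``MI(T;X_i) <= min(MI(T;X_a), MI(X_a;X_i))`` (non-strict), and
    its level is 1 + the maximum level among satisfying X_a, or 1 if none.
    """
    if not related.members:
        raise ValueError("related set is empty")
    if related.target != target:
        raise ValueError("related set belongs to a different target")
    for v in [target] + related.members:
        if v not in mi.var_names:
            raise KeyError(f"node {v!r} missing from MI matrix")
    levels: dict[str, int] = {}
    for i, xi in enumerate(related.members):
        if i == 0:
            levels[xi] = 1
            continue
        mi_t_xi = related.mi_values[i]
        best = 0
        for a in range(i):
            xa = related.members[a]
            mi_t_xa = related.mi_values[a]
            if mi_t_xi <= min(mi_t_xa, mi.get(xa, xi)):
                best = max(best, levels[xa])
        levels[xi] = best + 1
    return DPIRanking(target, levels)


def choose_theta(ranking: DPIRanking, policy: int | str = "mode") -> int:
    """Pruning depth θ from a ranking under a fixed-θ or mode policy.

    ``mode``: the most frequent DPI Level in R_T (ties to the smallest level),
    floored at 2.  An integer policy is passed through unchanged (must be ≥ 1).
    """
    if isinstance(policy, int) and not isinstance(policy, bool):
        if policy < 1:
            raise ValueError("fixed θ must be >= 1")
        return policy
    if policy != "mode":
        raise ValueError(f"unknown θ policy {policy!r}")
    values = ranking.level_values()
    if not values:
        import warnings

        warnings.warn("empty DPI ranking: falling back to θ = 2", stacklevel=2)
        return 2
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    mode = min(level for level, c in counts.items() if c == best)
    return max(mode, 2)


def prune(related: RelatedSet, ranking: DPIRanking, theta: int) -> list[str]:
    """Keep related nodes with DPI Level ≤ θ, in descending-MI order."""
    if theta < 1:
        raise ValueError("θ must be >= 1")
    return [v for v in related.members if ranking.levels[v] <= theta]


def fpns_from_mi(mi: MIMatrix, policy: int | str = "mode") -> NeighborSets:
    """Run flood → DPI ranking → θ selection → prune for every node of an MI matrix.

    Deterministic for a fixed matrix.  Per-node failures (e.g. too few nodes for
    the breakpoint scan) are recorded in ``failures`` rather than raised.
    """
    neighbors: dict[str, list[str]] = {}
    theta_used: dict[str, int] = {}
    failures: dict[str, str] = {}
    for target in mi.var_names:
        try:
            related = flood(target, mi)
            ranking = dpi_levels(target, related, mi)
            theta = choose_theta(ranking, policy)
            neighbors[target] = prune(related, ranking, theta)
            theta_used[target] = theta
        except (ValueError, KeyError) as exc:
            neighbors[target] = []
            failures[target] = str(exc)
    return NeighborSets(neighbors, theta_used, str(policy), failures)


def fpns_all(data: SampleMatrix, policy: int | str = "mode") -> NeighborSets:
    """FPNS on a discrete dataset: estimate the MI matrix, then select neighbors."""
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if data.n_vars < 4:
        raise ValueError("need at least 4 variables for breakpoint detection")
    return fpns_from_mi(mi_matrix(data), policy)
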
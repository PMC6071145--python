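"""Evaluation metrics for learned networks.

Neighbor selection is scored as binary classification over the n(n-1)/2
unordered node pairs (sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)).
Learned structures are scored with the edge F-score, the structural Hamming
distance (SHD) between the completed PDAGs of the two networks, and the
undirected SHD (USHD) between their skeletons.  Comparing CPDAGs rather than
DAGs avoids penalizing orientation differences inside a Markov equivalence
class: compelled edges stay directed, reversible edges become undirected
(v-structure orientation followed by Meek-rule closure).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict

from .bn_model import NetworkStructure, is_acyclic
from .fpns import NeighborSets

__all__ = [
    "ConfusionCounts",
    "PartiallyDirectedGraph",
    "EvalReport",
    "neighbor_confusion",
    "dag_to_cpdag",
    "shd",
    "ushd",
    "edge_fscore",
    "evaluate_structure",
    "mean_report",
]


@dataclass
class ConfusionCounts:
    """Unordered-pair confusion counts for neighbor selection."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 1.0


@dataclass
class PartiallyDirectedGraph:
    """Mixed graph: directed edges (ordered pairs) plus undirected edges."""

    nodes: list[str]
    directed: set[tuple[str, str]]
    undirected: set[frozenset[str]]

    def __post_init__(self) -> None:
        for a, b in self.directed:
            if frozenset((a, b)) in self.undirected:
                raise ValueError(f"pair {{{a}, {b}}} is both directed and undirected")
            if a == b:
                raise ValueError("self-loop")
        for pair in self.undirected:
            if len(pair) != 2:
                raise ValueError("undirected edge must join two distinct nodes")

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.directed} | set(self.undirected)


@dataclass
class EvalReport:
    """One row of structure-learning metrics; optionally normalized."""

    sensitivity: float
    specificity: float
    f_score: float
    shd: int
    ushd: int
    baseline: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
            fh.write("\n")

    def csv_row(self) -> str:
        return (
            f"{self.sensitivity:.6f},{self.specificity:.6f},"
            f"{self.f_score:.6f},{self.shd},{self.ushd}"
        )


def neighbor_confusion(
    predicted: NeighborSets, truth: NetworkStructure, rule: str = "union"
) -> ConfusionCounts:
    """Confusion counts of predicted neighbor pairs against the true skeleton."""
    if set(predicted.nodes()) != set(truth.nodes):
        raise ValueError("predicted neighbor sets and truth cover different nodes")
    pred = predicted.symmetrize(rule)
    true = truth.skeleton()
    tp = fp = tn = fn = 0
    for pair in itertools.combinations(truth.nodes, 2):
        p = frozenset(pair)
        if p in pred and p in true:
            tp += 1
        elif p in pred:
            fp += 1
        elif p in true:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _v_structures(dag: NetworkStructure) -> set[tuple[str, str, str]]:
    """Colliders a->z<-b with a, b non-adjacent, as (min(a,b), max(a,b), z)."""
    skel = dag.skeleton()
    out = set()
    for z in dag.nodes:
        pa = dag.parents(z)
        for a, b in itertools.combinations(pa, 2):
            if frozenset((a, b)) not in skel:
                x, y = sorted((a, b))
                out.add((x, y, z))
    return out


def dag_to_cpdag(dag: NetworkStructure) -> PartiallyDirectedGraph:
    """Completed PDAG of a DAG's Markov equivalence class.

    V-structure edges start directed and the Meek rules are applied to closure;
    all remaining skeleton edges are reversible and stay undirected.
    """
    if not is_acyclic(dag):
        raise ValueError("input must be a DAG")
    skel = dag.skeleton()
    directed: set[tuple[str, str]] = set()
    for a, b, z in _v_structures(dag):
        directed.add((a, z))
        directed.add((b, z))
    # orientations must agree with the DAG by construction; Meek closure:
    undirected = {p for p in skel if not any(frozenset(e) == p for e in directed)}

    def adjacent(x: str, y: str) -> bool:
        return frozenset((x, y)) in skel

    changed = True
    while changed:
        changed = False
        for pair in list(undirected):
            a, b = sorted(pair)
            for x, y in ((a, b), (b, a)):
                # R1: w -> x, x - y, w and y non-adjacent  =>  x -> y
                if any(
                    (w, x) in directed and not adjacent(w, y)
                    for w in dag.nodes
                    if w not in (x, y)
                ):
                    directed.add((x, y))
                    undirected.discard(pair)
                    changed = True
                    break
                # R2: x -> w -> y with x - y  =>  x -> y
                if any(
                    (x, w) in directed and (w, y) in directed
                    for w in dag.nodes
                    if w not in (x, y)
                ):
                    directed.add((x, y))
                    undirected.discard(pair)
                    changed = True
                    break
                # R3: x - c, x - d, c -> y, d -> y, c and d non-adjacent => x -> y
                half = [
                    w
                    for w in dag.nodes
                    if w not in (x, y)
                    and frozenset((x, w)) in undirected
                    and (w, y) in directed
                ]
                if any(
                    not adjacent(c, d) for c, d in itertools.combinations(half, 2)
                ):
                    directed.add((x, y))
                    undirected.discard(pair)
                    changed = True
                    break
            if changed:
                break
    return PartiallyDirectedGraph(list(dag.nodes), directed, undirected)


def _pair_kind(
    pdag: PartiallyDirectedGraph, a: str, b: str
) -> str | None:
    """'>' a->b, '<' b->a, '-' undirected, None absent."""
    if (a, b) in pdag.directed:
        return ">"
    if (b, a) in pdag.directed:
        return "<"
    if frozenset((a, b)) in pdag.undirected:
        return "-"
    return None


def shd(learned: NetworkStructure, truth: NetworkStructure) -> int:
    """Structural Hamming distance between the two networks' CPDAGs.

    One unit per unordered pair whose adjacency, orientation status, or
    direction differs.
    """
    if set(learned.nodes) != set(truth.nodes):
        raise ValueError("graphs cover different node sets")
    pl = dag_to_cpdag(learned)
    pt = dag_to_cpdag(truth)
    dist = 0
    for a, b in itertools.combinations(sorted(truth.nodes), 2):
        if _pair_kind(pl, a, b) != _pair_kind(pt, a, b):
            dist += 1
    return dist


def ushd(learned: NetworkStructure, truth: NetworkStructure) -> int:
    """Undirected SHD: size of the symmetric difference of the two skeletons."""
    if set(learned.nodes) != set(truth.nodes):
        raise ValueError("graphs cover different node sets")
    return len(learned.skeleton() ^ truth.skeleton())


def edge_fscore(
    learned: NetworkStructure, truth: NetworkStructure, mode: str = "skeleton"
) -> tuple[float, float, float]:
    """(F-score, precision, recall) over edges.

    ``skeleton`` compares unordered adjacencies; ``directed`` compares ordered
    edges.  F = 2PR/(P+R), defined as 0 when P + R = 0.
    """
    if set(learned.nodes) != set(truth.nodes):
        raise ValueError("graphs cover different node sets")
    if mode == "skeleton":
        pred, true = learned.skeleton(), truth.skeleton()
    elif mode == "directed":
        pred, true = set(learned.edges), set(truth.edges)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    tp = len(pred & true)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(true) if true else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return f, precision, recall


def evaluate_structure(
    learned: NetworkStructure,
    truth: NetworkStructure,
    predicted_neighbors: NeighborSets | None = None,
    baseline: "EvalReport | None" = None,
) -> EvalReport:
    """Full metric row for a learned network against the gold standard.

    Neighbor sensitivity/specificity come from ``predicted_neighbors`` when
    given, otherwise from the learned skeleton itself.  When a plain-HC
    ``baseline`` report is supplied, normalized ratios (metric / baseline
    metric) are attached.
    """
    if predicted_neighbors is not None:
        conf = neighbor_confusion(predicted_neighbors, truth)
    else:
        as_sets = NeighborSets(
            {v: learned.children(v) + learned.parents(v) for v in learned.nodes},
            {},
            "learned-skeleton",
        )
        conf = neighbor_confusion(as_sets, truth)
    f, _, _ = edge_fscore(learned, truth)
    report = EvalReport(
        sensitivity=conf.sensitivity,
        specificity=conf.specificity,
        f_score=f,
        shd=shd(learned, truth),
        ushd=ushd(learned, truth),
    )
    if baseline is not None:
        report.baseline = {
            "f_score_ratio": report.f_score / baseline.f_score
            if baseline.f_score
            else float("inf"),
            "shd_ratio": report.shd / baseline.shd if baseline.shd else float("inf"),
            "ushd_ratio": report.ushd / baseline.ushd
            if baseline.ushd
            else float("inf"),
        }
    return report


def mean_report(reports: list[EvalReport]) -> dict[str, float]:
    """Replicate-mean of each metric (the paper-style 10-dataset average)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    keys = ["sensitivity", "specificity", "f_score", "shd", "ushd"]
    return {k: sum(getattr(r, k) for r in reports) / len(reports) for k in keys}
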
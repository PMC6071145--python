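"""Discrete Bayesian network model: structure, CPTs, exact joint, sampling, I/O.

A Bayesian network over variables ``V = {X_1, ..., X_n}`` is a DAG ``G = (V, E)``
together with one conditional probability table (CPT) per node giving
``P(X_i | Pa(X_i))``.  The joint distribution factorizes as

    P(x_1, ..., x_n) = prod_i P(x_i | pa_i)

This module provides the network containers, an exact-joint-distribution oracle
(for small state spaces), ancestral forward sampling, and file I/O in a native
JSON format plus a read/write subset of the BIF 0.15 dialect.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NetworkStructure",
    "DiscreteBayesNet",
    "SampleMatrix",
    "is_acyclic",
    "topological_order",
    "exact_joint",
    "forward_sample",
    "read_network",
    "write_network",
    "StructureError",
    "NetworkParseError",
]

#: Default cap on the number of entries in an exact joint table.
DEFAULT_STATE_SPACE_CAP = 2**20


class StructureError(ValueError):
    """Raised for invalid graph structures (unknown nodes, cycles, self-loops)."""


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed under the declared dialect."""


@dataclass
class NetworkStructure:
    """A directed graph over named variables.

    ``nodes`` is an ordered list of variable names; ``edges`` is a set of
    ordered pairs ``(parent, child)``.  Acyclicity is *checked*, not assumed:
    cyclic objects may exist (e.g. the feedback motif used to demonstrate cycle
    detection) but are rejected by every operation that requires a DAG.
    """

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise StructureError("duplicate node names")
        self.edges = {(str(a), str(b)) for a, b in self.edges}
        known = set(self.nodes)
        for a, b in self.edges:
            if a not in known or b not in known:
                raise StructureError(f"edge ({a}, {b}) references unknown node")
            if a == b:
                raise StructureError(f"self-loop on node {a}")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def parents(self, node: str) -> list[str]:
        """Pa(node), in node order."""
        if node not in set(self.nodes):
            raise StructureError(f"unknown node {node!r}")
        ps = {a for a, b in self.edges if b == node}
        return [v for v in self.nodes if v in ps]

    def children(self, node: str) -> list[str]:
        cs = {b for a, b in self.edges if a == node}
        return [v for v in self.nodes if v in cs]

    def skeleton(self) -> set[frozenset[str]]:
        """Undirected adjacency as a set of unordered pairs."""
        return {frozenset(e) for e in self.edges}

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(list(self.nodes), set(self.edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkStructure):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


def is_acyclic(structure: NetworkStructure) -> bool:
    """True iff the directed graph has no cycle (Kahn's algorithm)."""
    indeg = {v: 0 for v in structure.nodes}
    children: dict[str, list[str]] = {v: [] for v in structure.nodes}
    for a, b in structure.edges:
        indeg[b] += 1
        children[a].append(b)
    queue = [v for v in structure.nodes if indeg[v] == 0]
    seen = 0
    while queue:
        v = queue.pop()
        seen += 1
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen == len(structure.nodes)


def topological_order(structure: NetworkStructure) -> list[str]:
    """A topological order of the DAG, stable w.r.t. node order.

    Raises :class:`StructureError` on cyclic input.
    """
    indeg = {v: 0 for v in structure.nodes}
    for _, b in structure.edges:
        indeg[b] += 1
    order: list[str] = []
    remaining = list(structure.nodes)
    while remaining:
        head = next((v for v in remaining if indeg[v] == 0), None)
        if head is None:
            raise StructureError("graph contains a directed cycle")
        order.append(head)
        remaining.remove(head)
        for c in (b for a, b in structure.edges if a == head):
            indeg[c] -= 1
    return order


@dataclass
class DiscreteBayesNet:
    """A :class:`NetworkStructure` plus per-node cardinalities and CPTs.

    ``cpts[node]`` is an ndarray of shape ``(card(pa_1), ..., card(pa_k),
    card(node))`` with parents ordered by node order; each row (last axis) is a
    probability vector.  ``state_labels`` maps each node to its category names.
    """

    structure: NetworkStructure
    cardinalities: dict[str, int]
    cpts: dict[str, np.ndarray]
    state_labels: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if not is_acyclic(self.structure):
            raise StructureError("Bayesian network structure must be acyclic")
        if self.state_labels is None:
            self.state_labels = {
                v: [str(s) for s in range(self.cardinalities[v])]
                for v in self.structure.nodes
            }
        for v in self.structure.nodes:
            r = self.cardinalities[v]
            if r < 2:
                raise ValueError(f"node {v!r}: cardinality must be >= 2, got {r}")
            pa = self.structure.parents(v)
            expected = tuple(self.cardinalities[p] for p in pa) + (r,)
            cpt = np.asarray(self.cpts[v], dtype=float)
            if cpt.shape != expected:
                raise ValueError(
                    f"node {v!r}: CPT shape {cpt.shape} != expected {expected}"
                )
            rows = cpt.reshape(-1, r)
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12, rtol=0):
                raise ValueError(f"node {v!r}: CPT rows must sum to 1 within 1e-12")
            if (rows < 0).any():
                raise ValueError(f"node {v!r}: CPT entries must be non-negative")
            self.cpts[v] = cpt

    @property
    def nodes(self) -> list[str]:
        return self.structure.nodes

    def state_space_size(self) -> int:
        size = 1
        for v in self.structure.nodes:
            size *= self.cardinalities[v]
        return size


@dataclass
class SampleMatrix:
    """A discrete dataset D: ``n_samples x n_vars`` integer-coded categories."""

    values: np.ndarray
    var_names: list[str]
    state_labels: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x variables)")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one sample")
        if self.values.shape[1] != len(self.var_names):
            raise ValueError("column count does not match var_names")
        if (self.values < 0).any():
            raise ValueError("state codes must be non-negative")
        if self.state_labels is not None:
            for j, v in enumerate(self.var_names):
                labels = self.state_labels.get(v)
                if labels is not None and self.values[:, j].max() >= len(labels):
                    raise ValueError(f"column {v!r} has a state code outside its labels")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.var_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.var_names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=np.int64), [str(c) for c in df.columns])


def exact_joint(
    bn: DiscreteBayesNet, cap: int = DEFAULT_STATE_SPACE_CAP
) -> np.ndarray:
    """Full joint probability table, shape ``(card_1, ..., card_n)`` in node order.

    Entry ``[x_1, ..., x_n] = prod_i P(x_i | pa_i)``.  Refuses state spaces
    larger than ``cap`` entries.
    """
    size = bn.state_space_size()
    if size > cap:
        raise ValueError(
            f"state space has {size} entries, above the cap of {cap}; "
            "exact joint enumeration refused"
        )
    nodes = bn.structure.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    shape = tuple(bn.cardinalities[v] for v in nodes)
    joint = np.ones(shape)
    for v in nodes:
        pa = bn.structure.parents(v)
        axes = [idx[p] for p in pa] + [idx[v]]
        # transpose CPT axes into node order, then broadcast over the rest
        order = np.argsort(axes)
        cpt = np.transpose(bn.cpts[v], order)
        full = [1] * len(nodes)
        for ax in axes:
            full[ax] = shape[ax]
        joint = joint * cpt.reshape(full)
    total = joint.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"joint table sums to {total}, not 1")
    return joint


def forward_sample(bn: DiscreteBayesNet, n_samples: int, seed: int) -> SampleMatrix:
    """Ancestral sampling: draw each node given its sampled parents.

    Nodes are visited in topological order with a single RNG stream, so a given
    ``(bn, n_samples, seed)`` always yields a bit-identical matrix.  Columns
    appear in the network's node order.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    order = topological_order(bn.structure)
    nodes = bn.structure.nodes
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for v in order:
        pa = bn.structure.parents(v)
        cpt = bn.cpts[v]
        r = bn.cardinalities[v]
        if pa:
            # row index per sample from already-sampled parent columns
            flat = cpt.reshape(-1, r)
            pa_cards = [bn.cardinalities[p] for p in pa]
            code = np.zeros(n_samples, dtype=np.int64)
            for p, c in zip(pa, pa_cards):
                code = code * c + cols[p]
            probs = flat[code]
        else:
            probs = np.broadcast_to(cpt, (n_samples, r))
        u = rng.random(n_samples)
        cols[v] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1).astype(np.int64)
        # guard against u landing beyond cumulative rounding
        np.clip(cols[v], 0, r - 1, out=cols[v])
    values = np.column_stack([cols[v] for v in nodes])
    return SampleMatrix(values, list(nodes), dict(bn.state_labels or {}))


# ---------------------------------------------------------------------------
# I/O: native JSON and a BIF 0.15 subset
# ---------------------------------------------------------------------------

def _bn_to_dict(bn: DiscreteBayesNet) -> dict:
    nodes = bn.structure.nodes
    out = {
        "nodes": nodes,
        "cardinalities": {v: int(bn.cardinalities[v]) for v in nodes},
        "states": {v: list(bn.state_labels[v]) for v in nodes},
        "edges": sorted([list(e) for e in bn.structure.edges]),
        "cpts": {},
    }
    for v in nodes:
        out["cpts"][v] = {
            "parents": bn.structure.parents(v),
            "table": bn.cpts[v].reshape(-1, bn.cardinalities[v]).tolist(),
        }
    return out


def _bn_from_dict(obj: dict) -> DiscreteBayesNet:
    try:
        nodes = [str(v) for v in obj["nodes"]]
        cards = {str(k): int(v) for k, v in obj["cardinalities"].items()}
        edges = {(str(a), str(b)) for a, b in obj["edges"]}
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkParseError(f"malformed network JSON: {exc}") from exc
    structure = NetworkStructure(nodes, edges)
    if not is_acyclic(structure):
        raise StructureError("network JSON defines a cyclic structure")
    cpts: dict[str, np.ndarray] = {}
    for v in nodes:
        entry = obj["cpts"].get(v)
        if entry is None:
            raise NetworkParseError(f"missing CPT for node {v!r}")
        pa = structure.parents(v)
        if list(entry.get("parents", [])) != pa:
            raise NetworkParseError(
                f"CPT parent list for {v!r} does not match edges (expected {pa})"
            )
        table = np.asarray(entry["table"], dtype=float)
        shape = tuple(cards[p] for p in pa) + (cards[v],)
        try:
            cpts[v] = table.reshape(shape)
        except ValueError as exc:
            raise NetworkParseError(f"CPT for {v!r} has wrong size") from exc
    labels = obj.get("states")
    state_labels = {v: [str(s) for s in labels[v]] for v in nodes} if labels else None
    return DiscreteBayesNet(structure, cards, cpts, state_labels)


_BIF_VAR_RE = re.compile(
    r"variable\s+(\S+)\s*\{\s*type\s+discrete\s*\[\s*(\d+)\s*\]\s*\{([^}]*)\}\s*;\s*\}",
)
_BIF_PROB_RE = re.compile(r"probability\s*\(\s*([^)]*)\)\s*\{([^}]*)\}", re.S)


def _parse_bif(text: str) -> DiscreteBayesNet:
    """Parse the supported BIF 0.15 subset.

    Supported: ``network``, ``variable`` blocks with discrete types, and
    ``probability`` blocks using either ``table`` lines (root nodes) or one
    ``(state, ...)`` row per parent configuration.  Variables must be declared
    before use.
    """
    text = re.sub(r"//[^\n]*", "", text)
    nodes: list[str] = []
    cards: dict[str, int] = {}
    labels: dict[str, list[str]] = {}
    declared_at: dict[str, int] = {}
    for m in _BIF_VAR_RE.finditer(text):
        name, card, states = m.group(1), int(m.group(2)), m.group(3)
        state_list = [s.strip() for s in states.split(",") if s.strip()]
        if len(state_list) != card:
            raise NetworkParseError(
                f"variable {name!r}: declared {card} states, listed {len(state_list)}"
            )
        nodes.append(name)
        cards[name] = card
        labels[name] = state_list
        declared_at[name] = m.start()

    edges: set[tuple[str, str]] = set()
    raw_cpts: dict[str, np.ndarray] = {}
    parents_of: dict[str, list[str]] = {}
    for m in _BIF_PROB_RE.finditer(text):
        head, body = m.group(1), m.group(2)
        parts = [p.strip() for p in head.split("|")]
        child = parts[0].strip()
        pa = (
            [p.strip() for p in parts[1].split(",") if p.strip()]
            if len(parts) > 1
            else []
        )
        line_no = text[: m.start()].count("\n") + 1
        for v in [child] + pa:
            if v not in cards:
                raise NetworkParseError(
                    f"line {line_no}: variable {v!r} used before declaration"
                )
            if v != child and declared_at[v] > m.start():
                raise NetworkParseError(
                    f"line {line_no}: variable {v!r} used before declaration"
                )
        if declared_at[child] > m.start():
            raise NetworkParseError(
                f"line {line_no}: variable {child!r} used before declaration"
            )
        for p in pa:
            edges.add((p, child))
        parents_of[child] = pa
        r = cards[child]
        if not pa:
            tm = re.search(r"table\s+([^;]+);", body)
            if tm is None:
                raise NetworkParseError(
                    f"line {line_no}: root node {child!r} needs a 'table' row"
                )
            row = np.array([float(x) for x in tm.group(1).split(",")])
            if row.size != r:
                raise NetworkParseError(
                    f"line {line_no}: table for {child!r} has {row.size} values, "
                    f"expected {r}"
                )
            raw_cpts[child] = row
        else:
            rows: dict[tuple[int, ...], np.ndarray] = {}
            for rm in re.finditer(r"\(([^)]*)\)\s*([^;]+);", body):
                states = [s.strip() for s in rm.group(1).split(",")]
                if len(states) != len(pa):
                    raise NetworkParseError(
                        f"line {line_no}: configuration {rm.group(1)!r} arity "
                        f"mismatch for {child!r}"
                    )
                try:
                    config = tuple(
                        labels[p].index(s) for p, s in zip(pa, states)
                    )
                except ValueError as exc:
                    raise NetworkParseError(
                        f"line {line_no}: unknown parent state in {rm.group(1)!r}"
                    ) from exc
                row = np.array([float(x) for x in rm.group(2).split(",")])
                if row.size != r:
                    raise NetworkParseError(
                        f"line {line_no}: row for {child!r} has {row.size} values"
                    )
                rows[config] = row
            shape = tuple(cards[p] for p in pa) + (r,)
            cpt = np.full(shape, np.nan)
            for config, row in rows.items():
                cpt[config] = row
            if np.isnan(cpt).any():
                raise NetworkParseError(
                    f"line {line_no}: CPT for {child!r} is missing parent "
                    "configurations"
                )
            # reorder parent axes into node order
            order_pa = [v for v in nodes if v in pa]
            perm = [pa.index(p) for p in order_pa] + [len(pa)]
            raw_cpts[child] = np.transpose(cpt, perm)
            parents_of[child] = order_pa

    missing = [v for v in nodes if v not in raw_cpts]
    if missing:
        raise NetworkParseError(f"no probability block for: {missing}")
    structure = NetworkStructure(nodes, edges)
    if not is_acyclic(structure):
        raise StructureError("BIF file defines a cyclic structure")
    cpts = {}
    for v in nodes:
        pa = structure.parents(v)
        shape = tuple(cards[p] for p in pa) + (cards[v],)
        cpts[v] = np.asarray(raw_cpts[v], dtype=float).reshape(shape)
    return DiscreteBayesNet(structure, cards, cpts, labels)


def _write_bif(bn: DiscreteBayesNet, path) -> None:
    lines = ["network unnamed {", "}"]
    for v in bn.structure.nodes:
        states = ", ".join(bn.state_labels[v])
        lines.append(
            f"variable {v} {{\n  type discrete [ {bn.cardinalities[v]} ] "
            f"{{ {states} }};\n}}"
        )
    for v in bn.structure.nodes:
        pa = bn.structure.parents(v)
        if not pa:
            row = ", ".join(f"{x:.12g}" for x in bn.cpts[v])
            lines.append(f"probability ( {v} ) {{\n  table {row};\n}}")
        else:
            head = f"probability ( {v} | {', '.join(pa)} ) {{"
            body = []
            pa_cards = [bn.cardinalities[p] for p in pa]
            for config in itertools.product(*[range(c) for c in pa_cards]):
                states = ", ".join(
                    bn.state_labels[p][s] for p, s in zip(pa, config)
                )
                row = ", ".join(f"{x:.12g}" for x in bn.cpts[v][config])
                body.append(f"  ({states}) {row};")
            lines.append(head + "\n" + "\n".join(body) + "\n}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_network(path, format: str = "json") -> DiscreteBayesNet:
    """Read a network from ``path`` in ``json`` (native) or ``bif`` format."""
    if format in ("json",):
        with open(path) as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise NetworkParseError(f"invalid JSON in {path}: {exc}") from exc
        return _bn_from_dict(obj)
    if format in ("bif", "bif-subset"):
        with open(path) as fh:
            return _parse_bif(fh.read())
    raise ValueError(f"unknown network format {format!r}")


def write_network(bn: DiscreteBayesNet, path, format: str = "json") -> None:
    """Write a network to ``path`` in ``json`` (native) or ``bif`` format."""
    if format in ("json",):
        with open(path, "w") as fh:
            json.dump(_bn_to_dict(bn), fh, indent=1)
            fh.write("\n")
        return
    if format in ("bif", "bif-subset"):
        _write_bif(bn, path)
        return
    raise ValueError(f"unknown network format {format!r}")
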
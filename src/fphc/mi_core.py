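"""Mutual information on discrete data, plus an exact-MI oracle.

MI between two discrete variables X, Y is

    MI(X;Y) = sum_{x,y} p(x,y) * log( p(x,y) / (p(x) p(y)) )

computed here as the maximum-likelihood plug-in estimate from empirical cell
frequencies (zero cells contribute nothing).  Natural logarithms are used
throughout, so all MI values are in nats; downstream only the ordering of MI
values matters, but a single base keeps segment likelihoods consistent.

The exact oracle computes the same quantity from the pairwise marginal of a
known network's enumerated joint distribution — the "MI estimated with no
errors" regime used by the identifiability results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bn_model import DiscreteBayesNet, SampleMatrix, exact_joint

__all__ = [
    "MIMatrix",
    "MIVector",
    "empirical_mi",
    "mi_matrix",
    "exact_mi",
    "exact_mi_matrix",
    "miller_madow_correction",
]

_NEG_TOL = 1e-12


@dataclass
class MIMatrix:
    """Symmetric matrix of pairwise MI values (nats); diagonal unused."""

    values: np.ndarray
    var_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.var_names)
        if self.values.shape != (n, n):
            raise ValueError("MI matrix shape does not match variable names")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("MI matrix must be symmetric within 1e-12")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and off.min() < -_NEG_TOL:
            raise ValueError("MI values must be >= 0 (within numeric floor)")

    def get(self, a: str, b: str) -> float:
        i, j = self.var_names.index(a), self.var_names.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.var_names, columns=self.var_names).to_csv(
            path, sep="\t"
        )


@dataclass
class MIVector:
    """MI of one target against every other variable (m = n - 1 entries)."""

    target: str
    entries: list[tuple[str, float]]
    ascending: bool = True

    def __post_init__(self) -> None:
        names = [v for v, _ in self.entries]
        if self.target in names:
            raise ValueError("MI vector must not contain the target itself")
        if len(set(names)) != len(names):
            raise ValueError("duplicate entries in MI vector")

    @property
    def m(self) -> int:
        return len(self.entries)

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries])


def _joint_counts(col_x: np.ndarray, col_y: np.ndarray) -> np.ndarray:
    rx = int(col_x.max()) + 1
    ry = int(col_y.max()) + 1
    counts = np.zeros((rx, ry))
    np.add.at(counts, (col_x, col_y), 1.0)
    return counts


def _mi_from_joint(pxy: np.ndarray) -> float:
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    terms = pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])
    # summing in sorted order makes the result invariant to argument order
    mi = float(np.sort(terms).sum())
    if mi < -_NEG_TOL:
        raise AssertionError(f"MI evaluated to {mi} < 0")
    return max(mi, 0.0)


def miller_madow_correction(counts: np.ndarray, n: int) -> float:
    """Additive Miller–Madow bias correction term for plug-in MI.

    ``(K_xy - K_x - K_y + 1) / (2n)`` with K the occupied-cell counts.
    Off by default everywhere; provided for sensitivity analyses only.
    """
    kxy = int((counts > 0).sum())
    kx = int((counts.sum(axis=1) > 0).sum())
    ky = int((counts.sum(axis=0) > 0).sum())
    return (kxy - kx - ky + 1) / (2.0 * n)


def empirical_mi(
    col_x: np.ndarray, col_y: np.ndarray, bias_correction: bool = False
) -> float:
    """Plug-in MI estimate (nats) between two integer-coded columns."""
    col_x = np.asarray(col_x)
    col_y = np.asarray(col_y)
    if col_x.ndim != 1 or col_y.ndim != 1:
        raise ValueError("inputs must be 1-D")
    if col_x.size == 0:
        raise ValueError("empty input")
    if col_x.size != col_y.size:
        raise ValueError(f"length mismatch: {col_x.size} vs {col_y.size}")
    counts = _joint_counts(col_x.astype(np.int64), col_y.astype(np.int64))
    n = col_x.size
    mi = _mi_from_joint(counts / n)
    if bias_correction:
        mi = max(mi + miller_madow_correction(counts, n), 0.0)
    return mi


def mi_matrix(data: SampleMatrix, bias_correction: bool = False) -> MIMatrix:
    """All pairwise plug-in MI values of a dataset."""
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate MI")
    if data.n_vars < 2:
        raise ValueError("need at least 2 variables to form pairs")
    n = data.n_vars
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi = empirical_mi(
                data.values[:, i], data.values[:, j], bias_correction=bias_correction
            )
            out[i, j] = out[j, i] = mi
    return MIMatrix(out, list(data.var_names))


def exact_mi(bn: DiscreteBayesNet, i: str, j: str, cap: int | None = None) -> float:
    """Exact MI (nats) between two nodes from the enumerated joint distribution."""
    kwargs = {} if cap is None else {"cap": cap}
    joint = exact_joint(bn, **kwargs)
    nodes = bn.structure.nodes
    ii, jj = nodes.index(i), nodes.index(j)
    if ii == jj:
        # MI of a node with itself is its entropy
        p = joint.sum(axis=tuple(k for k in range(len(nodes)) if k != ii))
        mask = p > 0
        return float(-(p[mask] * np.log(p[mask])).sum())
    axes = tuple(k for k in range(len(nodes)) if k not in (ii, jj))
    pxy = joint.sum(axis=axes)
    if ii > jj:
        pxy = pxy.T
    return _mi_from_joint(pxy)


def exact_mi_matrix(bn: DiscreteBayesNet, cap: int | None = None) -> MIMatrix:
    """Pairwise exact MI for every node pair of a (small) network.

    Enumerates the joint once and marginalizes per pair.
    """
    kwargs = {} if cap is None else {"cap": cap}
    joint = exact_joint(bn, **kwargs)
    nodes = bn.structure.nodes
    n = len(nodes)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            axes = tuple(k for k in range(n) if k not in (i, j))
            out[i, j] = out[j, i] = _mi_from_joint(joint.sum(axis=axes))
    return MIMatrix(out, list(nodes))
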
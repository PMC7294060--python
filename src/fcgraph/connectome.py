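"""Connectivity matrices and proportional density thresholding.

Edges are Pearson correlations between node BOLD series over the kept
volumes; the diagonal is set to zero and no Fisher transform is applied.
Proportional thresholding retains the same, predefined number of strongest
(largest signed) edges for every subject, so graph density is constant
across subjects at each threshold.  Densities above 45% are not analyzed
because they would start to include negative-valued edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_DENSITIES = tuple(np.round(np.arange(0.05, 0.46, 0.05), 2))


class ConnectomeError(ValueError):
    pass


@dataclass(frozen=True)
class ConnectivityMatrix:
    """N x N symmetric Pearson matrix with zero diagonal."""

    weights: np.ndarray = field(repr=False)
    network_name: str = ""
    subject_id: str = ""
    visit_id: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ConnectomeError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ConnectomeError("diagonal must be exactly zero")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ThresholdedGraph:
    """Weighted graph after proportional thresholding (non-retained edges = 0)."""

    weights: np.ndarray = field(repr=False)
    density: float
    n_edges_kept: int
    network_name: str = ""
    subject_id: str = ""
    visit_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class DensityGrid:
    """Strictly increasing density thresholds, by default 5% to 45% in 5% steps."""

    densities: tuple = DEFAULT_DENSITIES

    def __post_init__(self):
        d = tuple(float(x) for x in self.densities)
        if not d:
            raise ConnectomeError("density grid is empty")
        if any(not (0 < x <= 0.45) for x in d):
            raise ConnectomeError(f"densities must lie in (0, 0.45], got {d}")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ConnectomeError(f"densities must be strictly increasing, got {d}")
        object.__setattr__(self, "densities", d)

    def __iter__(self):
        return iter(self.densities)

    def __len__(self):
        return len(self.densities)


def correlation_matrix(ts, net=None) -> ConnectivityMatrix:
    """Pearson correlation matrix over kept volumes for the nodes of ``net``.

    ``net`` may be ``None`` (all columns), a ``NetworkDefinition``, or an
    index array.  Computed directly on the member-node columns of the time
    series; for Pearson correlation this is identical to masking a matrix
    computed on all nodes.
    """
    data = ts.data
    name = ""
    if net is not None:
        members = getattr(net, "member_nodes", net)
        name = getattr(net, "name", "")
        data = data[:, np.asarray(members)]
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if len(dead):
        raise ConnectomeError(f"nodes with zero temporal variance: {dead.tolist()}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        weights=r,
        network_name=name,
        subject_id=getattr(ts, "subject_id", ""),
        visit_id=getattr(ts, "visit_id", ""),
    )


def overall_connectivity(cm: ConnectivityMatrix) -> float:
    """Mean over the strictly positive upper-triangle edges; NaN when none
    are positive (a missing value, not an error)."""
    iu = np.triu_indices(cm.n_nodes, k=1)
    vals = cm.weights[iu]
    pos = vals[vals > 0]
    return float(pos.mean()) if len(pos) else float("nan")


def _edge_order(weights: np.ndarray):
    """Upper-triangle edges sorted by descending weight, ties broken by
    ascending (row, col)."""
    i, j = np.triu_indices(weights.shape[0], k=1)
    w = weights[i, j]
    order = np.lexsort((j, i, -w))
    return i[order], j[order], w[order]


def n_edges_at_density(n_nodes: int, density: float) -> int:
    """Edge count at a proportional density: round-half-away-from-zero of
    density * N(N-1)/2."""
    m = n_nodes * (n_nodes - 1) / 2
    return int(np.floor(density * m + 0.5))


def proportional_threshold(cm: ConnectivityMatrix, density: float) -> ThresholdedGraph:
    """Keep the fixed number of strongest (largest signed) edges.

    A deterministic tie-break (ascending row, col among equal weights) makes
    the retained edge set at density d a superset of the set at any smaller
    density.  If the retained set reaches a non-positive weight a warning is
    issued and the graph is still produced.
    """
    if not (0 < density <= 1):
        raise ConnectomeError(f"density must be in (0, 1], got {density}")
    n = cm.n_nodes
    k = n_edges_at_density(n, density)
    i, j, w = _edge_order(cm.weights)
    keep_i, keep_j, keep_w = i[:k], j[:k], w[:k]
    if k and keep_w[-1] <= 0:
        warnings.warn(
            f"density {density:.2f} retains {int(np.sum(keep_w <= 0))} non-positive edges",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.zeros_like(cm.weights)
    out[keep_i, keep_j] = keep_w
    out[keep_j, keep_i] = keep_w
    return ThresholdedGraph(
        weights=out,
        density=float(density),
        n_edges_kept=k,
        network_name=cm.network_name,
        subject_id=cm.subject_id,
        visit_id=cm.visit_id,
    )
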
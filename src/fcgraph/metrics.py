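"""Weighted graph statistics: global efficiency and clustering coefficient.

Conventions follow the Brain Connectivity Toolbox.  Edge lengths for
shortest paths are the reciprocal weights L_ij = 1/w_ij; global efficiency
is the mean inverse shortest-path length over ordered node pairs, with
disconnected pairs contributing zero (the d -> inf limit) -- necessary at
sparse densities where fragmentation is common.  The clustering
coefficient is the Onnela weighted variant: weights are normalized by the
graph maximum, each node's coefficient is the mean geometric-mean triangle
intensity over its degree pairs, nodes with degree < 2 contribute zero,
and the network value is the mean over all nodes (isolated nodes retained).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _sp

from fcgraph.connectome import (
    ConnectivityMatrix,
    DensityGrid,
    ThresholdedGraph,
    overall_connectivity,
    proportional_threshold,
)


class MetricError(ValueError):
    pass


def _check_weights(g) -> np.ndarray:
    w = np.asarray(g.weights if hasattr(g, "weights") else g, dtype=float)
    if np.any(w < 0):
        raise MetricError("retained edge weights must be positive")
    return w


def shortest_path_lengths(g: ThresholdedGraph) -> np.ndarray:
    """All-pairs shortest-path distances over edge lengths 1/w.

    Unreachable pairs are +inf; the diagonal is 0.
    """
    w = _check_weights(g)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    # dense csgraph input: zero entries mean "no edge"
    return _sp(lengths, method="FW", directed=False)


def global_efficiency(g: ThresholdedGraph) -> float:
    """GE = mean over ordered pairs i != j of 1/d_ij, with 1/inf = 0."""
    d = shortest_path_lengths(g)
    n = d.shape[0]
    if n < 2:
        raise MetricError("global efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficient(g: ThresholdedGraph) -> float:
    """Onnela weighted clustering, averaged over all nodes.

    C_i = (2 / (k_i (k_i - 1))) * sum over triangles at i of
    (w_ij w_jk w_ik / w_max^3)^(1/3); C_i = 0 for degree k_i < 2.
    """
    w = _check_weights(g)
    wmax = w.max()
    if wmax == 0:
        return 0.0
    cube = np.cbrt(w / wmax)
    # diagonal of cube^3 counts each triangle at i twice
    tri = np.diagonal(cube @ cube @ cube)
    k = np.count_nonzero(w > 0, axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def metrics_across_densities(cm: ConnectivityMatrix, grid: DensityGrid = DensityGrid()) -> pd.DataFrame:
    """One tidy row per density: ge, cc and the (unthresholded) overall FC."""
    fc = overall_connectivity(cm)
    rows = []
    for density in grid:
        g = proportional_threshold(cm, density)
        rows.append(
            {
                "subject_id": cm.subject_id,
                "visit_id": cm.visit_id,
                "network": cm.network_name,
                "density": density,
                "ge": global_efficiency(g),
                "cc": clustering_coefficient(g),
                "overall_fc": fc,
            }
        )
    return pd.DataFrame(rows)
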
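"""Small-world metrics on weighted networks.

Two nodal metrics quantify segregation and integration:

* **Weighted clustering coefficient** (Onnela): triangle intensity around a
  node as the geometric mean of its normalized edge weights,

  .. math:: C_i = \\frac{1}{k_i (k_i - 1)} \\sum_{j,h}
            (\\hat w_{ij} \\hat w_{ih} \\hat w_{jh})^{1/3},

  with :math:`\\hat w = w / \\max(w)` over the whole matrix and
  :math:`k_i` the number of positive edges at node *i*; :math:`C_i = 0`
  when :math:`k_i < 2`.

* **Nodal global efficiency**: mean inverse weighted shortest-path distance
  to all other nodes, with edge length :math:`1/w` and unreachable pairs
  contributing zero.

Structurally missing pairs are treated exactly like absent edges; the
metrics are computed on the network that survives edge exclusion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome import ConnectivityMatrix

__all__ = [
    "weighted_clustering",
    "weighted_shortest_paths",
    "nodal_global_efficiency",
    "node_degrees",
    "compute_nodal_metrics",
]


def _weight_array(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, ConnectivityMatrix):
        w = matrix.weights.copy()
        w[matrix.structural_missing] = 0.0
    else:
        w = np.asarray(matrix, dtype=float).copy()
    if np.any(w < 0):
        raise ValueError("metrics require a nonnegative (filtered) matrix")
    np.fill_diagonal(w, 0.0)
    return w


def node_degrees(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Number of strictly positive edges incident to each node."""
    w = _weight_array(matrix)
    return (w > 0).sum(axis=1)


def weighted_clustering(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    Weights are normalized by the matrix-wide maximum, so an all-zero
    matrix yields all-zero clustering rather than an error.
    """
    w = _weight_array(matrix)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    cube = np.cbrt(w / wmax)
    triangles = np.diagonal(cube @ cube @ cube)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return c


def weighted_shortest_paths(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances with edge length 1/w.

    Absent (or structurally missing) edges have no direct length; distances
    between disconnected nodes come back as ``inf``.
    """
    w = _weight_array(matrix)
    rows, cols = np.nonzero(w)
    lengths = csr_matrix((1.0 / w[rows, cols], (rows, cols)), shape=w.shape)
    return shortest_path(lengths, method="D", directed=False)


def nodal_global_efficiency(d: np.ndarray) -> np.ndarray:
    """Per-node efficiency from a pairwise distance matrix: mean of 1/d.

    ``E_i = (1/(n-1)) * sum_{j != i} 1/d_ij`` with ``1/inf = 0``.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def compute_nodal_metrics(matrix: ConnectivityMatrix) -> pd.DataFrame:
    """Clustering, efficiency, and degree for every node of one subject."""
    clustering = weighted_clustering(matrix)
    efficiency = nodal_global_efficiency(weighted_shortest_paths(matrix))
    return pd.DataFrame(
        {
            "node_id": list(matrix.node_ids),
            "clustering": clustering,
            "efficiency": efficiency,
            "degree": node_degrees(matrix),
        }
    )
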
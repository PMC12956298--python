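"""Construction and filtering of weighted functional connectivity matrices.

A subject's connectome is the Pearson correlation matrix of regional BOLD
time series, made nonnegative by zeroing negative correlations and with
short-range pairs (centroids closer than 20 mm) removed entirely, since
connectivity between nearby regions is inflated by head motion.  Pairs
removed by the distance rule are *structurally missing* — they were never
computed — and are tracked separately from edges that are merely zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "ConnectivityMatrix",
    "node_distances",
    "correlation_network",
    "apply_edge_filters",
    "network_density",
    "qc_filter_subjects",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted adjacency with a structural-missing mask.

    Parameters
    ----------
    weights
        ``(n, n)`` symmetric float array with a zero diagonal.  Signed
        right after :func:`correlation_network`; nonnegative and in
        ``[0, 1]`` once :func:`apply_edge_filters` has run.
    structural_missing
        ``(n, n)`` symmetric boolean mask flagging pairs excluded from
        network construction (distance rule).  Flagged pairs carry weight 0.
    node_ids
        Node labels bound to the row/column order.
    """

    weights: np.ndarray
    structural_missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    node_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] != n:
            raise ValueError("weights must be a square matrix")
        if self.structural_missing is None:
            self.structural_missing = np.zeros((n, n), dtype=bool)
        self.structural_missing = np.asarray(self.structural_missing, dtype=bool)
        if self.structural_missing.shape != (n, n):
            raise ValueError("structural_missing shape does not match weights")
        if self.node_ids is None:
            self.node_ids = tuple(f"n{i:03d}" for i in range(n))
        else:
            self.node_ids = tuple(str(x) for x in self.node_ids)
        if len(self.node_ids) != n:
            raise ValueError("node_ids length does not match matrix dimension")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10, equal_nan=False):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(self.structural_missing, self.structural_missing.T):
            raise ValueError("structural_missing must be symmetric")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def node_distances(nodes: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between node centroids.

    ``nodes`` must carry ``x``, ``y``, ``z`` columns in row order matching
    the connectivity matrices.
    """
    coords = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("node coordinates must be finite")
    return squareform(pdist(coords))


def correlation_network(
    runs: list[pd.DataFrame], fisher_z: bool = False
) -> ConnectivityMatrix:
    """Signed correlation network from one or more time-by-node runs.

    Each run is standardized column-wise (mean 0, SD 1) before the runs are
    concatenated in time; the Pearson correlation over all node pairs of the
    concatenated series is returned with a zero diagonal.  No sign or
    distance filtering is applied here.  ``fisher_z`` optionally maps the
    correlations through arctanh (off by default: plain correlations).
    """
    if not runs:
        raise ValueError("at least one run is required")
    cols = list(runs[0].columns)
    standardized = []
    for r, run in enumerate(runs):
        if list(run.columns) != cols:
            raise ValueError("all runs must share the same node columns")
        if len(run) < 3:
            raise ValueError("each run needs at least 3 time points")
        arr = run.to_numpy(dtype=float)
        sd = arr.std(axis=0, ddof=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValueError(
                f"zero-variance time series for node '{cols[flat[0]]}' in run {r}"
            )
        standardized.append((arr - arr.mean(axis=0)) / sd)
    series = np.vstack(standardized)
    weights = np.corrcoef(series, rowvar=False)
    weights = np.clip(weights, -1.0, 1.0)
    if fisher_z:
        weights = np.arctanh(np.clip(weights, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2.0
    return ConnectivityMatrix(weights=weights, node_ids=tuple(map(str, cols)))


def apply_edge_filters(
    matrix: ConnectivityMatrix,
    nodes: pd.DataFrame,
    min_dist_mm: float = 20.0,
) -> ConnectivityMatrix:
    """Zero negative weights and structurally exclude short-range pairs.

    Negative correlations are set to 0 (they remain observed edges of weight
    zero).  Pairs whose centroids lie strictly closer than ``min_dist_mm``
    are flagged structurally missing and carry weight 0.  Idempotent.
    """
    if len(nodes) != matrix.n:
        raise ValueError(
            f"node table has {len(nodes)} rows but matrix is {matrix.n}x{matrix.n}"
        )
    dist = node_distances(nodes)
    close = dist < min_dist_mm
    np.fill_diagonal(close, False)
    missing = matrix.structural_missing | close
    weights = np.where(matrix.weights < 0, 0.0, matrix.weights)
    weights = np.where(missing, 0.0, weights)
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(
        weights=weights, structural_missing=missing, node_ids=matrix.node_ids
    )


def network_density(matrix: ConnectivityMatrix) -> float:
    """Fraction of eligible (non-missing) node pairs with strictly positive weight."""
    iu = np.triu_indices(matrix.n, k=1)
    eligible = ~matrix.structural_missing[iu]
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError("no eligible node pairs (all structurally missing)")
    positive = (matrix.weights[iu] > 0) & eligible
    return float(positive.sum()) / n_eligible


def qc_filter_subjects(
    subjects: pd.DataFrame, rmd_threshold: float = 0.3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain subjects whose head motion passes QC (RMD strictly below threshold).

    Returns the retained table and an exclusion log with one row per dropped
    subject (``subject_id``, ``rmd``, ``reason``).
    """
    if len(subjects) == 0:
        return subjects.copy(), pd.DataFrame(columns=["subject_id", "rmd", "reason"])
    keep = subjects["rmd"] < rmd_threshold
    excluded = subjects.loc[~keep, ["subject_id", "rmd"]].copy()
    excluded["reason"] = [
        f"rmd {v:.4g} >= {rmd_threshold:g} mm" for v in excluded["rmd"]
    ]
    return subjects.loc[keep].reset_index(drop=True), excluded.reset_index(drop=True)
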
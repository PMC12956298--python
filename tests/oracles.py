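"""Brute-force oracles and tiny-fixture builders shared across test modules.

The oracles are deliberately naive and independent of the library's
implementation: clustering by direct triple enumeration of the Onnela
formula, distances by Floyd-Warshall (the library uses Dijkstra) or
exhaustive simple-path enumeration on tiny graphs.
"""

from itertools import permutations

import numpy as np
import pandas as pd

import netlmm as nl
from netlmm.metrics import compute_nodal_metrics


def brute_clustering(w):
    w = np.asarray(w, float)
    n = len(w)
    c = np.zeros(n)
    wmax = w.max()
    if wmax == 0:
        return c
    wh = w / wmax
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and w[j, h] > 0:
                    s += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
        c[i] = s / (k * (k - 1))
    return c


def brute_distances_fw(w):
    """Floyd-Warshall all-pairs distances with length 1/w."""
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def brute_distances_paths(w):
    """Exhaustive simple-path enumeration; only viable for tiny graphs."""
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = np.inf
            for r in range(n - 1):
                for mid in permutations([k for k in range(n) if k not in (i, j)], r):
                    path = (i, *mid, j)
                    if all(w[a, b] > 0 for a, b in zip(path, path[1:])):
                        best = min(
                            best, sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))
                        )
            d[i, j] = best
    return d


def tiny_cohort(weights, dmn, coords, missing=None):
    """Two-subject cohort over a hand-built matrix, for design tests."""
    nodes = pd.DataFrame(
        {
            "node_id": [f"n{i}" for i in range(len(dmn))],
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "z": [c[2] for c in coords],
            "dmn": dmn,
        }
    )
    cm = nl.ConnectivityMatrix(np.asarray(weights, float), missing, nodes["node_id"])
    subjects = pd.DataFrame(
        {
            "subject_id": ["s0", "s1"],
            "group": ["HIV-MJ-", "HIV+MJ+"],
            "hiv": [0, 1],
            "mj": [0, 1],
            "globalT": [50.0, 47.0],
            "age": [38.0, 41.0],
            "sex": [1, 0],
            "race": [0, 1],
            "education": [16.0, 13.0],
            "rmd": [0.1, 0.12],
        }
    )
    matrices = {"s0": cm, "s1": cm}
    metrics = {s: compute_nodal_metrics(cm) for s in ("s0", "s1")}
    return matrices, metrics, subjects, nodes
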
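"""Long-format edge table and fixed-effect design matrices.

Every retained edge of every subject becomes one row: its strength is the
response, and the regressors are the endpoint-averaged nodal metrics, the
inter-node distance and its square, the subnetwork class of the edge
(within the DMN, between DMN and the rest, or entirely outside), the
subject's group indicators (HIV, MJ, and their product HIVMJ), global
cognitive performance (GlobalT), and the confounders age, sex, race,
education, and head motion (RMD).

Two model formulas are supported.  ``model1`` crosses the three group
indicators with the two metrics and the two DMN-class indicators (all
two- and three-way products), yielding 43 fixed-effect columns.  ``model2``
additionally crosses everything with GlobalT, yielding 79 columns.  All
continuous covariates (metrics, distance terms, GlobalT, age, education,
RMD) are grand-mean centered over edge rows before any product is formed;
``dist2`` is the square of the raw distance, centered afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, node_distances

__all__ = [
    "GROUPS",
    "METRICS",
    "DMN_LEVELS",
    "CENTERED_COLUMNS",
    "model_terms",
    "EdgeTable",
    "DesignMatrix",
    "build_edge_table",
    "assemble_design_matrix",
    "assemble_terms",
]

GROUPS = ("hiv", "mj", "hivmj")
METRICS = ("clust", "eff")
DMN_LEVELS = ("dmn_within", "dmn_between")

#: edge-table columns that are grand-mean centered
CENTERED_COLUMNS = (
    "clust_mean",
    "eff_mean",
    "dist",
    "dist2",
    "globalT",
    "age",
    "education",
    "rmd",
)

_CONFOUNDERS = ("dist", "dist2", "age", "sex", "race", "education", "rmd")


def model_terms(model: str) -> list[str]:
    """Canonical ordered fixed-effect term names for ``model1`` or ``model2``."""
    if model not in ("model1", "model2"):
        raise ValueError(f"unknown model '{model}' (expected 'model1' or 'model2')")
    terms = ["Intercept", *GROUPS, *METRICS, *DMN_LEVELS, *_CONFOUNDERS]
    terms += [f"{g}:{m}" for g in GROUPS for m in METRICS]
    terms += [f"{g}:{d}" for g in GROUPS for d in DMN_LEVELS]
    terms += [f"{m}:{d}" for m in METRICS for d in DMN_LEVELS]
    terms += [f"{g}:{m}:{d}" for g in GROUPS for m in METRICS for d in DMN_LEVELS]
    if model == "model2":
        terms += ["globalT"]
        terms += [f"globalT:{g}" for g in GROUPS]
        terms += [f"globalT:{m}" for m in METRICS]
        terms += [f"globalT:{d}" for d in DMN_LEVELS]
        terms += [f"globalT:{m}:{d}" for m in METRICS for d in DMN_LEVELS]
        terms += [f"globalT:{g}:{m}" for g in GROUPS for m in METRICS]
        terms += [f"globalT:{g}:{d}" for g in GROUPS for d in DMN_LEVELS]
        terms += [
            f"globalT:{g}:{m}:{d}"
            for g in GROUPS
            for m in METRICS
            for d in DMN_LEVELS
        ]
    return terms


@dataclass
class EdgeTable:
    """Long-format edge design table plus the centering constants used.

    ``df`` has one row per (subject, retained edge).  The columns listed in
    :data:`CENTERED_COLUMNS` are already centered; ``centers`` records the
    grand means that were subtracted (needed e.g. to place a raw GlobalT
    score on the model scale).
    """

    df: pd.DataFrame
    centers: dict[str, float]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class DesignMatrix:
    """Named fixed-effect regressor matrix with response and grouping."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    groups: np.ndarray
    model: str
    centers: dict[str, float]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)


def build_edge_table(
    matrices: Mapping[str, ConnectivityMatrix],
    metrics: Mapping[str, pd.DataFrame],
    subjects: pd.DataFrame,
    nodes: pd.DataFrame,
    keep_all_edges: bool = False,
) -> EdgeTable:
    """Assemble the long-format edge table for a cohort.

    One row is emitted per subject and per non-missing node pair with
    strictly positive strength (``keep_all_edges=True`` keeps zero-strength
    eligible pairs too, which the oracle simulator uses to lay out rows
    before strengths exist).  Endpoint metrics are averaged, distances come
    from the node centroids, and all continuous covariates are grand-mean
    centered over the emitted rows.
    """
    node_ids = nodes["node_id"].astype(str).tolist()
    dmn = nodes["dmn"].to_numpy(dtype=bool)
    dist = node_distances(nodes)
    iu = np.triu_indices(len(node_ids), k=1)
    n_dmn_ends = dmn[iu[0]].astype(int) + dmn[iu[1]].astype(int)
    edge_class_all = np.array(["outside", "between", "within_dmn"])[n_dmn_ends]
    dist_all = dist[iu]

    sub_cols = ["hiv", "mj", "globalT", "age", "sex", "race", "education", "rmd"]
    frames = []
    for _, sub in subjects.iterrows():
        sid = str(sub["subject_id"])
        if sid not in matrices:
            raise ValueError(f"no connectivity matrix for subject '{sid}'")
        if sid not in metrics:
            raise ValueError(f"no nodal metrics for subject '{sid}'")
        cm = matrices[sid]
        if list(cm.node_ids) != node_ids:
            raise ValueError(f"node order mismatch for subject '{sid}'")
        met = metrics[sid].set_index("node_id")
        clust = met["clustering"].reindex(node_ids).to_numpy(dtype=float)
        eff = met["efficiency"].reindex(node_ids).to_numpy(dtype=float)
        if np.any(np.isnan(clust)) or np.any(np.isnan(eff)):
            raise ValueError(f"metrics for subject '{sid}' do not cover all nodes")
        strength = cm.weights[iu]
        eligible = ~cm.structural_missing[iu]
        keep = eligible if keep_all_edges else (eligible & (strength > 0))
        idx = np.flatnonzero(keep)
        frame = pd.DataFrame(
            {
                "subject_id": sid,
                "node_i": np.asarray(node_ids)[iu[0][idx]],
                "node_j": np.asarray(node_ids)[iu[1][idx]],
                "strength": strength[idx],
                "clust_mean": (clust[iu[0][idx]] + clust[iu[1][idx]]) / 2.0,
                "eff_mean": (eff[iu[0][idx]] + eff[iu[1][idx]]) / 2.0,
                "dist": dist_all[idx],
                "dist2": dist_all[idx] ** 2,
                "edge_class": edge_class_all[idx],
            }
        )
        for c in sub_cols:
            frame[c] = float(sub[c]) if pd.notna(sub[c]) else np.nan
        frame["hivmj"] = frame["hiv"] * frame["mj"]
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    centers: dict[str, float] = {}
    for col in CENTERED_COLUMNS:
        mu = float(df[col].mean())
        if np.isnan(mu):  # globalT may be absent for a model-1-only cohort
            mu = 0.0
        centers[col] = mu
        df[col] = df[col] - mu
    return EdgeTable(df=df, centers=centers)


def assemble_terms(components: Mapping[str, np.ndarray], terms: list[str]) -> np.ndarray:
    """Column-stack products of base components for the requested terms.

    Each term name is a ``:``-joined product of component names, except
    ``Intercept`` which is a column of ones.  Used both to assemble cohort
    design matrices and to score single prediction rows.
    """
    n = len(next(iter(components.values())))
    cols = []
    for term in terms:
        if term == "Intercept":
            cols.append(np.ones(n))
            continue
        col = np.ones(n)
        for part in term.split(":"):
            col = col * np.asarray(components[part], dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def table_components(table: EdgeTable) -> dict[str, np.ndarray]:
    """Base regressor columns (already centered where applicable) of an edge table."""
    df = table.df
    return {
        "hiv": df["hiv"].to_numpy(dtype=float),
        "mj": df["mj"].to_numpy(dtype=float),
        "hivmj": df["hivmj"].to_numpy(dtype=float),
        "clust": df["clust_mean"].to_numpy(dtype=float),
        "eff": df["eff_mean"].to_numpy(dtype=float),
        "dmn_within": (df["edge_class"] == "within_dmn").to_numpy(dtype=float),
        "dmn_between": (df["edge_class"] == "between").to_numpy(dtype=float),
        "dist": df["dist"].to_numpy(dtype=float),
        "dist2": df["dist2"].to_numpy(dtype=float),
        "age": df["age"].to_numpy(dtype=float),
        "sex": df["sex"].to_numpy(dtype=float),
        "race": df["race"].to_numpy(dtype=float),
        "education": df["education"].to_numpy(dtype=float),
        "rmd": df["rmd"].to_numpy(dtype=float),
        "globalT": df["globalT"].to_numpy(dtype=float),
    }


def assemble_design_matrix(table: EdgeTable, model: str) -> DesignMatrix:
    """Build the named fixed-effect design matrix for ``model1`` or ``model2``."""
    if len(table.df) == 0:
        raise ValueError("edge table is empty")
    terms = model_terms(model)
    comps = table_components(table)
    if model == "model2" and np.any(np.isnan(comps["globalT"])):
        raise ValueError("model2 requires globalT for every subject")
    X = assemble_terms(comps, terms)
    sd = X.std(axis=0)
    for j, term in enumerate(terms):
        if term != "Intercept" and sd[j] < 1e-12:
            raise ValueError(f"design column '{term}' is constant")
    return DesignMatrix(
        X=X,
        columns=terms,
        y=table.df["strength"].to_numpy(dtype=float),
        groups=table.df["subject_id"].to_numpy(),
        model=model,
        centers=dict(table.centers),
    )
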
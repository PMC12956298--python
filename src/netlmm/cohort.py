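"""Synthetic cohorts with recoverable ground truth.

The generator emulates the study conditions: four groups crossed on HIV
and marijuana-use status, weighted nonnegative connectomes whose mean
connectivity decays with inter-node distance, a spatially coherent DMN
block with elevated within-block connectivity, and subject covariates
drawn from the published per-group demographic distributions (GlobalT,
age, education means/SDs; sex/race proportions; sub-QC head motion).

Two regimes matter.  In the *endogenous* regime (real data, or the
reference networks here) the metric covariates are computed from the same
networks whose strengths are modeled, so no closed-form truth exists.  In
*oracle* mode, each subject's nodal clustering/efficiency are computed
once on a noisy reference network, frozen as covariates, and edge
strengths are then drawn from the linear predictor

    S = X beta + b_subject + eps,   b ~ N(0, sigma_b^2), eps ~ N(0, sigma_e^2),

clipped to [0, 1].  Refitting the mixed model on such a cohort recovers
``beta`` (and therefore every group contrast) up to sampling noise, which
is what the parameter-recovery tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, node_distances
from .design import (
    EdgeTable,
    assemble_design_matrix,
    build_edge_table,
    model_terms,
)
from .metrics import compute_nodal_metrics

__all__ = [
    "GroundTruth",
    "Cohort",
    "OracleCohort",
    "generate_node_layout",
    "generate_subject_table",
    "simulate_oracle_cohort",
    "default_ground_truth",
    "truth_from_contrasts",
    "GROUP_ORDER",
    "GROUP_COVARIATE_DISTRIBUTIONS",
    "DEFAULT_GROUP_DIFFERENCES",
    "DEFAULT_GLOBALT_MODERATION",
]

#: canonical group order: control first
GROUP_ORDER = ("HIV-MJ-", "HIV+MJ-", "HIV-MJ+", "HIV+MJ+")

_GROUP_FLAGS = {
    "HIV-MJ-": (0, 0),
    "HIV+MJ-": (1, 0),
    "HIV-MJ+": (0, 1),
    "HIV+MJ+": (1, 1),
}

#: per-group covariate distributions used as generator defaults
#: (GlobalT/age/education: mean, SD; sex: P(male); race: P(White);
#: rmd: mean, SD of a truncated normal kept inside the QC window).
GROUP_COVARIATE_DISTRIBUTIONS = {
    "HIV-MJ-": {"globalT": (50.45, 5.91), "age": (38.86, 9.23), "education": (16.24, 2.13),
                "sex": 44 / 59, "race": 24 / 59, "rmd": (0.10, 0.03)},
    "HIV+MJ-": {"globalT": (48.85, 5.29), "age": (39.09, 8.09), "education": (15.35, 2.60),
                "sex": 51 / 62, "race": 24 / 62, "rmd": (0.10, 0.05)},
    "HIV-MJ+": {"globalT": (50.59, 5.65), "age": (36.43, 7.83), "education": (14.33, 2.38),
                "sex": 41 / 53, "race": 17 / 53, "rmd": (0.10, 0.04)},
    "HIV+MJ+": {"globalT": (47.27, 5.21), "age": (37.81, 8.68), "education": (14.22, 2.41),
                "sex": 53 / 63, "race": 18 / 63, "rmd": (0.11, 0.05)},
}

#: default generative group-vs-control slope differences for the
#: (metric, DMN location) contrasts; these are the effect sizes the
#: recovery suites try to get back out of the fit.
DEFAULT_GROUP_DIFFERENCES = {
    ("HIV+MJ-", "clustering", "within"): -0.0015,
    ("HIV-MJ+", "clustering", "within"): -0.0116,
    ("HIV+MJ+", "clustering", "within"): -0.0179,
    ("HIV+MJ-", "clustering", "outside"): 0.0036,
    ("HIV-MJ+", "clustering", "outside"): 0.0037,
    ("HIV+MJ+", "clustering", "outside"): 0.0025,
    ("HIV+MJ-", "efficiency", "within"): 0.0120,
    ("HIV-MJ+", "efficiency", "within"): 0.0216,
    ("HIV+MJ+", "efficiency", "within"): 0.0367,
    ("HIV+MJ-", "efficiency", "outside"): -0.0026,
    ("HIV-MJ+", "efficiency", "outside"): -0.0024,
    ("HIV+MJ+", "efficiency", "outside"): -0.0019,
}

#: default generative group-vs-control differences in the GlobalT
#: moderation of each metric slope (per T-score point).
DEFAULT_GLOBALT_MODERATION = {
    ("HIV+MJ-", "clustering", "within"): 0.0227,
    ("HIV-MJ+", "clustering", "within"): 0.0174,
    ("HIV+MJ+", "clustering", "within"): 0.0207,
    ("HIV+MJ-", "clustering", "outside"): -0.0064,
    ("HIV-MJ+", "clustering", "outside"): 0.0011,
    ("HIV+MJ+", "clustering", "outside"): 0.0031,
    ("HIV+MJ-", "efficiency", "within"): -0.0208,
    ("HIV-MJ+", "efficiency", "within"): -0.0160,
    ("HIV+MJ+", "efficiency", "within"): -0.0214,
    ("HIV+MJ-", "efficiency", "outside"): 0.0043,
    ("HIV-MJ+", "efficiency", "outside"): -0.0005,
    ("HIV+MJ+", "efficiency", "outside"): -0.0030,
}

_METRIC_TERM = {"clustering": "clust", "efficiency": "eff"}

#: baseline fixed effects shared by both models (everything the group /
#: GlobalT difference dictionaries do not pin down)
_BASE_EFFECTS = {
    "Intercept": 0.5,
    "hiv": -0.010, "mj": -0.005, "hivmj": 0.005,
    "clust": 0.05, "eff": 0.08,
    "dmn_within": 0.05, "dmn_between": 0.02,
    "dist": -5e-4, "dist2": -2e-6,
    "age": -5e-4, "sex": 0.01, "race": 0.005, "education": 1e-3, "rmd": -0.1,
    "clust:dmn_within": 0.02, "eff:dmn_within": 0.02,
    "clust:dmn_between": 0.005, "eff:dmn_between": 0.005,
    "hiv:dmn_within": 0.005, "mj:dmn_within": 0.004, "hivmj:dmn_within": -0.003,
    "hiv:dmn_between": 0.002, "mj:dmn_between": 0.002, "hivmj:dmn_between": -0.001,
}

#: baseline GlobalT effects (model 2 only); the control group's metric
#: slopes drift with GlobalT: down for clustering, up for efficiency.
_BASE_GLOBALT_EFFECTS = {
    "globalT": 0.001,
    "globalT:hiv": 0.0005, "globalT:mj": 0.0003, "globalT:hivmj": -0.0002,
    "globalT:clust": -0.0005, "globalT:eff": 0.0005,
    "globalT:dmn_within": 0.001, "globalT:dmn_between": 0.0005,
    "globalT:clust:dmn_within": -0.0015, "globalT:eff:dmn_within": 0.0015,
    "globalT:clust:dmn_between": 0.0002, "globalT:eff:dmn_between": -0.0002,
}


@dataclass
class GroundTruth:
    """Generative fixed effects and variance components of an oracle cohort."""

    beta: pd.Series
    sigma_e: float
    sigma_b: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma_e < 0 or self.sigma_b < 0:
            raise ValueError("variance components must be nonnegative")

    @property
    def model(self) -> str:
        return "model2" if "globalT" in self.beta.index else "model1"


@dataclass
class Cohort:
    """Per-subject matrices and nodal metrics plus node/subject tables."""

    nodes: pd.DataFrame
    subjects: pd.DataFrame
    matrices: dict[str, ConnectivityMatrix]
    metrics: dict[str, pd.DataFrame]

    def edge_table(self, keep_all_edges: bool = False) -> EdgeTable:
        return build_edge_table(
            self.matrices, self.metrics, self.subjects, self.nodes,
            keep_all_edges=keep_all_edges,
        )


@dataclass
class OracleCohort(Cohort):
    """A simulated cohort carrying its generative truth.

    ``metrics`` are the frozen reference-network metrics: regressing the
    simulated strengths on them recovers ``truth.beta`` in expectation.
    """

    truth: GroundTruth = None  # type: ignore[assignment]
    clip_fraction: float = 0.0


def generate_node_layout(
    n_nodes: int = 80,
    n_dmn: int = 20,
    box_mm: float = 160.0,
    seed: int = 0,
    dmn_spread_mm: float = 40.0,
) -> pd.DataFrame:
    """Random 3-D node layout with a spatially coherent DMN block.

    Non-DMN nodes are uniform in a ``box_mm`` cube; DMN nodes are drawn
    isotropic-normal (SD ``dmn_spread_mm``) around one interior centroid so
    the DMN block is geometrically coherent, as in a real parcellation.
    """
    if not 0 < n_dmn < n_nodes:
        raise ValueError("n_dmn must satisfy 0 < n_dmn < n_nodes")
    if box_mm <= 40:
        raise ValueError("box_mm too small: all pairs would fall under the distance rule")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box_mm, size=(n_nodes, 3))
    center = rng.uniform(0.3 * box_mm, 0.7 * box_mm, size=3)
    dmn_coords = center + rng.normal(0.0, dmn_spread_mm, size=(n_dmn, 3))
    coords[:n_dmn] = np.clip(dmn_coords, 0.0, box_mm)
    dmn = np.zeros(n_nodes, dtype=bool)
    dmn[:n_dmn] = True
    order = rng.permutation(n_nodes)
    coords, dmn = coords[order], dmn[order]
    return pd.DataFrame(
        {
            "node_id": [f"n{i:03d}" for i in range(n_nodes)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "dmn": dmn,
        }
    )


def generate_subject_table(
    n_per_group: int = 15,
    seed: int = 0,
    group_means: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Balanced four-group subject table with realistic covariates.

    Continuous covariates are normal with the per-group defaults in
    :data:`GROUP_COVARIATE_DISTRIBUTIONS` (override selected entries via
    ``group_means``); sex/race are Bernoulli with the default proportions;
    RMD is kept strictly inside the (0, 0.3) mm QC window.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group in GROUP_ORDER:
        cfg = dict(GROUP_COVARIATE_DISTRIBUTIONS[group])
        if group_means and group in group_means:
            cfg.update(group_means[group])
        hiv, mj = _GROUP_FLAGS[group]
        for _ in range(n_per_group):
            mu, sd = cfg["rmd"]
            rmd = float(np.clip(rng.normal(mu, sd), 0.005, 0.295))
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "group": group,
                    "hiv": hiv,
                    "mj": mj,
                    "globalT": float(rng.normal(*cfg["globalT"])),
                    "age": float(rng.normal(*cfg["age"])),
                    "sex": int(rng.random() < cfg["sex"]),
                    "race": int(rng.random() < cfg["race"]),
                    "education": float(rng.normal(*cfg["education"])),
                    "rmd": rmd,
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    # tiny cohorts can draw an all-male or single-race table, which would
    # make a confounder column constant (inestimable); flip one subject
    for col in ("sex", "race"):
        if df[col].nunique() == 1:
            df.loc[0, col] = 1 - df.loc[0, col]
    return df


def truth_from_contrasts(
    model: str,
    group_differences: Mapping[tuple[str, str, str], float] | None = None,
    globalT_moderation: Mapping[tuple[str, str, str], float] | None = None,
    base_effects: Mapping[str, float] | None = None,
    sigma_e: float = 0.05,
    sigma_b: float = 0.02,
    seed: int = 42,
) -> GroundTruth:
    """Build a full coefficient vector whose group contrasts equal given values.

    With the HIV/MJ/HIVMJ indicator coding, a group-vs-control contrast is
    a *sum* of interaction coefficients; this inverts that map so the
    stated (group, metric, location) differences are hit exactly:
    single-indicator groups pin the ``hiv``/``mj`` terms, and the HIV+MJ+
    cell pins the ``hivmj`` terms as the remainder.
    """
    gd = dict(DEFAULT_GROUP_DIFFERENCES if group_differences is None else group_differences)
    beta = pd.Series(0.0, index=model_terms(model))
    for t, v in _BASE_EFFECTS.items():
        beta[t] = v
    if base_effects:
        for t, v in base_effects.items():
            beta[t] = v

    def _fill(prefix: str, diffs: Mapping[tuple[str, str, str], float]) -> None:
        for metric, m in _METRIC_TERM.items():
            out = {g: diffs[(g, metric, "outside")] for g in ("HIV+MJ-", "HIV-MJ+", "HIV+MJ+")}
            win = {g: diffs[(g, metric, "within")] for g in ("HIV+MJ-", "HIV-MJ+", "HIV+MJ+")}
            beta[f"{prefix}hiv:{m}"] = out["HIV+MJ-"]
            beta[f"{prefix}mj:{m}"] = out["HIV-MJ+"]
            beta[f"{prefix}hivmj:{m}"] = out["HIV+MJ+"] - out["HIV+MJ-"] - out["HIV-MJ+"]
            beta[f"{prefix}hiv:{m}:dmn_within"] = win["HIV+MJ-"] - out["HIV+MJ-"]
            beta[f"{prefix}mj:{m}:dmn_within"] = win["HIV-MJ+"] - out["HIV-MJ+"]
            beta[f"{prefix}hivmj:{m}:dmn_within"] = (
                (win["HIV+MJ+"] - out["HIV+MJ+"])
                - (win["HIV+MJ-"] - out["HIV+MJ-"])
                - (win["HIV-MJ+"] - out["HIV-MJ+"])
            )

    _fill("", gd)
    if model == "model2":
        for t, v in _BASE_GLOBALT_EFFECTS.items():
            beta[t] = v
        gm = dict(DEFAULT_GLOBALT_MODERATION if globalT_moderation is None else globalT_moderation)
        _fill("globalT:", gm)
    return GroundTruth(beta=beta, sigma_e=sigma_e, sigma_b=sigma_b, seed=seed)


def default_ground_truth(model: str = "model1", seed: int = 42) -> GroundTruth:
    """The default generative truth: published-scale group differences."""
    return truth_from_contrasts(model, seed=seed)


def simulate_oracle_cohort(
    nodes: pd.DataFrame,
    subjects: pd.DataFrame,
    truth: GroundTruth,
    lambda_mm: float = 60.0,
    dmn_increment: float = 0.15,
    baseline_shift: float = 0.2,
    hub_sd: float = 0.30,
    noise_sd: float = 0.05,
    min_dist_mm: float = 20.0,
) -> OracleCohort:
    """Simulate an oracle-mode cohort from a generative truth.

    Procedure: (1) build each subject's reference network with
    distance-decaying mean weight ``exp(-d/lambda_mm) - baseline_shift``
    plus a within-DMN increment and subject noise, clipped to [0, 1];
    the subject noise has a node-factor component (per-node strengths
    ``u_i ~ N(0, hub_sd)`` entering every incident edge, giving the hub
    heterogeneity real connectomes show) plus i.i.d. edge noise of SD
    ``noise_sd``.  The negative baseline shift makes distant low-strength
    pairs drop out, mimicking zeroed negative correlations, so reference
    networks are realistically sparse rather than complete.  Pairs under
    the distance rule are structurally missing.  (2) Nodal clustering and
    efficiency are computed on that reference network and frozen as
    covariates; (3) one row is laid out per eligible reference edge and
    strengths are drawn from the linear predictor with subject random
    intercepts; (4) strengths are clipped to [0, 1] and returned as
    matrices, together with the frozen metrics and the truth echo.
    Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n = len(nodes)
    node_ids = nodes["node_id"].astype(str).tolist()
    dmn = nodes["dmn"].to_numpy(dtype=bool)
    dist = node_distances(nodes)
    missing = dist < min_dist_mm
    np.fill_diagonal(missing, False)
    base = (
        np.exp(-dist / lambda_mm)
        - baseline_shift
        + dmn_increment * np.outer(dmn, dmn)
    )
    iu = np.triu_indices(n, k=1)

    ref_matrices: dict[str, ConnectivityMatrix] = {}
    metrics: dict[str, pd.DataFrame] = {}
    for sid in subjects["subject_id"].astype(str):
        hubs = rng.normal(0.0, hub_sd, size=n)
        noise = np.zeros((n, n))
        noise[iu] = rng.normal(0.0, noise_sd, size=len(iu[0]))
        noise += noise.T
        w = np.clip(base + hubs[:, None] + hubs[None, :] + noise, 0.0, 1.0)
        w[missing] = 0.0
        np.fill_diagonal(w, 0.0)
        cm = ConnectivityMatrix(weights=w, structural_missing=missing, node_ids=node_ids)
        ref_matrices[sid] = cm
        metrics[sid] = compute_nodal_metrics(cm)

    table = build_edge_table(ref_matrices, metrics, subjects, nodes)
    dm = assemble_design_matrix(table, truth.model)
    extra = [t for t in truth.beta.index if t not in dm.columns]
    missing_terms = [t for t in dm.columns if t not in truth.beta.index]
    if extra or missing_terms:
        raise ValueError(
            "truth.beta does not match the design: "
            f"unknown terms {extra}, missing terms {missing_terms}"
        )
    beta = truth.beta.reindex(dm.columns).to_numpy()
    linpred = dm.X @ beta
    sub_ids = subjects["subject_id"].astype(str).to_numpy()
    b = rng.normal(0.0, truth.sigma_b, size=len(sub_ids))
    b_by_sub = dict(zip(sub_ids, b))
    linpred = linpred + np.array([b_by_sub[s] for s in dm.groups])
    s_raw = linpred + rng.normal(0.0, truth.sigma_e, size=len(linpred))
    clip_fraction = float(np.mean((s_raw < 0.0) | (s_raw > 1.0)))
    s = np.clip(s_raw, 0.0, 1.0)

    matrices: dict[str, ConnectivityMatrix] = {}
    df = table.df
    ii = pd.Index(node_ids).get_indexer(df["node_i"])
    jj = pd.Index(node_ids).get_indexer(df["node_j"])
    for sid in sub_ids:
        sel = np.flatnonzero((df["subject_id"] == sid).to_numpy())
        w = np.zeros((n, n))
        w[ii[sel], jj[sel]] = s[sel]
        w[jj[sel], ii[sel]] = s[sel]
        matrices[sid] = ConnectivityMatrix(
            weights=w, structural_missing=missing, node_ids=node_ids
        )
    return OracleCohort(
        nodes=nodes.reset_index(drop=True),
        subjects=subjects.reset_index(drop=True),
        matrices=matrices,
        metrics=metrics,
        truth=truth,
        clip_fraction=clip_fraction,
    )
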
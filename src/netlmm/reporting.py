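"""Quantitative outputs behind the figures: slope lines, slope surfaces,
representative networks, and the group density comparison.

The fitted model is linear, so each group's within-DMN relationship between
connection strength and a metric is a line whose slope is the control
group's slope plus that group's contrast estimate; in the GlobalT model the
slope is additionally affine in the (centered) GlobalT score, giving a
slope *surface* over the T grid.  Representative networks visualize what
the fixed effects imply: edge strengths are predicted at cohort-mean
covariates for a chosen group and GlobalT value, and the strongest fraction
of edges is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, GROUP_ORDER
from .connectome import network_density
from .design import EdgeTable, assemble_terms
from .lmm import GROUP_LABELS, ModelFit, group_contrast_vector, wald_test

__all__ = [
    "SlopeSurface",
    "slope_lines",
    "slope_surfaces",
    "representative_network",
    "group_density_comparison",
]

_METRIC_TERM = {"clustering": "clust", "efficiency": "eff"}
_GROUP_FLAGS = {
    "HIV-MJ-": (0.0, 0.0),
    "HIV+MJ-": (1.0, 0.0),
    "HIV-MJ+": (0.0, 1.0),
    "HIV+MJ+": (1.0, 1.0),
}


@dataclass
class SlopeSurface:
    """Metric slope of one group across a GlobalT grid (within the DMN)."""

    group: str
    metric: str
    location: str
    globalT_grid: np.ndarray
    slope: np.ndarray


def _require_model(fit: ModelFit, model: str, what: str) -> None:
    if fit.model != model:
        raise ValueError(f"{what} requires a {model} fit, got {fit.model}")


def _base_slope(fit: ModelFit, metric: str) -> float:
    m = _METRIC_TERM[metric]
    return float(fit.params[m] + fit.params[f"{m}:dmn_within"])


def slope_lines(fit: ModelFit) -> pd.DataFrame:
    """Per-group within-DMN strength-vs-metric lines from a model-1 fit.

    The control slope is the metric main effect plus its within-DMN
    interaction; each other group's slope adds that group's contrast
    estimate, so slope differences equal the tested contrasts exactly.
    """
    _require_model(fit, "model1", "slope_lines")
    rows = []
    for metric in ("clustering", "efficiency"):
        base = _base_slope(fit, metric)
        for group in GROUP_ORDER:
            if group == "HIV-MJ-":
                delta = 0.0
            else:
                L = group_contrast_vector(fit.model, group, "within", metric)
                delta = wald_test(fit, L).estimate
            intercept = float(fit.params["Intercept"] + fit.params["dmn_within"])
            for g in GROUP_LABELS.get(group, ()):
                intercept += float(fit.params[g] + fit.params[f"{g}:dmn_within"])
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "slope": base + delta,
                    "intercept": intercept,
                }
            )
    return pd.DataFrame(rows)


def slope_surfaces(fit: ModelFit, globalT_grid: np.ndarray) -> list[SlopeSurface]:
    """Within-DMN metric slope as a function of GlobalT, per group (model 2).

    ``slope(group, T) = base + group contrast + (T - T_bar) * (GlobalT
    moderation of the base slope + the group's moderation contrast)`` with
    ``T_bar`` the centering constant stored with the design.
    """
    _require_model(fit, "model2", "slope_surfaces")
    grid = np.asarray(globalT_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("globalT_grid must be a strictly increasing vector")
    t_bar = fit.centers.get("globalT", 0.0)
    out = []
    for metric in ("clustering", "efficiency"):
        m = _METRIC_TERM[metric]
        base = _base_slope(fit, metric)
        base_mod = float(fit.params[f"globalT:{m}"] + fit.params[f"globalT:{m}:dmn_within"])
        for group in GROUP_ORDER:
            if group == "HIV-MJ-":
                delta, mod_delta = 0.0, 0.0
            else:
                delta = wald_test(
                    fit, group_contrast_vector("model2", group, "within", metric)
                ).estimate
                mod_delta = wald_test(
                    fit,
                    group_contrast_vector(
                        "model2", group, "within", metric, moderated_by_globalT=True
                    ),
                ).estimate
            slope = base + delta + (grid - t_bar) * (base_mod + mod_delta)
            out.append(
                SlopeSurface(
                    group=group,
                    metric=metric,
                    location="within",
                    globalT_grid=grid,
                    slope=slope,
                )
            )
    return out


def representative_network(
    fit: ModelFit,
    group: str,
    globalT_value: float,
    cohort: Cohort,
    retain_fraction: float = 0.15,
    table: EdgeTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-representative network implied by the fixed effects (model 2).

    Edge strengths are predicted with edge covariates at their cohort
    means, the group indicators set for the requested group, and GlobalT
    set to the requested score; the top ``retain_fraction`` of edges by
    predicted strength is retained.  Returns a node table (group-mean nodal
    metrics plus the group's slopes at this GlobalT, for sizing/coloring)
    and an edge list with predicted strengths.
    """
    _require_model(fit, "model2", "representative_network")
    if group not in _GROUP_FLAGS:
        raise ValueError(f"unknown group '{group}'")
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must lie in (0, 1]")
    t = cohort.subjects["globalT"]
    if globalT_value < t.min() - 10 or globalT_value > t.max() + 10:
        warnings.warn(
            f"GlobalT {globalT_value} is far outside the observed range "
            f"[{t.min():.1f}, {t.max():.1f}]"
        )
    if table is None:
        table = cohort.edge_table()
    summary = (
        table.df.groupby(["node_i", "node_j"], sort=True)
        .agg(
            clust=("clust_mean", "mean"),
            eff=("eff_mean", "mean"),
            dist=("dist", "mean"),
            dist2=("dist2", "mean"),
            edge_class=("edge_class", "first"),
        )
        .reset_index()
    )
    n_edges = len(summary)
    hiv, mj = _GROUP_FLAGS[group]
    const = np.ones(n_edges)
    components = {
        "hiv": hiv * const,
        "mj": mj * const,
        "hivmj": hiv * mj * const,
        "clust": summary["clust"].to_numpy(),
        "eff": summary["eff"].to_numpy(),
        "dmn_within": (summary["edge_class"] == "within_dmn").to_numpy(float),
        "dmn_between": (summary["edge_class"] == "between").to_numpy(float),
        "dist": summary["dist"].to_numpy(),
        "dist2": summary["dist2"].to_numpy(),
        "age": 0.0 * const,
        "education": 0.0 * const,
        "rmd": 0.0 * const,
        "sex": float(table.df["sex"].mean()) * const,
        "race": float(table.df["race"].mean()) * const,
        "globalT": (globalT_value - fit.centers.get("globalT", 0.0)) * const,
    }
    X = assemble_terms(components, list(fit.params.index))
    summary["predicted_strength"] = X @ fit.params.to_numpy()
    k = int(round(retain_fraction * n_edges))
    edges = (
        summary.sort_values("predicted_strength", ascending=False, kind="stable")
        .head(k)[["node_i", "node_j", "predicted_strength", "edge_class"]]
        .reset_index(drop=True)
    )

    members = cohort.subjects.loc[
        (cohort.subjects["hiv"] == hiv) & (cohort.subjects["mj"] == mj), "subject_id"
    ].astype(str)
    met = pd.concat([cohort.metrics[s] for s in members])
    node_means = met.groupby("node_id")[["clustering", "efficiency"]].mean()
    nodes_out = cohort.nodes.copy()
    nodes_out["clustering"] = node_means["clustering"].reindex(
        nodes_out["node_id"]
    ).to_numpy()
    nodes_out["efficiency"] = node_means["efficiency"].reindex(
        nodes_out["node_id"]
    ).to_numpy()
    grid = np.array([globalT_value - 1.0, globalT_value + 1.0])
    surfaces = {
        s.metric: s for s in slope_surfaces(fit, grid) if s.group == group
    }
    for metric in ("clustering", "efficiency"):
        s = surfaces[metric]
        mid = float(np.interp(globalT_value, s.globalT_grid, s.slope))
        nodes_out[f"slope_{metric}"] = mid
    return nodes_out, edges


def group_density_comparison(cohort: Cohort) -> pd.DataFrame:
    """Per-group network density and Welch t-tests versus the control group."""
    subs = cohort.subjects
    groups = [g for g in GROUP_ORDER if g in set(subs["group"])]
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    dens = {
        g: np.array(
            [
                network_density(cohort.matrices[s])
                for s in subs.loc[subs["group"] == g, "subject_id"].astype(str)
            ]
        )
        for g in groups
    }
    for g, d in dens.items():
        if len(d) < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    control = dens["HIV-MJ-"]
    rows = []
    for g in groups:
        d = dens[g]
        if g == "HIV-MJ-":
            t, p = np.nan, np.nan
        elif np.ptp(d) == 0 and np.ptp(control) == 0 and d[0] == control[0]:
            t, p = 0.0, 1.0  # identical constant densities: no evidence at all
        else:
            t, p = stats.ttest_ind(d, control, equal_var=False)
        rows.append(
            {
                "group": g,
                "n": len(d),
                "density_mean": float(d.mean()),
                "density_sd": float(d.std(ddof=1)),
                "t_vs_control": float(t) if np.isfinite(t) else np.nan,
                "p_vs_control": float(p) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(rows)
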
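"""Edge-level linear mixed-effects model, contrasts, and adaptive FDR.

The strength model is

.. math:: S_{ke} = x_{ke}^\\top \\beta + b_k + \\varepsilon_{ke},
          \\qquad b_k \\sim N(0, \\sigma_b^2),\\
          \\varepsilon_{ke} \\sim N(0, \\sigma_e^2),

with one row per (subject *k*, edge *e*) and a subject random intercept
absorbing within-subject correlation of edge strengths.  With
:math:`V_0 = I + \\lambda Z Z^\\top` and :math:`\\lambda =
\\sigma_b^2/\\sigma_e^2`, both :math:`\\beta` and :math:`\\sigma_e^2` have
closed forms given :math:`\\lambda`, so (RE)ML reduces to a 1-D
optimization over :math:`\\log\\lambda`; the grouped structure makes every
evaluation O(G p^2 + p^3) via rank-one downdates of the per-subject
cross-products.  This keeps desk-scale cohorts (10^5 rows) in the
sub-second range.

Group differences versus the HIV-MJ- control are tested with contrast
statements: fixed linear combinations of the fitted interaction
coefficients, with Wald z inference (row counts are large enough that
degrees-of-freedom corrections are negligible) and two-stage adaptive FDR
across each model's family of twelve contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .design import DesignMatrix, METRICS

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "ContrastResult",
    "fit_lmm",
    "group_contrast_vector",
    "wald_test",
    "contrast_table",
    "adaptive_fdr",
    "collinearity_check",
    "likelihood_ratio_pvalue",
    "GROUP_LABELS",
    "CONTRAST_GRID",
]

#: non-control groups, as (label, component-indicator) pairs; the HIV+MJ+
#: cell difference vs control is the sum of all three indicator effects
GROUP_LABELS = {
    "HIV+MJ-": ("hiv",),
    "HIV-MJ+": ("mj",),
    "HIV+MJ+": ("hiv", "mj", "hivmj"),
}

#: the 12 contrasts reported per model: 3 groups x 2 locations x 2 metrics
CONTRAST_GRID = list(product(GROUP_LABELS, ("within", "outside"), ("clustering", "efficiency")))

_METRIC_TERM = {"clustering": "clust", "efficiency": "eff"}


@dataclass
class ModelFit:
    """REML (or ML) fit of the edge-strength mixed model."""

    params: pd.Series
    cov_params: pd.DataFrame
    sigma_b: float
    sigma_e: float
    loglik: float
    n_rows: int
    n_subjects: int
    converged: bool
    method: str
    model: str
    centers: dict[str, float]


@dataclass
class ContrastResult:
    """A tested contrast: estimate, Wald SE/z/p, and (optionally) adjusted p."""

    label: str
    weights: pd.Series
    estimate: float
    se: float
    z: float
    p: float
    p_adj: float | None = None


def _rank_check(XtX: np.ndarray, columns: list[str]) -> None:
    # pivoted QR of the (p x p) cross-product; columns beyond the numerical
    # rank are linearly dependent on earlier ones
    from scipy.linalg import qr as scipy_qr

    scale = np.sqrt(np.maximum(np.diag(XtX), 1e-300))
    corr = XtX / np.outer(scale, scale)
    _, r, piv = scipy_qr(corr, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * len(columns) * np.finfo(float).eps * 100
    bad = [columns[piv[j]] for j in np.flatnonzero(diag < tol)]
    if bad:
        raise ValueError(f"design matrix is rank deficient; dependent columns: {bad}")


def fit_lmm(design: DesignMatrix, reml: bool = True) -> ModelFit:
    """Fit the subject-random-intercept mixed model by (RE)ML.

    The variance ratio :math:`\\lambda = \\sigma_b^2/\\sigma_e^2` is profiled
    out and optimized on the log scale (bounded scalar minimization,
    relative tolerance 1e-6); :math:`\\lambda = 0` (pure OLS) is checked as
    a boundary candidate.  Non-convergence is reported honestly through the
    ``converged`` flag rather than raised.
    """
    X, y = design.X, design.y
    n, p = X.shape
    codes, inverse = np.unique(design.groups, return_inverse=True)
    g = len(codes)
    if g < 2:
        raise ValueError("at least 2 subjects are required")

    order = np.argsort(inverse, kind="stable")
    Xs, ys = X[order], y[order]
    counts = np.bincount(inverse, minlength=g).astype(float)
    bounds = np.concatenate([[0], np.cumsum(counts).astype(int)])
    S = np.add.reduceat(Xs, bounds[:-1], axis=0)  # per-subject column sums
    ysum = np.add.reduceat(ys, bounds[:-1])
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    _rank_check(XtX, design.columns)

    def crossprods(lam: float):
        c = lam / (1.0 + lam * counts)
        A = XtX - (S * c[:, None]).T @ S
        b = Xty - S.T @ (c * ysum)
        q = yty - float(c @ (ysum**2))
        return A, b, q

    dof = n - p if reml else n

    def neg2ll(loglam: float) -> float:
        lam = np.exp(loglam)
        A, b, q = crossprods(lam)
        try:
            cho = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        beta = cho_solve(cho, b)
        rss = max(q - float(beta @ b), 1e-300)
        val = dof * np.log(rss / dof) + float(np.sum(np.log1p(lam * counts)))
        if reml:
            val += 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        return val

    res = optimize.minimize_scalar(
        neg2ll, bounds=(-25.0, 12.0), method="bounded", options={"xatol": 1e-8}
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn("variance-ratio optimization did not converge", RuntimeWarning)
        logger.warning("fit_lmm: optimizer reported non-convergence: %s", res)
    lam = float(np.exp(res.x))
    # boundary candidate: no subject-level variance at all
    at_zero = _neg2ll_ols(XtX, Xty, yty, dof, reml)
    if at_zero <= res.fun + 1e-10:
        lam = 0.0

    A, b, q = crossprods(lam)
    cho = cho_factor(A, lower=True)
    beta = cho_solve(cho, b)
    rss = max(q - float(beta @ b), 1e-300)
    sigma2 = rss / dof
    crit = dof * np.log(sigma2) + float(np.sum(np.log1p(lam * counts))) + dof
    if reml:
        crit += 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    loglik = -0.5 * (crit + dof * np.log(2 * np.pi))
    cov = sigma2 * cho_solve(cho, np.eye(p))
    cov = (cov + cov.T) / 2.0

    return ModelFit(
        params=pd.Series(beta, index=design.columns),
        cov_params=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        sigma_b=float(np.sqrt(lam * sigma2)),
        sigma_e=float(np.sqrt(sigma2)),
        loglik=float(loglik),
        n_rows=n,
        n_subjects=g,
        converged=converged,
        method="reml" if reml else "ml",
        model=design.model,
        centers=dict(design.centers),
    )


def _neg2ll_ols(XtX, Xty, yty, dof, reml) -> float:
    cho = cho_factor(XtX, lower=True)
    beta = cho_solve(cho, Xty)
    rss = max(yty - float(beta @ Xty), 1e-300)
    val = dof * np.log(rss / dof)
    if reml:
        val += 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return val


def group_contrast_vector(
    model: str,
    group: str,
    location: str,
    metric: str,
    moderated_by_globalT: bool = False,
) -> pd.Series:
    """Contrast weights for a group-vs-control slope difference.

    ``location='outside'`` selects the group x metric interaction terms
    only; ``'within'`` adds the corresponding three-way terms with the
    within-DMN indicator.  With ``moderated_by_globalT`` the same pattern is
    applied to the GlobalT-moderation terms (model 2 only), testing the
    group difference in how GlobalT shifts the metric slope.
    """
    from .design import model_terms

    if group not in GROUP_LABELS:
        raise ValueError(f"unknown group '{group}'")
    if location not in ("within", "outside"):
        raise ValueError(f"unknown location '{location}'")
    if metric not in _METRIC_TERM:
        raise ValueError(f"unknown metric '{metric}'")
    if moderated_by_globalT and model != "model2":
        raise ValueError("GlobalT moderation contrasts require model2")
    m = _METRIC_TERM[metric]
    terms = []
    for g in GROUP_LABELS[group]:
        terms.append(f"{g}:{m}")
        if location == "within":
            terms.append(f"{g}:{m}:dmn_within")
    if moderated_by_globalT:
        terms = [f"globalT:{t}" for t in terms]
    all_terms = model_terms(model)
    missing = [t for t in terms if t not in all_terms]
    if missing:
        raise ValueError(f"terms not in {model}: {missing}")
    weights = pd.Series(0.0, index=all_terms)
    weights[terms] = 1.0
    return weights


def wald_test(fit: ModelFit, L: pd.Series, label: str = "") -> ContrastResult:
    """Wald z-test of the linear combination ``L @ beta``."""
    L = pd.Series(L)
    unknown = [t for t in L.index if t not in fit.params.index]
    if unknown:
        raise ValueError(f"contrast refers to unknown terms: {unknown}")
    L = L.reindex(fit.params.index, fill_value=0.0)
    v = L.to_numpy()
    if np.all(v == 0):
        raise ValueError("contrast vector is all zeros")
    est = float(v @ fit.params.to_numpy())
    var = float(v @ fit.cov_params.to_numpy() @ v)
    se = float(np.sqrt(max(var, 0.0)))
    z = est / se if se > 0 else 0.0
    p = float(min(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)), 1.0))
    return ContrastResult(label=label, weights=L, estimate=est, se=se, z=z, p=p)


def contrast_table(
    fit: ModelFit,
    moderated_by_globalT: bool = False,
    q: float = 0.05,
) -> pd.DataFrame:
    """The model's twelve group contrasts with adaptive-FDR adjusted p-values.

    Mirrors the published result tables: one row per (group, DMN location,
    metric) with the estimated slope difference versus the control group.
    """
    rows = []
    for group, location, metric in CONTRAST_GRID:
        L = group_contrast_vector(fit.model, group, location, metric, moderated_by_globalT)
        label = f"{group} / {'Within' if location == 'within' else 'Outside'} DMN / {metric}"
        rows.append((group, location, metric, wald_test(fit, L, label=label)))
    p_adj, reject = adaptive_fdr([r[3].p for r in rows], q=q)
    records = []
    for (group, location, metric, res), pa, rej in zip(rows, p_adj, reject):
        res.p_adj = float(pa)
        records.append(
            {
                "group": group,
                "location": location,
                "metric": metric,
                "estimate": res.estimate,
                "se": res.se,
                "z": res.z,
                "p": res.p,
                "p_adj": float(pa),
                "significant": bool(rej),
            }
        )
    return pd.DataFrame.from_records(records)


def _bh_reject(pvals: np.ndarray, level: float) -> int:
    """Number of Benjamini-Hochberg step-up rejections at the given level."""
    m = len(pvals)
    order = np.sort(pvals)
    thresh = level * np.arange(1, m + 1) / m
    passed = np.flatnonzero(order <= thresh)
    return int(passed[-1] + 1) if passed.size else 0


def _two_stage_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Rejection flags of the two-stage adaptive step-up procedure at level q."""
    m = len(pvals)
    r1 = _bh_reject(pvals, q / (1.0 + q))
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, dtype=bool)
    r2 = _bh_reject(pvals, q * m / m0)
    cutoff = np.sort(pvals)[r2 - 1] if r2 > 0 else -np.inf
    return pvals <= cutoff


def adaptive_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage adaptive false discovery rate control.

    Stage 1 runs a Benjamini-Hochberg step-up at level ``q/(1+q)`` to
    estimate the number of true nulls ``m0 = m - r1``; stage 2 reruns the
    step-up at level ``q * m / m0``.  If stage 1 rejects nothing, nothing is
    rejected; if it rejects everything, everything is.  Adjusted p-values
    are the smallest level at which each hypothesis would be rejected
    (found by bisection; the procedure is monotone in ``q``).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals <= 0) | (pvals > 1)) or np.any(np.isnan(pvals)):
        raise ValueError("p-values must lie in (0, 1]")
    reject = _two_stage_reject(pvals, q)
    ever = _two_stage_reject(pvals, 1.0 - 1e-12)
    p_adj = np.ones(len(pvals))
    for i in range(len(pvals)):
        if not ever[i]:
            continue
        lo, hi = 0.0, 1.0
        for _ in range(50):
            mid = (lo + hi) / 2.0
            if mid > 0 and _two_stage_reject(pvals, mid)[i]:
                hi = mid
            else:
                lo = mid
        p_adj[i] = hi
    return p_adj, reject


def collinearity_check(
    design: DesignMatrix, contrast_terms: list[str] | None = None
) -> pd.DataFrame:
    """Correlations between each metric column and its interaction columns.

    Mean-centering the continuous covariates is what keeps these benign;
    any pair with ``|r| > 0.95`` is flagged as problematic collinearity.
    """
    frame = design.frame()
    metric_terms = [t for t in design.columns if t in ("clust", "eff")]
    rows = []
    for m in metric_terms:
        partners = [
            t
            for t in design.columns
            if t != m and m in t.split(":")
            and (contrast_terms is None or t in contrast_terms)
        ]
        base = frame[m]
        for t in partners:
            r = float(np.corrcoef(base, frame[t])[0, 1])
            rows.append(
                {"metric": m, "interaction": t, "r": r, "flagged": bool(abs(r) > 0.95)}
            )
    return pd.DataFrame.from_records(rows)


def likelihood_ratio_pvalue(design: DesignMatrix, term: str) -> float:
    """LRT p-value for dropping a single fixed-effect column (ML refits)."""
    if term not in design.columns:
        raise ValueError(f"unknown term '{term}'")
    full = fit_lmm(design, reml=False)
    keep = [j for j, t in enumerate(design.columns) if t != term]
    reduced = DesignMatrix(
        X=design.X[:, keep],
        columns=[design.columns[j] for j in keep],
        y=design.y,
        groups=design.groups,
        model=design.model,
        centers=design.centers,
    )
    red = fit_lmm(reduced, reml=False)
    lr = max(2.0 * (full.loglik - red.loglik), 0.0)
    return float(stats.chi2.sf(lr, df=1))
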
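# Methods

## Network construction

Per subject, regional time series (one column per node, one or more runs)
are column-standardized within run, concatenated in time, and correlated
(plain Pearson; a Fisher-z switch exists in the config but defaults off,
since nothing downstream requires variance stabilization).  Two filters
follow:

* negative correlations are set to zero — they remain *observed* edges of
  weight zero;
* node pairs whose centroids lie strictly closer than 20 mm are
  **structurally missing**: their connectivity is never computed (motion
  artificially inflates short-range correlations).  They are excluded from
  the edge design and from the density denominator, and are treated as
  absent edges by the graph metrics.

Subjects with relative mean displacement (RMD) of 0.3 mm or more fail QC
and are dropped, with a per-subject exclusion log.  Both thresholds are
strict inequalities.

## Graph metrics

Two nodal metrics summarize small-world organization on the weighted,
nonnegative, filtered matrix:

* **Onnela weighted clustering**: weights are normalized by the
  matrix-wide maximum, and `C_i` is the mean geometric triangle intensity
  `(ŵ_ij ŵ_ih ŵ_jh)^{1/3}` over ordered neighbor pairs, divided by
  `k_i (k_i − 1)`; `C_i = 0` for degree < 2.  An all-zero matrix yields
  all-zero clustering rather than an error.
* **Nodal global efficiency**: edge length is `1/w`; all-pairs shortest
  paths are computed by Dijkstra; `E_i` is the mean of `1/d_ij` over the
  other `n − 1` nodes with unreachable pairs contributing zero (the
  denominator is not reduced).

The `1/w` length map was chosen over `−log w` for interpretability (an
edge of weight 0.5 is "twice as long" as a unit edge); with max-normalized
weights both metrics live in [0, 1].  Tests verify both metrics against
brute-force oracles (triple enumeration; Floyd–Warshall and exhaustive
simple-path enumeration) and against networkx's Onnela clustering.

## Edge design

One row per subject and per retained edge (non-missing, strictly positive
strength; zero-strength edges belong to the "presence" half of a two-part
framework and are excluded from this strength model).  Covariates:
endpoint-averaged clustering and efficiency; Euclidean distance and its
square (squared **before** centering); an edge class with three levels —
within-DMN, between (one endpoint in the DMN), outside — coded as two
indicators with *outside* as reference; group indicators HIV, MJ and their
product HIVMJ (so group-vs-control differences are coefficient sums);
GlobalT; and age, sex, race, education, RMD.  All continuous covariates
are grand-mean centered over edge rows (the centering constants are stored
with the table; GlobalT's is needed later to place raw T-scores on the
model scale), and interaction columns are products of the already-centered
parents.  Model 1 enumerates to exactly 43 named columns, model 2 to 79.

## Mixed model and inference

The strength model has a subject random intercept only — the simplest
structure consistent with treating motion and demographics as fixed
effects; random metric slopes were considered and left out as the
generator has no subject-level slope heterogeneity to estimate.  With
`V₀ = I + λZZᵀ` and `λ = σ_b²/σ_e²`, both β and σ_e² are profiled out in
closed form, so REML (default; ML by flag, used by the likelihood-ratio
helper) reduces to a bounded 1-D search over `log λ` with the `λ = 0`
boundary checked explicitly; per-subject rank-one downdates make each
evaluation O(G·p² + p³).  The fit agrees with statsmodels MixedLM to
numerical precision (dual-route test), but runs in milliseconds at 10⁵
rows, which the replicate studies need.

Contrasts are Wald z tests: edge-row counts are ~10⁵, so normal
approximation is appropriate and degrees-of-freedom corrections are
negligible.  Each model's family of twelve contrasts (3 groups × 2
locations × 2 metrics) is adjusted together by **two-stage adaptive FDR**:
stage 1 runs the Benjamini–Hochberg step-up at `q/(1+q)` to estimate the
number of true nulls `m₀ = m − r₁`; stage 2 reruns BH at `q·m/m₀`.
Adjusted p-values are obtained by bisection on `q` (the procedure is
monotone in `q`).  Collinearity between metric columns and their
interaction terms is monitored (|r| > 0.95 flags); grand-mean centering
keeps the default design's largest |r| around 0.7.

## Synthetic cohorts and oracle mode

The generator emulates the study conditions: four balanced groups;
GlobalT, age, education drawn normal with the published per-group means
and SDs (e.g. GlobalT 50.45 ± 5.91 for controls, 47.27 ± 5.21 for
HIV+MJ+); sex and race Bernoulli with the published proportions (one
subject is flipped if a tiny table draws a constant column, which would
make a confounder inestimable); RMD truncated inside the (0, 0.3) mm QC
window.  Node layouts place 20 of 80 nodes as a spatially coherent DMN
cluster (isotropic normal, SD 40 mm) inside a 160 mm box.

Reference networks have mean weight `exp(−d/60 mm) − 0.2` plus a 0.15
within-DMN increment; subject noise is a per-node hub factor
`u_i ~ N(0, 0.30)` entering every incident edge plus i.i.d. edge noise
(SD 0.05), and weights are clipped to [0, 1].  The negative baseline
shift makes weak long-range pairs drop out, so reference networks are
realistically sparse (density ≈ 0.5, mimicking the zeroing of negative
correlations), and the hub factors give the node-strength heterogeneity
real connectomes show.  These two ingredients were calibrated once so
that the nodal metrics carry enough variation that is not collinear with
distance for the metric-slope contrasts to be identifiable at desk scale
(and so that clustering and efficiency are only moderately correlated,
r ≈ 0.5); without them the metric covariates are almost deterministic
functions of geometry and the contrast SEs blow up several-fold.

**Oracle mode** computes each subject's nodal metrics on its reference
network, freezes them as covariates, lays out one row per eligible
reference edge, and draws strengths from the linear predictor
`S = Xβ + b_k + ε` (clipped to [0, 1]; the clipping fraction at defaults
is ~0, well under the 5% bias guard).  Because the covariates are frozen,
refitting recovers β exactly in expectation — the *endogenous* regime of
real data, where metrics are computed from the same networks being
modeled, has no such closed-form truth, which is why the recovery suites
use oracle mode.  The default generative coefficients reproduce the
published group-difference estimates exactly as contrasts (the
single-indicator groups pin the HIV/MJ terms; the HIV+MJ+ cell pins the
HIVMJ terms as remainders), with unremarkable baseline effects elsewhere
(intercept 0.5, weak distance decay, small confounder effects, and
GlobalT drifts making the control group's clustering slope fall and its
efficiency slope rise with T).

What the generator does **not** emulate: BOLD time series, motion or
physiological noise (strengths are generated at the network level), an
empirical edge-strength distribution (the clipped Gaussian is a modeling
choice), or endogenous metric feedback.  Passing recovery tests therefore
demonstrates correctness of the design/fit/contrast machinery under the
assumed statistical structure, not robustness to real fMRI artifacts.

## Reporting

Slope lines (model 1) share their code path with the contrasts, so slope
differences equal contrast estimates to machine precision.  Slope surfaces
(model 2) are affine in GlobalT by construction: `slope(group, T) = base +
group contrast + (T − T̄)·(GlobalT moderation terms)`, evaluated by default
at the published anchor scores 38 and 60.  Representative networks predict
every edge's strength from the fixed effects at cohort-mean covariates
with the group indicators and GlobalT set as requested, and retain the top
15% by predicted strength (the original construction is supplementary
material not available here; top-fraction retention is a reproducible
stand-in that is monotone in the fitted slopes).  Group density uses Welch
t-tests versus control, with p = 1 returned for identical constant
densities.

## Problem sizes, tolerances, degenerate inputs

* Default recovery cohorts: 80 nodes / 20 DMN / 15 subjects per group
  (~10⁵ edge rows); replicate studies (null calibration: 200 cohorts;
  coverage/unbiasedness: 100 cohorts; density calibration: 20 cohorts)
  run on 30–40-node cohorts so the whole suite stays in a few minutes.
* Variance-ratio optimization: bounded search on `log λ ∈ [−25, 12]`,
  `xatol 1e−8`; honest `converged` flag; rank deficiency reported with the
  names of dependent columns; constant design columns are an error naming
  the column.
* Figure-logic sign checks run on low-noise cohorts (σ_e = 5·10⁻⁴): they
  verify the reporting algebra and the published sign structure, not
  sampling noise, which the recovery and calibration suites cover.
* At the prescribed recovery scale the contrast SEs are ≈ 0.025
  (efficiency) and ≈ 0.055 (clustering) against generative effects of
  0.012–0.037, so recovery is assessed at ±2 SE and is unbiased but not
  sharp: a variance floor follows from the within-DMN cell sizes (≈ 2.2k
  rows per group at 20 DMN nodes and 15 subjects) with σ_e = 0.05 and
  bounded metric spread, and cannot be engineered away by generator
  settings.  The GlobalT moderation contrasts are considerably sharper
  (SE ≈ 0.006) because the T-score spread multiplies the identifying
  variance.

## Known limitations

* The strength model ignores spatial autocorrelation across edges beyond
  the subject intercept.
* Only the strength half of the two-part (presence + strength) framework
  is implemented.
* Contrasts are linear functionals of a single fitted model; no two-step
  residual refitting.
* No binary-graph metrics and no randomized-reference small-world index;
  clustering and efficiency were chosen as simple, well-defined measures.
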
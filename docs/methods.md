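# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## The FSOR objective

Feature selection with orthogonal regression (FSOR) ranks genes by fitting

```
min_{W, b, phi}  || W^T Phi X + b 1_n^T - Y ||_F^2
s.t.  W^T W = I_k,   phi >= 0,
```

where `X` (d genes × n samples, log2 scale) is the expression matrix,
`Phi = diag(phi)` carries one nonnegative importance weight per gene, `W`
(d × k) is an orthogonal projection, `b` a bias, and `Y` (k × n) a label
matrix built from survival information. Setting the gradient in `b` to zero
gives `b = (1/n)(Y 1 - W^T Phi X 1)`, and substituting it back centers both
sides:

```
min || W^T Phi X M - Y M ||_F^2,    M = I_n - (1/n) 1 1^T.
```

`M` is symmetric and idempotent; it is applied implicitly as row-mean
subtraction (O(dn)) and never materialized.

The label matrix combines a one-hot encoding of vital status with survival
time. The combination rule is not canonical; we use k = 3 rows — the
alive/censored indicator, the dead indicator, and follow-up time min–max
normalized to [0, 1] — which keeps all rows on comparable scales, with a
k = 2 status-only scheme as an option. Censored patients contribute a
status-0 row and their (normalized) censoring time; the label matrix does
not distinguish censoring from long survival, which is a known limitation
of this supervision scheme.

## The W-step: generalized power iteration

With `phi` fixed, the problem reduces to a quadratic program on the Stiefel
manifold,

```
min_{W^T W = I} Tr(W^T C W - 2 W^T D),
C = Phi X M X^T Phi^T,  D = Phi X M Y^T,
```

solved by generalized power iteration (GPI) on the equivalent maximization
of `Tr(W^T C~ W) + 2 Tr(W^T D)` with `C~ = alpha I - C`. Taking `alpha`
exactly at the dominant eigenvalue of `C` leaves `C~` singular, so we use
`alpha = lambda_max(C) (1 + eps) + eps` with `eps = alpha_margin = 1e-6`,
which guarantees positive definiteness. Each sweep replaces `W` by the
polar factor `U V^T` of `G = 2 C~ W + 2 D`; this never decreases the
relaxed objective, and the sweep stops when `||W_{t+1} - W_t||_F <= 1e-8`
or after 500 sweeps.

GPI is only locally convergent: non-global fixed points of the polar map
can be attracting (easily exhibited at d = 2, k = 1). `solve_w_gpi`
therefore restarts the sweep from a small deterministic set of initial
points — the caller's `W0`, the orthogonal-Procrustes polar factor of `D`
(optimal when `C` is a multiple of the identity), and the eigenvectors of
the k smallest eigenvalues of `C` (optimal when `D = 0`) — and returns the
best iterate. The warm start `W0` stays in the set, so the outer objective
cannot increase through the W-step.

## The phi-step: augmented Lagrangian

With `W` fixed, the diagonal-matrix trace identity
`Tr(A B A C) = a^T (B^T ∘ C) a` reduces the problem to the quadratic
program

```
min_{phi >= 0} phi^T H phi - phi^T r,
H = (X M X^T) ∘ (W W^T),   r = diag(2 X M Y^T W^T),
```

where `∘` is the Hadamard product. `H` is positive semidefinite by the
Schur product theorem, since both factors are PSD. We additionally enforce
the simplex constraint `phi^T 1 = 1`: the weights are relative importances,
and without a scale constraint the objective is minimized by shrinking
`phi` toward zero. (The constraint appears only inside the augmented
Lagrangian's penalty term in the source formulation; we treat it as part of
the feasible set and note the discrepancy.)

The augmented Lagrangian introduces a nonnegative slack `v` and multipliers
`lambda_1` (vector, for `phi = v`) and `lambda_2` (scalar, for the simplex):

* phi-update: solve `J phi = g` with `J = 2H + mu I + mu 1 1^T` and
  `g = mu v + mu 1 - lambda_2 1 - lambda_1 + r`. `J` is obtained by setting
  the gradient of the augmented Lagrangian in `phi` to zero; it is the
  unique matrix for which this linear system reproduces the stated `g`.
* v-update: `v = max(phi + lambda_1 / mu, 0)` (projection onto the
  nonnegative orthant).
* Multipliers: first-order updates
  `lambda_1 += mu (phi - v)`, `lambda_2 += mu (phi^T 1 - 1)`, and penalty
  inflation `mu <- rho mu` with `mu_0 = 1`, `rho = 1.1`.
* Stop when `max(||phi - v||_inf, |phi^T 1 - 1|) <= 1e-6`, cap 200
  iterations; the best (least-infeasible) iterate is returned with a
  convergence flag, then projected onto the nonnegative orthant and
  renormalized so the returned weights always satisfy the constraints
  exactly.

On random PSD instances the ALM solution matches a 0.001-step grid search
over the simplex to better than 1e-4 in objective.

A practical property worth knowing: the minimizer of a strictly convex QP
on the simplex is typically sparse. At pipeline scale (d ~ 100, k = 3) the
fitted `phi` concentrates on a handful of genes; the ordering among the
near-zero weights is then numerically arbitrary. At larger d (the intended
design point, d ~ 10^3) the weight distribution is more graded.

## Outer alternation

`fit_fsor` initializes `phi = 1/d` and `W` from a seeded QR factorization
of a standard-normal draw, then alternates the W-step and phi-step,
rebuilding `C, D` and `H, r` from the current iterates. Because the ALM is
inexact, a candidate `phi` is accepted only if it does not increase the
centered objective by more than the ALM tolerance; otherwise the incumbent
is kept. The loop stops when the objective changes by at most `outer_tol`
(default 0.1, the published convergence setting; note it is scale-dependent
and exposed as an option) or after 1000 iterations. The model records the
objective and a feasibility triple (Stiefel error, min weight, simplex
error) per outer iteration. Genes are ranked by `phi` descending with
lexicographic tie-breaks.

## Meta-analytic DEG filter

Per study and gene, the standardized mean difference between tumor and
normal groups is Hedges' g: the pooled-SD mean difference scaled by the
small-sample factor `J(m) = 1 - 3/(4m - 1)`, `m = n1 + n2 - 2`, with
sampling variance `(n1+n2)/(n1 n2) + g^2 / (2(n1+n2))`. Studies are pooled
by DerSimonian–Laird: the homogeneity statistic `Q` gives the moment
estimate `tau^2 = max(0, (Q - (s-1)) / (sum w - sum w^2 / sum w))`, and the
combined effect is the inverse-variance mean under weights
`1/(var_i + tau^2)`, with a two-sided normal-approximation p-value. Genes
observed in fewer than 2 studies are pooled over what is available
(`tau^2 = 0`) and flagged. Multiple testing uses Benjamini–Hochberg (the
standard reading of "FDR at 0.05"); the DEG rule is strict
`|CombinedES| > 1.0` with `FDR <= 0.05`.

`batch_adjust` is a deliberately simple location/scale surrogate — per-gene
z-scoring within each batch, rescaled to the gene's global moments. It is
not an empirical-Bayes method and makes no attempt to preserve small-batch
effect estimates; it exists so the pipeline can be exercised end-to-end on
batch-confounded synthetic data.

## Prognostic model construction

* Univariate Cox proportional-hazards screen per gene (lifelines, Efron tie
  handling): beta, HR = exp(beta), 95% CI, Wald p.
* Candidate rule: keep genes with univariate HR >= 1 — risk-increasing
  genes only, no p-value condition (a marginally non-significant gene can
  still enter the multivariate model).
* Bidirectional stepwise search minimizing
  `BIC = -2 log PL + q log(n_events)`, scanning additions and deletions in
  candidate order with lexicographic tie-breaks (deterministic); covariates
  whose fit fails to converge are skipped and logged. BIC is the selection
  criterion; the concordance index is reported as a diagnostic only.
* Risk score: `LP = sum_m beta_m expr_m` and relative hazard `exp(LP)`.
  No baseline hazard is estimated — the score ranks patients, it is not an
  absolute risk. The literal published eight-gene LUAD signature is
  available via `published_luad_signature()`; its printed weights coincide
  with the multivariate hazard ratios rather than log-hazards, so both
  weightings (`hr`, the printed form, and `log_hr`) are offered.
* Stratification: median split by default (ties to low), quantile cut
  optional; groups are compared by Kaplan–Meier curves and the two-group
  log-rank test (chi-square, 1 df).

## Time-dependent ROC

Cumulative-case/dynamic-control ROC at horizon t: cases are subjects with
an observed event by t, controls those event-free past t. Under the default
`ipcw` method both groups are reweighted by inverse Kaplan–Meier censoring
probabilities (`1/G(T_i^-)` for cases, `1/G(t)` for controls), so with no
censoring the estimator reduces *exactly* to the plain binary ROC/AUC; an
unweighted `uncensored` method is available. The AUC is the weighted
Mann–Whitney statistic with half-credit ties. Horizons are measured in
years at 365.25 days/year.

## LASSO–Cox comparator

The comparator fits the L1-penalized Cox partial likelihood over the
Coxnet regularization path (scikit-survival), scoring each penalty by the
Cox partial log-likelihood of the frozen linear predictor on held-out folds
(stratified by vital status, seeded) and refitting at the best penalty.
`compare_pipelines` runs the FSOR arm (FSOR ranking → top-m → HR screen →
stepwise BIC) and the LASSO arm on the same status-stratified split
(default 60% train, seeded; resubstitution available) and reports
per-horizon AUCs at 1–4 years plus 1–3y and 1–4y means.

## Network screens

The interaction graph is read from a STRING-export-style TSV (two gene
columns plus a combined score; 0–1000 scales are auto-detected and divided
down, overridable). The connectivity filter keeps candidates with at least
one edge inside the candidate-induced subgraph. Hubs are ranked by maximal
clique centrality, `MCC(v) = sum_{maximal cliques C ∋ v} (|C| - 1)!`, with
maximal cliques enumerated exactly by Bron–Kerbosch with pivoting; isolated
nodes score 0 by convention, and graphs above a configurable node-count
guard (default 5000) are refused rather than approximated.

## Synthetic data

The generators are pure functions of config + seed and define the
conditions under which the package is tested:

* **Multi-study two-group design** (default: 4 studies, 1000 genes, 30 up-
  and 30 down-regulated genes, standardized effects ~ N(1.5, 0.2), 30
  samples per group, study intercepts ~ N(0, 1), unit noise, baselines
  ~ N(7, 1) on the log2 scale) — sized after a typical small microarray
  meta-analysis.
* **Survival cohort** (default: 300 patients, 100 standardized genes in
  equicorrelated blocks of 10 at rho = 0.3, 5 prognostic genes with
  log-hazards uniform in [0.5, 1.0], Weibull baseline with shape 1.2 and
  scale 900 days, ~30% censoring): event times by inverse-transform
  sampling of the Cox model `h0(t) exp(LP)`; censoring is independent
  uniform with its scale tuned by bisection to the target rate — simpler
  than administrative censoring but adequate for testing. The Weibull scale
  puts the median event time near two years so 1–4-year horizons are
  observable.
* **FSOR testbed** (d genes, n samples, balanced two-class design,
  informative genes shifted by 2 SD): vital status equals the class
  indicator and follow-up is exponential with class-dependent scale, so the
  label matrix carries the class signal on all rows.

What the generators do **not** emulate: real LUAD expression distributions,
probe/platform effects, gene–gene regulatory structure beyond block
correlation, informative censoring, or covariate-dependent follow-up.
Passing tests therefore demonstrate algorithmic correctness and sane
statistical behavior at desk scale, not clinical performance.

## Problem sizes and numerics

Tests and the acceptance script run at deliberately modest sizes (solver
instances up to d = 200, n = 300; 20-cohort comparisons; 50-seed recovery
runs), chosen so the whole suite completes in minutes on one CPU while
keeping every statistical check adequately powered. Degenerate inputs fail
loudly: constant survival times break min–max normalization, constant
genes are skipped in the Cox screen with a log entry, singleton batches and
zero within-batch variance are rejected or left unadjusted, and an
all-identical risk-score vector refuses to stratify.

## Known limitations

* The simplex-constrained weights concentrate at small d (see above); the
  tail ordering of near-zero weights is not meaningful.
* The outer convergence threshold (0.1) is on the objective's own scale and
  should be tightened for very small or very large problems.
* The label matrix treats censoring as "alive", biasing supervision when
  censoring is heavy and informative.
* `batch_adjust` removes only location/scale batch effects.
* The log-rank test and KM utilities are two-group only, matching the
  high/low risk design.
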
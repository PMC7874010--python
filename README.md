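# fsor

Feature selection with orthogonal regression (FSOR) and the full
expression-based prognostic-model pipeline built around it.

## The problem

Building a gene-expression survival signature — for example an early-stage
lung adenocarcinoma risk model — involves a chain of statistical steps:
pooling differential expression across heterogeneous studies, reducing
thousands of genes to a tractable candidate set, fitting a multivariate Cox
model, and validating the resulting risk score. This package implements
that chain as a tested, seeded, reusable library plus CLI, with synthetic
generators so every stage can be exercised without downloading cohort data.

The core contribution is the FSOR feature-selection method: a supervised
weighted orthogonal regression

```
min_{W, b, φ}  ‖ Wᵀ Φ X + b 1ₙᵀ − Y ‖²_F    s.t.  WᵀW = I_k,  φ ≥ 0,
```

where X is the d×n log2 expression matrix, Φ = diag(φ) holds one
nonnegative importance weight per gene, W is a d×k orthogonal projection,
and Y is a k×n label matrix built from survival status and time. After
eliminating the bias b, the objective is minimized by alternating

* a **W-step** — a quadratic program on the Stiefel manifold, solved by
  generalized power iteration (SVD-based polar updates on
  C̃ = αI − ΦXMXᵀΦᵀ, with deterministic multi-start), and
* a **φ-step** — a nonnegative, sum-to-one quadratic program
  min φᵀHφ − φᵀr with H = (XMXᵀ)∘(WWᵀ), solved by an augmented
  Lagrangian method.

Genes are ranked by the fitted weights φ. Around the solver the package
provides: Hedges' g effect sizes with DerSimonian–Laird random-effects
pooling and a Benjamini–Hochberg |CombinedES| > 1, FDR ≤ 0.05 filter;
univariate Cox screening with an HR ≥ 1 rule; bidirectional stepwise
multivariate Cox under BIC; the linear risk score Σ βₘ·exprₘ with
median-split stratification, Kaplan–Meier/log-rank validation and
time-dependent ROC; an L1-penalized (LASSO) Cox comparator; and
maximal-clique-centrality hub ranking on a user-supplied interaction
network. See `docs/methods.md` for the full model description.

## Worked example

Simulate a 300-patient survival cohort with 100 genes of which 5 drive the
hazard, rank genes with FSOR, build the risk model, and validate it:

```python
import fsor

expr, clin, truth = fsor.simulate_survival_cohort(fsor.SurvSimConfig(seed=7))
Y = fsor.build_label_matrix(clin)                       # status one-hot + time
model = fsor.fit_fsor(expr, Y, fsor.FsorOptions(seed=7))
ranked = fsor.rank_features(model, 50)

screen = fsor.univariate_cox(expr.subset_genes([g for g, _ in ranked]), clin)
candidates = fsor.select_candidates(screen)             # HR >= 1
risk = fsor.stepwise_cox_bic(expr, clin, candidates)    # BIC stepwise

scores = fsor.risk_score(risk, expr)["linear_predictor"].to_numpy()
groups = fsor.stratify_risk(scores)                     # median split
_, chi2, p = fsor.km_logrank(clin, groups)
aucs = [fsor.time_dependent_roc(scores, clin, h).auc for h in (1, 2, 3, 4)]
```

With seed 7 the planted genes are G0011, G0051, G0055, G0064, G0093, and
the run prints:

```
objective: 93.8125 after 4 iterations
 1  G0055  0.3821
 2  G0064  0.2118
 3  G0011  0.2072
 4  G0093  0.1989
risk model: ['G0055', 'G0011', 'G0093', 'G0064', 'G0092']
log-rank chi2 184.56, p 4.9e-42
AUC 1y: 0.887   2y: 0.916   3y: 0.883   4y: 0.907
```

Four of the five planted genes carry essentially all the FSOR weight (the
simplex-constrained φ is sparse; the fifth gene's signal is absorbed by its
correlated block), the stepwise Cox model recovers them with coefficients
near the planted log-hazards (0.5–1.0), the median-split groups separate
decisively, and the risk score discriminates at AUC ≈ 0.9 across 1–4-year
horizons.

The same pipeline is available from the shell:

```sh
fsor simulate --kind survival --seed 7 --out data/
fsor fsor --expression data/expression.tsv --clinical data/clinical.tsv
fsor prognosis --expression data/expression.tsv --clinical data/clinical.tsv
fsor run --config config.json          # all four stages, every intermediate on disk
```

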
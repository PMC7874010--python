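"""From candidate genes to a validated prognostic risk model.

The stages mirror how expression-based survival signatures are usually
built: a univariate Cox proportional-hazards screen per gene, a hazard-ratio
filter (HR >= 1 keeps risk-increasing genes), bidirectional stepwise
multivariate Cox selection under the BIC, a linear risk score
LP = sum_m beta_m * expr_m (relative hazard exp(LP), no baseline hazard),
median-split risk stratification checked by Kaplan-Meier curves and the
log-rank test, time-dependent ROC/AUC at yearly horizons, and an
L1-penalized (LASSO) Cox model as the reference comparator.

Cox fits use lifelines (Efron tie handling); the LASSO path comes from
scikit-survival's Coxnet, with the penalty chosen by cross-validated
held-out partial likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .core import ExpressionMatrix, FsorOptions, build_label_matrix, fit_fsor, rank_features

__all__ = [
    "ClinicalTable",
    "CoxScreenRow",
    "RiskModel",
    "SurvivalRocResult",
    "DAYS_PER_YEAR",
    "published_luad_signature",
    "cox_partial_loglik",
    "univariate_cox",
    "select_candidates",
    "stepwise_cox_bic",
    "risk_score",
    "stratify_risk",
    "km_logrank",
    "time_dependent_roc",
    "lasso_cox_baseline",
    "compare_pipelines",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ClinicalTable:
    """Survival follow-up: sample id, time in days, vital status (1 = dead)."""

    sample_ids: list[str]
    time: np.ndarray
    status: np.ndarray
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if self.time.shape != (n,) or self.status.shape != (n,):
            raise ValueError("time/status length must match sample_ids")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("survival times must be finite and > 0")
        if not np.all(np.isin(self.status, (0, 1))):
            raise ValueError("status must be 0 (censored) or 1 (dead)")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx) -> "ClinicalTable":
        idx = np.asarray(idx)
        return ClinicalTable(
            [self.sample_ids[i] for i in idx],
            self.time[idx],
            self.status[idx],
            None if self.extra is None else self.extra.iloc[idx].reset_index(drop=True),
        )


@dataclass
class CoxScreenRow:
    """One gene's univariate Cox fit: beta, HR with 95% CI, Wald p."""

    gene: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class RiskModel:
    """Selected genes with Cox coefficients; maps expression to risk scores."""

    genes: list[str]
    coefficients: np.ndarray
    hrs: np.ndarray
    bic: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.hrs = np.asarray(self.hrs, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in risk model")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficient")

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "coefficients": [float(c) for c in self.coefficients],
            "hrs": [float(h) for h in self.hrs],
            "bic": None if self.bic is None else float(self.bic),
            "metadata": self.metadata,
        }


@dataclass
class SurvivalRocResult:
    """Time-dependent ROC at one horizon: curve grids plus the AUC."""

    horizon: float
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


# The eight-gene LUAD signature with its published risk-score weights.  The
# printed weights coincide with the multivariate hazard ratios rather than
# the log-hazard coefficients; both weightings are offered.
_PUBLISHED_WEIGHTS = {
    "RACGAP1": 1.1168,
    "CDCA8": 0.4740,
    "RCC2": 1.4432,
    "PLK1": 1.7456,
    "KIF20B": 1.6966,
    "ALG3": 1.1153,
    "BRCA1": 0.6784,
    "CHAF1B": 1.3090,
}


def published_luad_signature(weighting: str = "hr") -> RiskModel:
    """The literal published eight-gene LUAD risk model.

    ``weighting='hr'`` uses the printed weights as-is (they equal the
    multivariate hazard ratios); ``weighting='log_hr'`` uses their
    logarithms as conventional Cox coefficients.
    """
    genes = list(_PUBLISHED_WEIGHTS)
    hrs = np.array([_PUBLISHED_WEIGHTS[g] for g in genes])
    if weighting == "hr":
        coefs = hrs.copy()
    elif weighting == "log_hr":
        coefs = np.log(hrs)
    else:
        raise ValueError("weighting must be 'hr' or 'log_hr'")
    return RiskModel(genes, coefs, hrs, metadata={"weighting": weighting})


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties) — used for BIC and for LASSO CV scoring
# ---------------------------------------------------------------------------


def cox_partial_loglik(time, status, lp) -> float:
    """Cox log partial likelihood of a fixed linear predictor (Efron ties)."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    lp = np.asarray(lp, dtype=float)
    order = np.argsort(time, kind="stable")
    time, status, lp = time[order], status[order], lp[order]
    exp_lp = np.exp(lp)
    ll = 0.0
    # risk-set sum of exp(lp) for subjects with T >= t, built from the tail
    tail = np.concatenate([np.cumsum(exp_lp[::-1])[::-1], [0.0]])
    i = 0
    n = time.size
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        ev = [idx for idx in range(i, j) if status[idx] == 1]
        if ev:
            d = len(ev)
            risk = tail[i]
            tied = float(np.sum(exp_lp[ev]))
            ll += float(np.sum(lp[ev]))
            for r in range(d):
                ll -= np.log(risk - (r / d) * tied)
        i = j
    return float(ll)


def _fit_cox(
    X: ExpressionMatrix, clinical: ClinicalTable, genes: list[str]
) -> CoxPHFitter:
    df = pd.DataFrame(
        {g: X.values[X.gene_ids.index(g)] for g in genes},
        index=X.sample_ids,
    )
    df["time"] = clinical.time
    df["status"] = clinical.status
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="status")
    return cph


# ---------------------------------------------------------------------------
# Univariate screen and candidate selection
# ---------------------------------------------------------------------------


def univariate_cox(X: ExpressionMatrix, clinical: ClinicalTable) -> list[CoxScreenRow]:
    """One single-covariate Cox PH fit per gene (beta, HR, 95% CI, Wald p)."""
    if clinical.n < 10:
        raise ValueError("need at least 10 samples for the Cox screen")
    if clinical.n_events < 1:
        raise ValueError("need at least one event")
    if X.sample_ids != clinical.sample_ids:
        raise ValueError("expression and clinical sample ids do not match")
    rows: list[CoxScreenRow] = []
    for gene in X.gene_ids:
        expr = X.values[X.gene_ids.index(gene)]
        if np.ptp(expr) == 0:
            logger.warning("gene %s: constant expression, skipped", gene)
            continue
        try:
            cph = _fit_cox(X, clinical, [gene])
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            logger.warning("gene %s: Cox fit failed (%s), skipped", gene, exc)
            continue
        summ = cph.summary.loc[gene]
        rows.append(
            CoxScreenRow(
                gene=gene,
                beta=float(summ["coef"]),
                hr=float(summ["exp(coef)"]),
                ci_low=float(summ["exp(coef) lower 95%"]),
                ci_high=float(summ["exp(coef) upper 95%"]),
                p=float(summ["p"]),
            )
        )
    return rows


def select_candidates(
    rows: list[CoxScreenRow], hr_threshold: float = 1.0
) -> list[str]:
    """Genes whose univariate HR is at least ``hr_threshold``.

    No p-value condition is applied: the screen keeps every risk-increasing
    gene and defers pruning to the stepwise multivariate fit.
    """
    if not rows:
        raise ValueError("empty screen results")
    return [row.gene for row in rows if row.hr >= hr_threshold]


# ---------------------------------------------------------------------------
# Stepwise multivariate Cox under BIC
# ---------------------------------------------------------------------------


def _cox_bic(X, clinical, genes: list[str]) -> tuple[float, CoxPHFitter | None]:
    """BIC = -2 logPL + q log(n_events); the null model has q = 0."""
    pen = np.log(max(clinical.n_events, 1))
    if not genes:
        ll0 = cox_partial_loglik(clinical.time, clinical.status, np.zeros(clinical.n))
        return -2.0 * ll0, None
    cph = _fit_cox(X, clinical, genes)
    return -2.0 * float(cph.log_likelihood_) + len(genes) * pen, cph


def stepwise_cox_bic(
    X: ExpressionMatrix, clinical: ClinicalTable, candidates: list[str]
) -> RiskModel:
    """Bidirectional stepwise covariate search minimizing the BIC.

    Starts from the empty model; at each round tries every single addition
    and deletion, accepting the move with the lowest BIC if it improves the
    incumbent.  Scan order follows the candidate input order with
    lexicographic tie-breaking, so the search is deterministic.  Covariates
    whose fit fails to converge are skipped and logged.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    missing = [g for g in candidates if g not in X.gene_ids]
    if missing:
        raise KeyError(f"candidates not in expression matrix: {missing}")
    if clinical.n_events < len(candidates):
        logger.warning(
            "fewer events (%d) than candidates (%d); stepwise may be unstable",
            clinical.n_events,
            len(candidates),
        )

    current: list[str] = []
    best_bic, best_fit = _cox_bic(X, clinical, current)
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, str, str]] = []
        for gene in candidates:
            trial = current + [gene] if gene not in current else [
                g for g in current if g != gene
            ]
            action = "add" if gene not in current else "drop"
            try:
                bic, fit = _cox_bic(X, clinical, trial)
            except (ConvergenceError, np.linalg.LinAlgError) as exc:
                logger.warning("stepwise %s %s failed (%s), skipped", action, gene, exc)
                continue
            if np.isfinite(bic):
                moves.append((bic, gene, action))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[1]))
        bic, gene, action = moves[0]
        if bic < best_bic - 1e-10:
            if action == "add":
                current = current + [gene]
            else:
                current = [g for g in current if g != gene]
            best_bic, best_fit = _cox_bic(X, clinical, current)
            improved = True

    if not current:
        return RiskModel([], np.array([]), np.array([]), bic=best_bic,
                         metadata={"criterion": "bic", "n_events": clinical.n_events})
    summ = best_fit.summary
    coefs = np.array([float(summ.loc[g, "coef"]) for g in current])
    hrs = np.exp(coefs)
    return RiskModel(
        list(current),
        coefs,
        hrs,
        bic=best_bic,
        metadata={
            "criterion": "bic",
            "n_events": clinical.n_events,
            "concordance": float(best_fit.concordance_index_),
        },
    )


# ---------------------------------------------------------------------------
# Risk score and stratification
# ---------------------------------------------------------------------------


def risk_score(model: RiskModel, X: ExpressionMatrix) -> pd.DataFrame:
    """Linear predictor LP = sum_m beta_m expr_m and relative hazard exp(LP).

    Baseline-free by design: the score ranks patients by relative hazard
    without estimating h0(t).
    """
    missing = [g for g in model.genes if g not in X.gene_ids]
    if missing:
        raise KeyError(f"model genes missing from expression matrix: {missing}")
    if model.genes:
        sub = X.subset_genes(list(model.genes))
        lp = model.coefficients @ sub.values
    else:
        lp = np.zeros(X.n)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite risk score")
    return pd.DataFrame(
        {"linear_predictor": lp, "relative_hazard": np.exp(lp)},
        index=X.sample_ids,
    )


def stratify_risk(scores, rule: str = "median", quantile: float = 0.5) -> np.ndarray:
    """Split scores into 'high'/'low' risk groups; ties go to 'low'."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples to stratify")
    if np.ptp(s) == 0:
        raise ValueError("all risk scores identical; stratification degenerate")
    if rule == "median":
        cut = float(np.median(s))
    elif rule == "quantile":
        cut = float(np.quantile(s, quantile))
    else:
        raise ValueError(f"unknown stratification rule: {rule!r}")
    return np.where(s > cut, "high", "low")


def km_logrank(
    clinical: ClinicalTable, groups
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns (curves, chi-square statistic, p) with the p-value from a
    chi-square reference with 1 degree of freedom.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    if clinical.n_events < 1:
        raise ValueError("need at least one event")
    curves: dict[str, pd.DataFrame] = {}
    for lab in labels:
        idx = groups == lab
        if not idx.any():
            raise ValueError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(clinical.time[idx], clinical.status[idx], label=str(lab))
        curves[str(lab)] = kmf.survival_function_
    a, b = labels
    res = logrank_test(
        clinical.time[groups == a],
        clinical.time[groups == b],
        event_observed_A=clinical.status[groups == a],
        event_observed_B=clinical.status[groups == b],
    )
    return curves, float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------


def _censoring_survival(time, status):
    """Kaplan-Meier estimate of the censoring survival G(t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - np.asarray(status))
    return kmf


def time_dependent_roc(
    scores,
    clinical: ClinicalTable,
    horizon_years: float,
    method: str = "ipcw",
) -> SurvivalRocResult:
    """Cumulative-case/dynamic-control ROC at t = horizon.

    Cases are subjects with an observed event by the horizon, controls are
    those still event-free past it.  Under ``method='ipcw'`` both are
    reweighted by inverse Kaplan-Meier censoring probabilities, so the
    estimator reduces exactly to the plain binary ROC when no one is
    censored.  ``method='uncensored'`` skips the weighting (subjects
    censored before the horizon are dropped).
    """
    s = np.asarray(scores, dtype=float)
    t_h = float(horizon_years) * DAYS_PER_YEAR
    time, status = clinical.time, clinical.status
    if t_h > time.max():
        raise ValueError("horizon beyond observed follow-up")
    case = (time <= t_h) & (status == 1)
    control = time > t_h
    if not case.any():
        raise ValueError("no events before the horizon")
    if not control.any():
        raise ValueError("no subjects at risk past the horizon")

    w = np.zeros(time.size)
    if method == "ipcw":
        km_c = _censoring_survival(time, status)
        g_case = np.asarray(
            km_c.survival_function_at_times(time[case] - 1e-9), dtype=float
        )
        g_ctrl = float(km_c.survival_function_at_times([t_h]).iloc[0])
        g_case = np.maximum(g_case, 1e-12)
        g_ctrl = max(g_ctrl, 1e-12)
        w[case] = 1.0 / g_case
        w[control] = 1.0 / g_ctrl
    elif method == "uncensored":
        w[case] = 1.0
        w[control] = 1.0
    else:
        raise ValueError(f"unknown ROC method: {method!r}")

    sc, wc = s[case], w[case]
    sk, wk = s[control], w[control]
    thresholds = np.unique(s)[::-1]
    sens = [0.0]
    spec = [1.0]
    for c in thresholds:
        sens.append(float(np.sum(wc[sc >= c]) / np.sum(wc)))
        spec.append(float(np.sum(wk[sk < c]) / np.sum(wk)))
    sens.append(1.0)
    spec.append(0.0)

    # weighted Mann-Whitney AUC with half credit for score ties
    diff = sc[:, None] - sk[None, :]
    wt = wc[:, None] * wk[None, :]
    auc = float(np.sum(wt * ((diff > 0) + 0.5 * (diff == 0))) / np.sum(wt))
    return SurvivalRocResult(
        horizon=float(horizon_years),
        sensitivity=np.asarray(sens),
        specificity=np.asarray(spec),
        auc=auc,
    )


# ---------------------------------------------------------------------------
# LASSO–Cox comparator
# ---------------------------------------------------------------------------


def lasso_cox_baseline(
    X: ExpressionMatrix,
    clinical: ClinicalTable,
    cv_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 50,
) -> RiskModel:
    """L1-penalized Cox model with the penalty chosen by cross-validation.

    The Coxnet regularization path is scored on held-out folds by the Cox
    partial log-likelihood of the frozen linear predictor; folds are
    stratified by vital status so every fold contains events.  Returns the
    refit at the selected penalty as a RiskModel interchangeable with the
    stepwise one.
    """
    if not 3 <= cv_folds <= clinical.n:
        raise ValueError("need n >= cv_folds >= 3")
    Xt = X.values.T  # samples x genes
    y = Surv.from_arrays(clinical.status.astype(bool), clinical.time)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(Xt, y)
    alphas = np.asarray(path.alphas_)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_scores = np.zeros((cv_folds, alphas.size))
    for f, (tr, te) in enumerate(skf.split(Xt, clinical.status)):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Xt[tr], Surv.from_arrays(clinical.status[tr].astype(bool),
                                           clinical.time[tr]))
        coefs = np.asarray(m.coef_)  # genes x n_alphas
        for a in range(alphas.size):
            lp_te = Xt[te] @ coefs[:, a]
            fold_scores[f, a] = cox_partial_loglik(
                clinical.time[te], clinical.status[te], lp_te
            )
    mean_scores = fold_scores.mean(axis=0)
    best = int(np.argmax(mean_scores))
    alpha = float(alphas[best])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Xt, y)
    coefs = np.asarray(final.coef_)[:, 0]
    nz = np.flatnonzero(coefs != 0.0)
    genes = [X.gene_ids[i] for i in nz]
    betas = coefs[nz]
    return RiskModel(
        genes,
        betas,
        np.exp(betas),
        metadata={"method": "lasso_cox", "alpha": alpha, "cv_folds": cv_folds,
                  "seed": seed},
    )


# ---------------------------------------------------------------------------
# FSOR-vs-LASSO comparison harness
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Per-horizon AUCs for both arms plus the 1-3y and 1-4y means."""

    per_horizon: pd.DataFrame
    means: pd.DataFrame
    models: dict[str, RiskModel]


def _fsor_arm(
    X: ExpressionMatrix,
    clinical: ClinicalTable,
    top_m: int,
    hr_threshold: float,
    seed: int,
) -> RiskModel:
    Y = build_label_matrix(clinical)
    model = fit_fsor(X, Y, FsorOptions(seed=seed))
    ranked = [g for g, _ in rank_features(model, min(top_m, X.d))]
    screen = univariate_cox(X.subset_genes(ranked), clinical)
    candidates = select_candidates(screen, hr_threshold)
    if not candidates:
        logger.warning("no candidates passed the HR filter; using top-ranked gene")
        candidates = ranked[:1]
    return stepwise_cox_bic(X, clinical, candidates)


def compare_pipelines(
    X: ExpressionMatrix,
    clinical: ClinicalTable,
    horizons=(1, 2, 3, 4),
    top_m: int = 50,
    hr_threshold: float = 1.0,
    cv_folds: int = 5,
    train_frac: float | None = 0.6,
    roc_method: str = "ipcw",
    seed: int = 0,
) -> ComparisonResult:
    """Fit the FSOR->stepwise-Cox arm and the LASSO-Cox arm on one split.

    With ``train_frac`` set, a seeded status-stratified split is drawn and
    AUCs are computed on the held-out part; ``train_frac=None`` scores on
    the training data itself (resubstitution).
    """
    rng = np.random.default_rng(seed)
    if train_frac is not None:
        idx = np.arange(clinical.n)
        train_idx: list[int] = []
        for st in (0, 1):
            pool = idx[clinical.status == st]
            take = max(1, int(round(train_frac * pool.size)))
            train_idx.extend(rng.permutation(pool)[:take])
        train_idx = np.sort(np.asarray(train_idx))
        test_idx = np.setdiff1d(idx, train_idx)
        X_tr = ExpressionMatrix(X.values[:, train_idx], X.gene_ids,
                                [X.sample_ids[i] for i in train_idx])
        X_te = ExpressionMatrix(X.values[:, test_idx], X.gene_ids,
                                [X.sample_ids[i] for i in test_idx])
        clin_tr, clin_te = clinical.subset(train_idx), clinical.subset(test_idx)
    else:
        X_tr = X_te = X
        clin_tr = clin_te = clinical

    models = {
        "fsor_cox": _fsor_arm(X_tr, clin_tr, top_m, hr_threshold, seed),
        "lasso_cox": lasso_cox_baseline(X_tr, clin_tr, cv_folds=cv_folds, seed=seed),
    }

    records = []
    for name, model in models.items():
        scores = risk_score(model, X_te)["linear_predictor"].to_numpy()
        if np.ptp(scores) == 0:
            # empty/constant model: tie-broken by sample order, AUC 0.5
            scores = scores + rng.normal(0, 1e-12, scores.size)
        for h in horizons:
            roc = time_dependent_roc(scores, clin_te, h, method=roc_method)
            records.append({"method": name, "horizon_years": h, "auc": roc.auc})
    per_horizon = pd.DataFrame.from_records(records)

    means = []
    for name in models:
        sub = per_horizon[per_horizon["method"] == name]
        h = sub["horizon_years"]
        means.append({
            "method": name,
            "mean_auc_1_3y": float(sub.loc[h <= 3, "auc"].mean()),
            "mean_auc_1_4y": float(sub.loc[h <= 4, "auc"].mean()),
            "n_genes": len(models[name].genes),
        })
    return ComparisonResult(per_horizon, pd.DataFrame.from_records(means), models)
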
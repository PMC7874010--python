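"""Random-effects meta-analysis of multi-study two-group expression data.

Each study contributes a standardized mean difference (Hedges' g, tumor
minus normal) per gene; studies are pooled under a DerSimonian-Laird
random-effects model, yielding a combined effect size (CombinedES), its
variance, the between-study heterogeneity tau^2, and a normal-approximation
p-value.  Genes pass the differential-expression filter when
|CombinedES| > es_cut (strict) and the Benjamini-Hochberg FDR is at most
fdr_cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix

__all__ = [
    "Study",
    "StudySet",
    "study_effect_size",
    "combine_effects_rem",
    "fdr_adjust",
    "effect_size_table",
    "filter_degs",
    "batch_adjust",
]

logger = logging.getLogger(__name__)

GROUP_NORMAL = "normal"
GROUP_TUMOR = "tumor"


@dataclass
class Study:
    """One study: an expression matrix plus a normal/tumor label per sample."""

    expression: ExpressionMatrix
    groups: list[str]
    study_id: str

    def __post_init__(self) -> None:
        if len(self.groups) != self.expression.n:
            raise ValueError("group labels must match the sample count")
        bad = set(self.groups) - {GROUP_NORMAL, GROUP_TUMOR}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in (GROUP_NORMAL, GROUP_TUMOR):
            if sum(g == grp for g in self.groups) < 2:
                raise ValueError(f"study {self.study_id}: < 2 {grp} samples")


@dataclass
class StudySet:
    studies: list[Study]

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("need at least one study")
        universes = [set(s.expression.gene_ids) for s in self.studies]
        if not set.intersection(*universes):
            raise ValueError("study gene universes share no genes")

    @property
    def gene_universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.studies:
            for g in s.expression.gene_ids:
                seen.setdefault(g)
        return list(seen)


def study_effect_size(group1: np.ndarray, group2: np.ndarray) -> tuple[float, float]:
    """Hedges' g (group2 minus group1) and its sampling variance.

    Standardized mean difference with the pooled SD, scaled by the
    small-sample correction J(m) = 1 - 3/(4m - 1) with m = n1 + n2 - 2;
    variance (n1+n2)/(n1*n2) + g^2 / (2*(n1+n2)).
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled standard deviation is zero")
    m = n1 + n2 - 2
    j = 1.0 - 3.0 / (4.0 * m - 1.0)
    g = j * (x2.mean() - x1.mean()) / np.sqrt(sp2)
    var = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return float(g), float(var)


def combine_effects_rem(
    es_list, var_list
) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects pooling.

    Returns (combined_es, combined_var, tau2, two-sided p).  tau2 is the
    moment estimate max(0, (Q - (s-1)) / (sum w - sum w^2 / sum w)) from the
    fixed-effect homogeneity statistic Q; a single study gives tau2 = 0 and
    returns its own effect unchanged.
    """
    es = np.asarray(es_list, dtype=float)
    var = np.asarray(var_list, dtype=float)
    if es.size == 0:
        raise ValueError("no studies to combine")
    if np.any(var <= 0) or not np.all(np.isfinite(es)):
        raise ValueError("effect sizes must be finite with positive variances")
    s = es.size
    w = 1.0 / var
    es_fixed = float(np.sum(w * es) / np.sum(w))
    if s == 1:
        tau2 = 0.0
    else:
        q = float(np.sum(w * (es - es_fixed) ** 2))
        denom = float(np.sum(w) - np.sum(w * w) / np.sum(w))
        tau2 = max(0.0, (q - (s - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (var + tau2)
    combined = float(np.sum(w_star * es) / np.sum(w_star))
    combined_var = float(1.0 / np.sum(w_star))
    z = combined / np.sqrt(combined_var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return combined, combined_var, tau2, max(p, np.finfo(float).tiny)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effect_size_table(
    studies: StudySet, es_cut: float = 1.0, fdr_cut: float = 0.05
) -> pd.DataFrame:
    """Per-gene effect sizes per study plus the pooled CombinedES columns.

    Genes observed in fewer than 2 studies are pooled over whatever is
    available (tau2 then 0) and flagged in ``n_studies``.  The ``direction``
    column applies the |CombinedES| > es_cut, FDR <= fdr_cut rule.
    """
    universe = studies.gene_universe
    per_study_es: dict[str, dict[str, float]] = {}
    per_study_var: dict[str, dict[str, float]] = {}
    for study in studies.studies:
        groups = np.asarray(study.groups)
        expr = study.expression
        idx1 = groups == GROUP_NORMAL
        idx2 = groups == GROUP_TUMOR
        es_col: dict[str, float] = {}
        var_col: dict[str, float] = {}
        for gi, gene in enumerate(expr.gene_ids):
            row = expr.values[gi]
            try:
                es, var = study_effect_size(row[idx1], row[idx2])
            except ValueError:
                logger.warning(
                    "study %s gene %s: degenerate effect size, skipped",
                    study.study_id,
                    gene,
                )
                continue
            es_col[gene] = es
            var_col[gene] = var
        per_study_es[study.study_id] = es_col
        per_study_var[study.study_id] = var_col

    records = []
    for gene in universe:
        es_list, var_list = [], []
        for sid in per_study_es:
            if gene in per_study_es[sid]:
                es_list.append(per_study_es[sid][gene])
                var_list.append(per_study_var[sid][gene])
        if not es_list:
            continue
        combined, cvar, tau2, p = combine_effects_rem(es_list, var_list)
        rec = {
            "gene": gene,
            "n_studies": len(es_list),
            "combined_es": combined,
            "combined_var": cvar,
            "tau2": tau2,
            "p_value": p,
        }
        for sid in per_study_es:
            rec[f"es_{sid}"] = per_study_es[sid].get(gene, np.nan)
        records.append(rec)
    table = pd.DataFrame.from_records(records).set_index("gene")
    table["fdr"] = fdr_adjust(table["p_value"].to_numpy())
    sig = table["fdr"] <= fdr_cut
    table["direction"] = "ns"
    table.loc[sig & (table["combined_es"] > es_cut), "direction"] = "up"
    table.loc[sig & (table["combined_es"] < -es_cut), "direction"] = "down"
    return table


def filter_degs(
    table: pd.DataFrame, es_cut: float = 1.0, fdr_cut: float = 0.05
) -> tuple[list[str], list[str]]:
    """Differential genes: (up, down) lists under the strict |ES| cut."""
    if table.empty:
        return [], []
    sig = table["fdr"] <= fdr_cut
    up = table.index[sig & (table["combined_es"] > es_cut)].tolist()
    down = table.index[sig & (table["combined_es"] < -es_cut)].tolist()
    return up, down


def batch_adjust(X: ExpressionMatrix, batches) -> ExpressionMatrix:
    """Per-gene, per-batch standardization with global moments restored.

    A deliberately simple location/scale surrogate for batch-effect removal
    (not an empirical-Bayes method such as ComBat): within each batch every
    gene is z-scored, then rescaled to the gene's overall mean and SD.
    Genes with zero variance inside a batch are left unadjusted there and
    logged.
    """
    batches = np.asarray(batches)
    if batches.size != X.n:
        raise ValueError("every sample needs a batch label")
    values = X.values.copy()
    labels = np.unique(batches)
    for b in labels:
        if np.sum(batches == b) < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    if labels.size == 1:
        return ExpressionMatrix(values, list(X.gene_ids), list(X.sample_ids))
    gmean = values.mean(axis=1, keepdims=True)
    gsd = values.std(axis=1, ddof=1, keepdims=True)
    out = values.copy()
    for b in labels:
        cols = batches == b
        block = values[:, cols]
        bmean = block.mean(axis=1, keepdims=True)
        bsd = block.std(axis=1, ddof=1, keepdims=True)
        flat = (bsd[:, 0] == 0) | (gsd[:, 0] == 0)
        scale = np.where(bsd == 0, 1.0, bsd)
        adj = (block - bmean) / scale * gsd + gmean
        adj[flat] = block[flat]
        if np.any(flat):
            logger.warning(
                "batch %r: %d gene(s) with zero variance left unadjusted",
                b,
                int(np.sum(flat)),
            )
        out[:, cols] = adj
    return ExpressionMatrix(out, list(X.gene_ids), list(X.sample_ids))
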
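"""Seeded generators with known planted structure.

Three generators cover the pipeline's input shapes:

* ``simulate_multistudy`` — several two-group (normal/tumor) expression
  studies with per-study batch intercepts and planted differentially
  expressed genes, for exercising the meta-analysis stage;
* ``simulate_survival_cohort`` — an expression matrix plus right-censored
  survival follow-up whose hazard follows a Cox model
  h0(t) * exp(sum beta_j x_j) on a small planted gene set, with a Weibull
  baseline and uniform censoring tuned to a target rate;
* ``make_fsor_testbed`` — a two-class design with a handful of informative
  genes, paired with the survival-style label matrix the FSOR solver
  consumes.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, LabelMatrix, build_label_matrix
from .meta import GROUP_NORMAL, GROUP_TUMOR, Study, StudySet
from .prognosis import ClinicalTable

__all__ = [
    "MetaSimConfig",
    "SurvSimConfig",
    "TruthTable",
    "simulate_multistudy",
    "simulate_survival_cohort",
    "make_fsor_testbed",
]


@dataclass
class MetaSimConfig:
    """Multi-study two-group design.

    Defaults emulate a four-study microarray meta-analysis on the log2
    scale: ~10^3 genes, a few dozen samples per group and study, planted
    standardized effects around 1.5 so they clear the |CombinedES| > 1
    filter, unit residual noise, and study-level intercept shifts.
    """

    n_studies: int = 4
    genes: int = 1000
    n_up: int = 30
    n_down: int = 30
    effect_mean: float = 1.5
    effect_sd: float = 0.2
    samples_per_group: int = 30
    batch_shift_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.genes:
            raise ValueError("more planted genes than genes")
        if min(self.n_studies, self.genes, self.samples_per_group) < 1:
            raise ValueError("counts must be positive")
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("planted counts must be >= 0")
        if min(self.effect_sd, self.batch_shift_sd) < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class SurvSimConfig:
    """Survival cohort with a planted Cox signal.

    Defaults: 300 patients, 100 standardized genes in correlated blocks,
    5 prognostic genes with log-hazard coefficients in [0.5, 1.0], a
    Weibull(shape 1.2, scale 900 days) baseline, and ~30% censoring.
    """

    n_samples: int = 300
    n_genes: int = 100
    n_prognostic: int = 5
    beta_range: tuple[float, float] = (0.5, 1.0)
    baseline_shape: float = 1.2
    baseline_scale: float = 900.0
    censor_rate: float = 0.3
    correlation_block_size: int = 10
    block_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_prognostic > self.n_genes:
            raise ValueError("n_prognostic may not exceed n_genes")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull parameters must be > 0")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block correlation must be in [0, 1)")


@dataclass
class TruthTable:
    """Planted structure: per-gene truth plus (optionally) per-sample LP."""

    genes: pd.DataFrame
    linear_predictor: pd.Series | None = None


def simulate_multistudy(config: MetaSimConfig) -> tuple[StudySet, TruthTable]:
    """Draw the multi-study two-group expression data.

    Per study: baseline log2 gene means ~ N(7, 1); each planted gene's
    tumor group is shifted by (per-study effect) x noise_sd with the effect
    drawn N(effect_mean, effect_sd); a study-wide batch intercept
    ~ N(0, batch_shift_sd) is added to every gene; residual noise is
    i.i.d. N(0, noise_sd).
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i:04d}" for i in range(config.genes)]
    up = gene_ids[: config.n_up]
    down = gene_ids[config.n_up : config.n_up + config.n_down]
    signs = {g: 1.0 for g in up}
    signs.update({g: -1.0 for g in down})

    studies = []
    per_study_effects = np.empty((config.genes, config.n_studies))
    for s in range(config.n_studies):
        npg = config.samples_per_group
        n_tot = 2 * npg
        base = rng.normal(7.0, 1.0, size=config.genes)
        batch = rng.normal(0.0, config.batch_shift_sd)
        values = (
            base[:, None]
            + batch
            + rng.normal(0.0, config.noise_sd, size=(config.genes, n_tot))
        )
        effects = rng.normal(config.effect_mean, config.effect_sd, size=config.genes)
        per_study_effects[:, s] = effects
        for gi, g in enumerate(gene_ids):
            sign = signs.get(g)
            if sign is not None:
                values[gi, npg:] += sign * effects[gi] * config.noise_sd
        sample_ids = [f"S{s}_{j:03d}" for j in range(n_tot)]
        groups = [GROUP_NORMAL] * npg + [GROUP_TUMOR] * npg
        studies.append(
            Study(
                ExpressionMatrix(values, list(gene_ids), sample_ids),
                groups,
                f"study{s}",
            )
        )

    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "true_effect": [
                signs.get(g, 0.0) * per_study_effects[i].mean()
                for i, g in enumerate(gene_ids)
            ],
            "direction": [
                "up" if g in signs and signs[g] > 0
                else "down" if g in signs
                else "null"
                for g in gene_ids
            ],
        }
    )
    return StudySet(studies), TruthTable(genes=truth)


def _tune_censor_scale(event_t, u_cens, target, tol=0.005, max_iter=200):
    """Bisection on the uniform-censoring scale to hit the target rate."""
    if target == 0:
        return float("inf"), 0.0
    lo, hi = 1e-6, float(event_t.max()) * 4.0
    # widen until the censoring rate at hi is below target
    for _ in range(60):
        if np.mean(u_cens * hi < event_t) <= target:
            break
        hi *= 2.0
    rate = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rate = float(np.mean(u_cens * mid < event_t))
        if abs(rate - target) <= tol:
            return mid, rate
        if rate > target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"could not reach target censoring rate {target} (achieved {rate})"
    )


def simulate_survival_cohort(
    config: SurvSimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, TruthTable]:
    """Draw the survival cohort with a planted Cox-model signal.

    Expression is block-equicorrelated Gaussian, standardized per gene.
    Event times come from inverse-transform sampling of a Weibull baseline
    scaled by exp(LP); censoring times are uniform with their scale tuned
    by bisection so the realized censoring fraction matches the target.
    """
    rng = np.random.default_rng(config.seed)
    d, n = config.n_genes, config.n_samples
    rho = config.block_correlation
    bs = max(1, config.correlation_block_size)
    values = np.empty((d, n))
    for start in range(0, d, bs):
        stop = min(start + bs, d)
        shared = rng.standard_normal(n)
        indiv = rng.standard_normal((stop - start, n))
        values[start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * indiv
    values = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, keepdims=True
    )
    gene_ids = [f"G{i:04d}" for i in range(d)]
    sample_ids = [f"P{j:04d}" for j in range(n)]

    prog_idx = rng.choice(d, size=config.n_prognostic, replace=False)
    lo, hi = config.beta_range
    betas = rng.uniform(lo, hi, size=config.n_prognostic)
    lp = betas @ values[prog_idx] if config.n_prognostic else np.zeros(n)

    # T = scale * (-log U / exp(LP))^(1/shape): Weibull baseline, Cox scaling
    u = rng.uniform(1e-12, 1.0, size=n)
    event_t = config.baseline_scale * (
        -np.log(u) / np.exp(lp)
    ) ** (1.0 / config.baseline_shape)

    u_cens = rng.uniform(1e-6, 1.0, size=n)
    if config.censor_rate > 0:
        c_scale, _ = _tune_censor_scale(event_t, u_cens, config.censor_rate)
        cens_t = u_cens * c_scale
        time = np.minimum(event_t, cens_t)
        status = (event_t <= cens_t).astype(int)
    else:
        time = event_t
        status = np.ones(n, dtype=int)
    time = np.maximum(time, 1e-3)

    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    clinical = ClinicalTable(sample_ids, time, status)
    beta_full = np.zeros(d)
    beta_full[prog_idx] = betas
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "gene": gene_ids,
                "true_beta": beta_full,
                "direction": np.where(beta_full > 0, "prognostic", "null"),
            }
        ),
        linear_predictor=pd.Series(lp, index=sample_ids, name="true_lp"),
    )
    return expr, clinical, truth


def make_fsor_testbed(
    d: int, n: int, n_informative: int, seed: int = 0
) -> tuple[ExpressionMatrix, LabelMatrix, TruthTable]:
    """Two balanced classes; informative genes get a between-class shift of 2 SD.

    Vital status equals the class indicator and follow-up times are
    exponential with a class-dependent scale (events arrive faster in the
    high-risk class), so the survival-derived label matrix carries the class
    signal on all three rows.
    """
    if n_informative > d:
        raise ValueError("n_informative may not exceed d")
    if n < 4 or n % 2:
        raise ValueError("n must be even and >= 4")
    rng = np.random.default_rng(seed)
    half = n // 2
    classes = np.array([0] * half + [1] * half)
    values = rng.normal(7.0, 1.0, size=(d, 1)) + rng.standard_normal((d, n))
    info_idx = rng.choice(d, size=n_informative, replace=False)
    values[np.ix_(info_idx, classes == 1)] += 2.0

    gene_ids = [f"G{i:04d}" for i in range(d)]
    sample_ids = [f"P{j:04d}" for j in range(n)]
    status = classes.copy()
    time = np.where(
        classes == 1,
        rng.exponential(300.0, size=n),
        rng.exponential(1500.0, size=n),
    )
    time = np.maximum(time, 1e-3)
    clinical = ClinicalTable(sample_ids, time, status)
    Y = build_label_matrix(clinical)

    flags = np.zeros(d)
    flags[info_idx] = 2.0
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "gene": gene_ids,
                "true_effect": flags,
                "direction": np.where(flags > 0, "informative", "null"),
            }
        )
    )
    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    return expr, Y, truth
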
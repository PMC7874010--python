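"""On-disk formats, configuration, and the four-step pipeline runner.

Every format is plain TSV (UTF-8, Unix newlines): expression matrices with
a gene-id first column and a sample-id header; clinical tables with
sample_id / time_days / status columns; multi-study design tables mapping
samples to group, study, and batch; edge lists for the interaction screen.
Risk models and run manifests are JSON.

``run_pipeline`` ties the stages together: (1) meta-analytic DEG filter,
(2) FSOR ranking of the up-regulated genes, (3) optional network
connectivity filter, (4) Cox screening, stepwise BIC model construction,
risk stratification with KM/log-rank, and time-dependent ROC against the
LASSO-Cox comparator.  All randomness derives from one global seed expanded
per stage by a fixed rule, so any stage can be replayed in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    FsorOptions,
    build_label_matrix,
    fit_fsor,
    rank_features,
)
from .meta import Study, StudySet, batch_adjust, effect_size_table, filter_degs
from .network import connected_candidates, read_interaction_edges
from .prognosis import (
    ClinicalTable,
    RiskModel,
    compare_pipelines,
    km_logrank,
    risk_score,
    select_candidates,
    stepwise_cox_bic,
    stratify_risk,
    univariate_cox,
)

__all__ = [
    "PipelineConfig",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_design",
    "write_design",
    "write_truth",
    "read_truth",
    "write_risk_model",
    "read_risk_model",
    "stage_seed",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression(path) -> ExpressionMatrix:
    """Expression TSV: gene ids in the first column, sample ids as header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene rows: {dupes}")
    if df.isna().any().any():
        bad = [
            (g, c)
            for g, row in df.iterrows()
            for c in df.columns[row.isna()]
        ]
        raise ValueError(f"missing expression values at (gene, sample): {bad[:10]}")
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(g) for g in df.index], [str(c) for c in df.columns]
    )


def write_expression(X: ExpressionMatrix, path) -> None:
    pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids).to_csv(
        path, sep="\t", index_label="gene"
    )


def read_clinical(path) -> ClinicalTable:
    """Clinical TSV with sample_id, time_days, status; extras kept as metadata."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_days", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    extra_cols = [c for c in df.columns if c not in required]
    return ClinicalTable(
        df["sample_id"].astype(str).tolist(),
        pd.to_numeric(df["time_days"], errors="raise").to_numpy(),
        pd.to_numeric(df["status"], errors="raise").to_numpy(),
        extra=df[extra_cols].copy() if extra_cols else None,
    )


def write_clinical(clinical: ClinicalTable, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": clinical.sample_ids,
            "time_days": clinical.time,
            "status": clinical.status,
        }
    )
    if clinical.extra is not None:
        df = pd.concat([df, clinical.extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    """Design TSV mapping sample_id to group, study, and batch."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "study"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if "batch" not in df.columns:
        df["batch"] = df["study"]
    return df


def write_design(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_truth(truth, path) -> None:
    truth.genes.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    # keep_default_na=False: category labels like "null" are data, not NaN
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_risk_model(model: RiskModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_risk_model(path) -> RiskModel:
    with open(path) as fh:
        obj = json.load(fh)
    return RiskModel(
        obj["genes"],
        np.asarray(obj["coefficients"], dtype=float),
        np.asarray(obj["hrs"], dtype=float),
        bic=obj.get("bic"),
        metadata=obj.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths plus stage options; defaults follow the published cutoffs
    (|CombinedES| > 1.0, FDR 0.05, outer tolerance 0.1, top 50 FSOR genes,
    HR >= 1 screen, top 100 central nodes, 1-4 year ROC horizons)."""

    expression: str | None = None
    clinical: str | None = None
    design: str | None = None
    edges: str | None = None
    out_dir: str = "fsor_run"
    es_cut: float = 1.0
    fdr_cut: float = 0.05
    fsor: FsorOptions = field(default_factory=FsorOptions)
    top_m: int = 50
    hr_threshold: float = 1.0
    horizons: tuple = (1, 2, 3, 4)
    cut_rule: str = "median"
    roc_method: str = "ipcw"
    cv_folds: int = 5
    top_central_k: int = 100
    edge_score_cutoff: float = 0.0
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            obj = json.load(fh)
        fsor_opts = FsorOptions(**obj.pop("fsor", {}))
        cfg = cls(**obj, fsor=fsor_opts)
        cfg.horizons = tuple(cfg.horizons)
        return cfg

    def to_json(self, path) -> None:
        obj = asdict(self)
        obj["horizons"] = list(self.horizons)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def config_hash(self) -> str:
        obj = asdict(self)
        obj["horizons"] = list(self.horizons)
        blob = json.dumps(obj, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with the stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------


def _load_study_set(expr: ExpressionMatrix, design: pd.DataFrame) -> StudySet:
    studies = []
    for sid, block in design.groupby("study", sort=True):
        samples = block["sample_id"].tolist()
        idx = [expr.sample_ids.index(s) for s in samples]
        sub = ExpressionMatrix(expr.values[:, idx], list(expr.gene_ids), samples)
        if block["batch"].nunique() > 1:
            sub = batch_adjust(sub, block["batch"].to_numpy())
        studies.append(Study(sub, block["group"].tolist(), str(sid)))
    return StudySet(studies)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write every intermediate to out_dir.

    Returns the run directory.  A structured JSON log records the config
    hash, per-stage seeds and timings, so reruns with the same config and
    seed reproduce every numeric output.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_json(out / "config.json")

    def _stage(name):
        manifest["stages"][name] = {
            "seed": stage_seed(config.seed, name),
            "started": _time.time(),
        }
        return manifest["stages"][name]

    def _done(rec):
        rec["seconds"] = round(_time.time() - rec["started"], 3)
        del rec["started"]

    def _abort(stage: str, exc: Exception):
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    expr = read_expression(config.expression)
    clinical = read_clinical(config.clinical)

    # Step 1: meta-analytic DEG filter (skipped without a design table)
    if config.design:
        rec = _stage("meta")
        try:
            design = read_design(config.design)
            studies = _load_study_set(expr, design)
            table = effect_size_table(studies, config.es_cut, config.fdr_cut)
            up, down = filter_degs(table, config.es_cut, config.fdr_cut)
            table.to_csv(out / "effect_sizes.tsv", sep="\t")
            pd.DataFrame({"gene": up}).to_csv(
                out / "degs_up.tsv", sep="\t", index=False
            )
            pd.DataFrame({"gene": down}).to_csv(
                out / "degs_down.tsv", sep="\t", index=False
            )
        except Exception as exc:  # noqa: BLE001 - abort carries stage context
            _abort("meta", exc)
        _done(rec)
        gene_pool = [g for g in up if g in expr.gene_ids]
        if not gene_pool:
            logger.warning("no up-regulated DEGs; falling back to all genes")
            gene_pool = list(expr.gene_ids)
    else:
        manifest["stages"]["meta"] = {"skipped": True}
        gene_pool = list(expr.gene_ids)

    # Step 2: FSOR ranking on the gene pool
    rec = _stage("fsor")
    try:
        pool_expr = expr.subset_genes(gene_pool)
        fsor_opts = FsorOptions(**{**asdict(config.fsor),
                                   "seed": stage_seed(config.seed, "fsor")})
        Y = build_label_matrix(clinical)
        model = fit_fsor(pool_expr, Y, fsor_opts)
        top_m = min(config.top_m, pool_expr.d)
        ranked = rank_features(model, top_m)
        pd.DataFrame(
            [(i + 1, g, w) for i, (g, w) in enumerate(ranked)],
            columns=["rank", "gene", "weight"],
        ).to_csv(out / "fsor_ranking.tsv", sep="\t", index=False)
        with open(out / "fsor_model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001
        _abort("fsor", exc)
    _done(rec)
    candidates = [g for g, _ in ranked]

    # Step 3: connectivity filter on the interaction network (optional)
    if config.edges:
        rec = _stage("network")
        try:
            graph = read_interaction_edges(config.edges, config.edge_score_cutoff)
            connected = connected_candidates(graph, candidates)
            candidates = [g for g in candidates if g in connected]
            pd.DataFrame({"gene": candidates}).to_csv(
                out / "candidates.tsv", sep="\t", index=False
            )
        except Exception as exc:  # noqa: BLE001
            _abort("network", exc)
        _done(rec)
    else:
        manifest["stages"]["network"] = {"skipped": True}
        pd.DataFrame({"gene": candidates}).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )

    # Step 4: Cox screen -> stepwise BIC -> risk model -> KM / ROC vs LASSO
    rec = _stage("prognosis")
    try:
        cand_expr = expr.subset_genes(candidates)
        screen = univariate_cox(cand_expr, clinical)
        pd.DataFrame([vars(r) for r in screen]).to_csv(
            out / "cox_screen.tsv", sep="\t", index=False
        )
        selected = select_candidates(screen, config.hr_threshold)
        if not selected:
            raise ValueError("no genes passed the univariate HR filter")
        risk_model = stepwise_cox_bic(expr, clinical, selected)
        write_risk_model(risk_model, out / "risk_model.json")

        scores = risk_score(risk_model, expr)
        scores.to_csv(out / "risk_scores.tsv", sep="\t", index_label="sample_id")
        if risk_model.genes:
            labels = stratify_risk(
                scores["linear_predictor"].to_numpy(), config.cut_rule
            )
            curves, chi2, p = km_logrank(clinical, labels)
            pd.concat(curves.values(), axis=1).to_csv(
                out / "km_curves.tsv", sep="\t", index_label="time_days"
            )
            with open(out / "logrank.json", "w") as fh:
                json.dump({"chi_square": chi2, "p_value": p}, fh, indent=2)

        comparison = compare_pipelines(
            expr,
            clinical,
            horizons=config.horizons,
            top_m=config.top_m,
            hr_threshold=config.hr_threshold,
            cv_folds=config.cv_folds,
            roc_method=config.roc_method,
            seed=stage_seed(config.seed, "comparison"),
        )
        comparison.per_horizon.to_csv(
            out / "auc_comparison.tsv", sep="\t", index=False
        )
        comparison.means.to_csv(out / "auc_means.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        _abort("prognosis", exc)
    _done(rec)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
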
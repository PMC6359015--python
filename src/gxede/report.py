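"""End-to-end pipeline orchestration and summary reporting.

``run_pipeline`` wires the stages together: read the expression matrix and
sample sheet, optionally filter undetected genes, optionally log2-transform
and quantile-normalize, fit the factorial models, moderate variances, test
the four comparisons, classify every gene, and write the tabular artifacts
(per-comparison DE tables, category table, count summary, optional
enrichment tables) plus a run log. All outputs are TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import attach_log2fc, build_comparison_groups, classify_all
from .detest import (
    COMPARISON_ORDER,
    ModerationParams,
    ThresholdConfig,
    call_de,
    contrast_test,
    estimate_moderation,
    fit_gene_models,
    run_comparisons,
    unmoderated,
)
from .enrich import fisher_enrichment, read_annotation
from .ingest import (
    ExpressionMatrix,
    filter_absent,
    log2_transform,
    quantile_normalize,
    read_detection_calls,
    read_expression_matrix,
)

logger = logging.getLogger("gxede")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    ``input_scale`` declares the scale of the input file; when ``"raw"`` the
    matrix is log2-transformed (after the optional absent-gene filter).
    Quantile normalization and variance moderation can each be switched off.
    """

    expression_path: str
    meta_path: str
    output_dir: str
    calls_path: str | None = None
    input_scale: str = "raw"
    intensity_floor: float | None = None
    quantile: bool = True
    moderate: bool = True
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    annotation_path: str | None = None
    enrich_categories: tuple[str, ...] = ()
    enrich_min_mapped: int = 5
    enrich_alpha: float = 0.05
    knockout_gene: str | None = None


def prepare_matrix(config: PipelineConfig) -> ExpressionMatrix:
    """Run the ingest/normalize stages of a configured pipeline."""
    matrix = read_expression_matrix(
        config.expression_path, config.meta_path, scale=config.input_scale
    )
    logger.info("read %d genes x %d samples", *matrix.values.shape)
    calls = read_detection_calls(config.calls_path) if config.calls_path else None
    if calls is not None or config.intensity_floor is not None:
        matrix = filter_absent(matrix, calls, config.intensity_floor)
        logger.info("absent-gene filter kept %d genes", len(matrix.gene_ids))
    if matrix.scale == "raw":
        matrix = log2_transform(matrix)
    if config.quantile:
        matrix = quantile_normalize(matrix)
    return matrix


def analyze(matrix: ExpressionMatrix, thresholds: ThresholdConfig, moderate: bool = True):
    """Model fitting through classification; returns all intermediate frames."""
    fits = fit_gene_models(matrix)
    moderation = estimate_moderation(fits) if moderate else unmoderated(fits)
    logger.info(
        "variance prior: d0=%s, s0^2=%.4g", moderation.prior_df, moderation.prior_var
    )
    results = run_comparisons(fits, moderation, thresholds)
    groups = build_comparison_groups(results)
    assignments, summary = classify_all(groups)
    assignments = attach_log2fc(assignments, results)
    return fits, moderation, results, assignments, summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write artifacts to the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = prepare_matrix(config)
    fits, moderation, results, assignments, summary = analyze(
        matrix, config.thresholds, config.moderate
    )

    for name in COMPARISON_ORDER:
        df = results[name].drop(columns="comparison")
        df.index.name = "gene_id"
        df.to_csv(out / f"de_{name}.tsv", sep="\t", float_format="%.6g")
    assignments.index.name = "gene_id"
    assignments.to_csv(out / "categories.tsv", sep="\t", float_format="%.6g")
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    knockout_report = None
    if config.knockout_gene is not None:
        knockout_report = verify_knockout(
            matrix, config.knockout_gene, config.thresholds, moderation=moderation
        )
        pd.DataFrame([knockout_report]).to_csv(
            out / "knockout_verification.tsv", sep="\t", index=False
        )

    if config.annotation_path and config.enrich_categories:
        annotation = read_annotation(config.annotation_path)
        background = list(matrix.gene_ids)
        for cat in config.enrich_categories:
            hits = assignments.index[assignments["primary_category"] == cat]
            table = fisher_enrichment(
                list(hits), background, annotation,
                min_mapped=config.enrich_min_mapped, alpha=config.enrich_alpha,
            )
            table.to_csv(out / f"enrichment_{cat}.tsv", sep="\t", index=False)

    with open(out / "run_log.txt", "w", encoding="utf-8") as handle:
        handle.write(f"gxede {__version__}\n")
        handle.write(f"expression: {config.expression_path}\n")
        handle.write(f"samples: {config.meta_path}\n")
        handle.write(f"genes analyzed: {len(matrix.gene_ids)}\n")
        handle.write(
            f"thresholds: p<{config.thresholds.p_threshold} "
            f"({'adjusted' if config.thresholds.use_adjusted_p else 'raw'}), "
            f"|log2FC|>{config.thresholds.lfc_threshold}\n"
        )
        handle.write(
            f"moderation: d0={moderation.prior_df}, s0^2={moderation.prior_var}\n"
        )
    return {
        "matrix": matrix,
        "fits": fits,
        "moderation": moderation,
        "results": results,
        "assignments": assignments,
        "summary": summary,
        "knockout": knockout_report,
    }


def verify_knockout(
    matrix: ExpressionMatrix,
    gene_id: str,
    thresholds: ThresholdConfig | None = None,
    moderation: ModerationParams | None = None,
) -> dict:
    """Check that a knockout target is significantly depressed on the ground.

    Reports the raw-scale (2^log2) group-mean intensities per genotype in
    the ground environment, the ground KO-vs-WT log2 fold change and its
    p-value, and a pass/fail flag (``depressed``): the gene must be called
    significantly down in the knockout.
    """
    if gene_id not in matrix.gene_ids:
        raise ValueError(f"gene {gene_id!r} not present in matrix")
    thresholds = thresholds or ThresholdConfig()
    fits = fit_gene_models(matrix)
    if moderation is None:
        moderation = estimate_moderation(fits)
    result = call_de(contrast_test(fits, moderation, "KO_vs_WT_ground"), thresholds)
    row = result.loc[gene_id]
    wt_mean = float(fits.group_means.loc[gene_id, "WT:ground"])
    ko_mean = float(fits.group_means.loc[gene_id, "KO:ground"])
    return {
        "gene_id": gene_id,
        "wt_ground_mean_raw": float(np.exp2(wt_mean)),
        "ko_ground_mean_raw": float(np.exp2(ko_mean)),
        "log2FC_KO_vs_WT_ground": float(row["log2FC"]),
        "p_raw": float(row["p_raw"]),
        "p_adj": float(row["p_adj"]),
        "depressed": bool(row["status"] == "down"),
    }
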
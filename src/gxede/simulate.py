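"""Synthetic expression data with the factorial structure the pipeline assumes.

The generator emulates a summarized two-color-free microarray experiment:
log2-scale intensities for each gene across the four genotype x environment
groups with unbalanced replication (by default 5 wild-type and 3 knockout
cultures per environment, matching the flight experiment's plate counts).
Gene-wise variances are drawn from a scaled inverse chi-square prior — the
same hierarchical model the empirical-Bayes testing assumes — and noise is
Gaussian on the log2 scale with a single shared variance per gene across
all four groups.

Planted effects are organized by classification category: each category
name maps to a canonical effect pattern that, in expectation, satisfies
exactly that category's defining significance pattern across the four
comparisons. The returned truth table records every planted effect and the
intended category, enabling end-to-end recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .classify import CATEGORIES
from .ingest import DESIGN_CELLS, ExpressionMatrix

TRUTH_COLUMNS = (
    "genotype_effect",
    "environment_effect_WT",
    "environment_effect_KO",
    "flight_genotype_effect",
    "true_variance",
    "intended_category",
)


class EffectPattern(NamedTuple):
    """Planted log2 effects for one gene.

    ``genotype_effect`` is the KO-minus-WT difference on the ground,
    ``environment_effect_*`` the flight-minus-ground difference within each
    genotype. The flight KO-minus-WT difference is determined by the other
    three: flight = genotype + env_KO - env_WT.
    """

    genotype_effect: float
    environment_effect_wt: float
    environment_effect_ko: float

    @property
    def flight_genotype_effect(self) -> float:
        return (
            self.genotype_effect
            + self.environment_effect_ko
            - self.environment_effect_wt
        )


def category_effect_pattern(category: str, effect_size: float) -> EffectPattern:
    """Canonical planted-effect pattern for one category at a given size.

    Pushed through expectation (no noise) each pattern produces exactly its
    category's significance/non-significance pattern over the four
    comparisons. ``"null"`` returns all-zero effects.
    """
    e = float(effect_size)
    patterns = {
        "shared_same": EffectPattern(0.0, e, e),
        "shared_opposite": EffectPattern(0.0, e, -e),
        # KO sits at the flight level already; WT must move up to it.
        "required": EffectPattern(e, e, 0.0),
        # KO starts low on the ground and rises to the WT flight level.
        "corrected": EffectPattern(-e, 0.0, e),
        "genotype_dependent": EffectPattern(0.0, e, 0.0),
        "compensated": EffectPattern(0.0, 0.0, e),
        "persistent_genotype_difference": EffectPattern(e, 0.0, 0.0),
        "null": EffectPattern(0.0, 0.0, 0.0),
    }
    if category not in patterns:
        raise ValueError(
            f"unknown category {category!r}; expected one of {sorted(patterns)}"
        )
    return patterns[category]


def _default_replicates() -> dict[tuple[str, str], int]:
    return {
        ("WT", "ground"): 5,
        ("WT", "flight"): 5,
        ("KO", "ground"): 3,
        ("KO", "flight"): 3,
    }


def _default_category_counts() -> dict[str, int]:
    return {c: 20 for c in CATEGORIES}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic factorial experiment.

    Defaults mirror the flight study's design where it is stated (5 WT and
    3 KO biological replicates per environment) and otherwise use values
    typical of summarized log2 array data: a gene baseline spread of
    sd 1.5 around log2 intensity 7, a variance prior with 4 prior df and
    scale 0.05 (log2 sd ~0.22 per gene), and planted effects of 2 log2
    units (4-fold), comfortably above the |log2FC| > 1 call threshold.
    """

    n_genes: int = 10_000
    replicates: dict[tuple[str, str], int] = field(default_factory=_default_replicates)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    effect_size: float = 2.0
    prior_df_d0: float = 4.0
    prior_var_s0sq: float = 0.05
    category_counts: dict[str, int] = field(default_factory=_default_category_counts)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        for cell in DESIGN_CELLS:
            n = self.replicates.get(cell, 0)
            if n < 2:
                raise ValueError(
                    f"replicates for cell {cell} must be >= 2, got {n}"
                )
        if self.baseline_sd < 0:
            raise ValueError(f"baseline_sd must be >= 0, got {self.baseline_sd}")
        if not self.prior_var_s0sq > 0:
            raise ValueError(
                f"prior_var_s0sq must be > 0, got {self.prior_var_s0sq}"
            )
        if not self.prior_df_d0 > 0:
            raise ValueError(f"prior_df_d0 must be > 0, got {self.prior_df_d0}")
        for cat, count in self.category_counts.items():
            if cat not in CATEGORIES:
                raise ValueError(f"category_counts has unknown category {cat!r}")
            if count < 0:
                raise ValueError(
                    f"category_counts[{cat!r}] must be >= 0, got {count}"
                )
        if sum(self.category_counts.values()) > self.n_genes:
            raise ValueError(
                "category_counts sum "
                f"{sum(self.category_counts.values())} exceeds n_genes {self.n_genes}"
            )


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw one synthetic experiment; returns the matrix and its truth table.

    Planted genes occupy the first rows in category order; the remainder are
    null. Identical configs (including seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"G{i + 1:06d}" for i in range(n)], name="gene_id")

    # Planted effects, planted genes first.
    geno = np.zeros(n)
    env_wt = np.zeros(n)
    env_ko = np.zeros(n)
    intended = np.array(["null"] * n, dtype=object)
    row = 0
    for cat in CATEGORIES:
        count = config.category_counts.get(cat, 0)
        pat = category_effect_pattern(cat, config.effect_size)
        geno[row : row + count] = pat.genotype_effect
        env_wt[row : row + count] = pat.environment_effect_wt
        env_ko[row : row + count] = pat.environment_effect_ko
        intended[row : row + count] = cat
        row += count

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    if math.isinf(config.prior_df_d0):
        true_var = np.full(n, config.prior_var_s0sq)
    else:
        d0, s0sq = config.prior_df_d0, config.prior_var_s0sq
        true_var = d0 * s0sq / rng.chisquare(d0, size=n)

    cell_mean = {
        ("WT", "ground"): baseline,
        ("WT", "flight"): baseline + env_wt,
        ("KO", "ground"): baseline + geno,
        ("KO", "flight"): baseline + geno + env_ko,
    }
    sd = np.sqrt(true_var)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for genotype, environment in DESIGN_CELLS:
        for r in range(config.replicates[(genotype, environment)]):
            sid = f"{genotype}_{environment}_{r + 1}"
            columns[sid] = cell_mean[(genotype, environment)] + rng.normal(0.0, sd)
            meta_rows.append(
                {"sample_id": sid, "genotype": genotype, "environment": environment}
            )
    values = pd.DataFrame(columns, index=gene_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = ExpressionMatrix(values=values, sample_meta=meta, scale="log2")

    truth = pd.DataFrame(
        {
            "genotype_effect": geno,
            "environment_effect_WT": env_wt,
            "environment_effect_KO": env_ko,
            "flight_genotype_effect": geno + env_ko - env_wt,
            "true_variance": true_var,
            "intended_category": intended,
        },
        index=gene_ids,
    )
    return matrix, truth


def write_truth_table(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_truth_table(path) -> pd.DataFrame:
    # keep_default_na: the literal category label "null" is not missing data
    truth = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    numeric = [c for c in TRUTH_COLUMNS if c != "intended_category"]
    return truth.astype({c: float for c in numeric})
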
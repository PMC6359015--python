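"""Factorial differential-expression testing with moderated t-statistics.

Each gene is fit by a cell-means linear model over the four
genotype x environment groups: per-cell sample means plus a single pooled
residual variance s_g^2 on ``N - 4`` degrees of freedom. Gene-wise variances
are then shrunk toward a global prior estimated by empirical Bayes.

The variance model is hierarchical: s_g^2 | sigma_g^2 follows a scaled
chi-square, and sigma_g^2 follows a scaled inverse chi-square prior with
``d0`` degrees of freedom and scale ``s0^2``. Marginally, log s_g^2 is then
a shifted log-F variate, and (d0, s0^2) are recovered by matching its first
two moments through the digamma/trigamma functions. The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in the t-statistic, which gains d0 extra degrees of freedom.
Contrasts are literal group-mean differences, so log2 fold changes read
directly as "first group minus second group".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .ingest import DESIGN_CELLS, ExpressionMatrix

# The four comparisons of the two-dimensional analysis, each "first group
# minus second group" on the log2 scale. The two "vertical" comparisons
# contrast flight against ground within a genotype (physiological adaptation);
# the two "horizontal" comparisons contrast knockout against wild type within
# an environment (ground- and flight-adapted states).
COMPARISONS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "WT_flight_vs_ground": (("WT", "flight"), ("WT", "ground")),
    "KO_flight_vs_ground": (("KO", "flight"), ("KO", "ground")),
    "KO_vs_WT_ground": (("KO", "ground"), ("WT", "ground")),
    "KO_vs_WT_flight": (("KO", "flight"), ("WT", "flight")),
}

#: Canonical comparison order used for classification 4-tuples.
COMPARISON_ORDER = tuple(COMPARISONS)


def _cell_key(genotype: str, environment: str) -> str:
    return f"{genotype}:{environment}"


@dataclass
class GeneFit:
    """Per-gene least-squares summaries of the 2x2 cell-means model."""

    group_means: pd.DataFrame  # genes x 4 cells, columns "WT:ground" etc.
    residual_var: pd.Series  # pooled within-cell variance s_g^2
    residual_df: int  # N - 4, identical for all genes
    n_per_cell: dict[tuple[str, str], int]

    @property
    def gene_ids(self) -> pd.Index:
        return self.group_means.index


@dataclass
class ModerationParams:
    """Empirical-Bayes variance prior and per-gene posterior variances.

    ``prior_df`` may be 0 (no shrinkage: posterior equals the gene-wise
    variance and the test reduces to an ordinary pooled t-test) or infinity
    (complete shrinkage: every gene uses ``prior_var`` and the t reference
    becomes normal).
    """

    prior_df: float
    prior_var: float
    posterior_var: pd.Series
    residual_df: int

    @property
    def total_df(self) -> float:
        return self.residual_df + self.prior_df


@dataclass
class ThresholdConfig:
    """Significance gates for DE calls: p < p_threshold and |log2FC| > lfc_threshold.

    Both inequalities are strict. ``use_adjusted_p`` selects BH-adjusted
    (default) versus raw p-values for the gate.
    """

    p_threshold: float = 0.01
    lfc_threshold: float = 1.0
    use_adjusted_p: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if self.lfc_threshold < 0:
            raise ValueError(f"lfc_threshold must be >= 0, got {self.lfc_threshold}")


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_gene_models(matrix: ExpressionMatrix) -> GeneFit:
    """Fit the cell-means model to every gene of a log2-scale matrix.

    Returns per-cell sample means and the pooled within-cell residual
    variance with ``N - 4`` degrees of freedom (N = total samples).
    """
    if matrix.scale != "log2":
        raise ValueError("fit_gene_models expects a log2-scale matrix")
    means = {}
    n_per_cell = {}
    rss = np.zeros(len(matrix.gene_ids))
    n_total = 0
    for cell in DESIGN_CELLS:
        samples = matrix.samples_in_cell(*cell)
        if len(samples) < 2:
            raise ValueError(f"design cell {cell} has fewer than 2 samples")
        sub = matrix.values[samples].to_numpy(dtype=float)
        cell_mean = sub.mean(axis=1)
        means[_cell_key(*cell)] = cell_mean
        rss += ((sub - cell_mean[:, None]) ** 2).sum(axis=1)
        n_per_cell[cell] = len(samples)
        n_total += len(samples)
    df = n_total - len(DESIGN_CELLS)
    group_means = pd.DataFrame(means, index=matrix.gene_ids)
    residual_var = pd.Series(rss / df, index=matrix.gene_ids, name="s2")
    return GeneFit(group_means, residual_var, df, n_per_cell)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0); bracketed Brent iteration."""
    trigamma = lambda x: scipy.special.polygamma(1, x)
    lo, hi = 1e-8, 1e8
    if y >= trigamma(lo):
        return lo
    if y <= trigamma(hi):
        return hi
    return scipy.optimize.brentq(lambda x: trigamma(x) - y, lo, hi, xtol=1e-12)

_D0_CAP = 1e6  # fitted prior df beyond this is reported as infinity


def estimate_moderation(fits: GeneFit) -> ModerationParams:
    """Estimate the variance prior (d0, s0^2) by moment-matching log s_g^2.

    With z_g = log s_g^2 and d_g the residual df, the marginal moments are

        E[z]   = log s0^2 + psi(d_g/2) - log(d_g/2) - psi(d0/2) + log(d0/2)
        Var[z] = psi'(d_g/2) + psi'(d0/2)

    so d0 solves psi'(d0/2) = Var[z] - psi'(d_g/2). When the observed
    dispersion does not exceed the psi'(d_g/2) floor the prior df is
    infinite and every posterior variance equals s0^2. Genes with zero
    sample variance are excluded from the moment fit but still shrunk.
    """
    s2 = fits.residual_var.to_numpy(dtype=float)
    dg = fits.residual_df
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("need at least 2 genes with positive residual variance")
    z = np.log(positive)
    z_mean = z.mean()
    z_var = z.var(ddof=1)
    digamma, trigamma = scipy.special.digamma, lambda x: scipy.special.polygamma(1, x)
    excess = z_var - trigamma(dg / 2)
    if excess <= 0:
        d0 = math.inf
        log_s0sq = z_mean - digamma(dg / 2) + math.log(dg / 2)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        if d0 > _D0_CAP:
            d0 = math.inf
            log_s0sq = z_mean - digamma(dg / 2) + math.log(dg / 2)
        else:
            log_s0sq = (
                z_mean
                - digamma(dg / 2)
                + math.log(dg / 2)
                + digamma(d0 / 2)
                - math.log(d0 / 2)
            )
    s0sq = float(math.exp(log_s0sq))
    return ModerationParams(
        prior_df=d0,
        prior_var=s0sq,
        posterior_var=posterior_variance(fits, d0, s0sq),
        residual_df=dg,
    )


def posterior_variance(fits: GeneFit, prior_df: float, prior_var: float) -> pd.Series:
    """Shrink gene-wise variances toward the prior: (d0 s0^2 + d_g s_g^2)/(d0 + d_g)."""
    s2 = fits.residual_var
    if prior_df == 0:
        return s2.copy()
    if math.isinf(prior_df):
        return pd.Series(prior_var, index=s2.index, name="s2_post")
    dg = fits.residual_df
    return ((prior_df * prior_var + dg * s2) / (prior_df + dg)).rename("s2_post")


def unmoderated(fits: GeneFit) -> ModerationParams:
    """Moderation disabled (d0 = 0): ordinary pooled t-tests on d_g df."""
    return ModerationParams(
        prior_df=0.0,
        prior_var=float("nan"),
        posterior_var=fits.residual_var.copy(),
        residual_df=fits.residual_df,
    )


# ---------------------------------------------------------------------------
# Contrast testing and calls
# ---------------------------------------------------------------------------

def contrast_test(
    fits: GeneFit, moderation: ModerationParams, comparison: str
) -> pd.DataFrame:
    """Two-sided moderated t-test for one of the four named comparisons.

    Returns a DataFrame indexed by gene id with columns ``log2FC``
    (first-named group mean minus second), ``t_mod``, ``p_raw`` and BH
    ``p_adj``. The t reference has ``d_g + d0`` degrees of freedom (normal
    when d0 is infinite).
    """
    if comparison not in COMPARISONS:
        raise ValueError(
            f"unknown comparison {comparison!r}; expected one of {list(COMPARISONS)}"
        )
    (g1, e1), (g2, e2) = COMPARISONS[comparison]
    lfc = fits.group_means[_cell_key(g1, e1)] - fits.group_means[_cell_key(g2, e2)]
    n1, n2 = fits.n_per_cell[(g1, e1)], fits.n_per_cell[(g2, e2)]
    se = np.sqrt(moderation.posterior_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    if math.isinf(moderation.total_df):
        p = 2.0 * scipy.stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=moderation.total_df)
    return pd.DataFrame(
        {
            "log2FC": lfc,
            "t_mod": t,
            "p_raw": p,
            "p_adj": bh_adjust(p),
            "comparison": comparison,
        },
        index=fits.gene_ids,
    )


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(result: pd.DataFrame, thresholds: ThresholdConfig) -> pd.DataFrame:
    """Append an up/down/ns status column from the significance gates."""
    p = result["p_adj"] if thresholds.use_adjusted_p else result["p_raw"]
    significant = (p < thresholds.p_threshold) & (
        result["log2FC"].abs() > thresholds.lfc_threshold
    )
    status = np.where(
        significant, np.where(result["log2FC"] > 0, "up", "down"), "ns"
    )
    out = result.copy()
    out["status"] = status
    return out


def run_comparisons(
    fits: GeneFit,
    moderation: ModerationParams,
    thresholds: ThresholdConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Test all four comparisons and call DE status for each."""
    thresholds = thresholds or ThresholdConfig()
    return {
        name: call_de(contrast_test(fits, moderation, name), thresholds)
        for name in COMPARISON_ORDER
    }
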
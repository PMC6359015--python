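"""Reading, filtering and normalizing expression matrices.

The pipeline starts from a summarized probe-set/gene expression table
(genes x samples, tab-delimited) plus a sample sheet assigning each sample
a genotype (WT or KO) and an environment (ground or flight). Probe-level
processing (background correction, summarization) is out of scope; the
optional steps here are the "absent in all samples" detection-call filter,
a log2 transform, and quantile normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats

GENOTYPES = ("WT", "KO")
ENVIRONMENTS = ("ground", "flight")

#: (genotype, environment) cells of the two-factor design, in display order.
DESIGN_CELLS = tuple((g, e) for g in GENOTYPES for e in ENVIRONMENTS)

DETECTION_CALLS = ("P", "M", "A")  # present / marginal / absent


class ExpressionDataError(ValueError):
    """Raised when an expression matrix or its metadata is malformed."""


@dataclass
class ExpressionMatrix:
    """A gene x sample intensity matrix with factorial sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    sample_meta
        DataFrame indexed by sample id with ``genotype`` and
        ``environment`` columns. Must cover the matrix columns exactly.
    scale
        ``"raw"`` for linear-scale intensities (all positive), ``"log2"``
        after log transformation. Linear modeling requires ``"log2"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ExpressionDataError(f"unknown scale flag {self.scale!r}")
        vals = self.values
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise ExpressionDataError(f"duplicate gene ids: {dups[:5]}")
        if vals.columns.has_duplicates:
            dups = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise ExpressionDataError(f"duplicate sample ids: {dups[:5]}")
        if not all(np.issubdtype(d, np.number) for d in vals.dtypes):
            bad = [c for c, d in vals.dtypes.items() if not np.issubdtype(d, np.number)]
            raise ExpressionDataError(f"non-numeric expression columns: {bad}")
        if vals.isna().any().any():
            gene = vals.index[vals.isna().any(axis=1)][0]
            raise ExpressionDataError(f"missing values (first offending gene: {gene})")
        if self.scale == "raw" and (vals.to_numpy() <= 0).any():
            r, c = np.argwhere(vals.to_numpy() <= 0)[0]
            raise ExpressionDataError(
                f"nonpositive raw intensity at gene {vals.index[r]!r}, "
                f"sample {vals.columns[c]!r}"
            )
        meta = self.sample_meta
        for col in ("genotype", "environment"):
            if col not in meta.columns:
                raise ExpressionDataError(f"sample metadata lacks column {col!r}")
        missing = [s for s in vals.columns if s not in meta.index]
        if missing:
            raise ExpressionDataError(f"samples missing from metadata: {missing}")
        extra = [s for s in meta.index if s not in vals.columns]
        if extra:
            raise ExpressionDataError(f"metadata rows without samples: {extra}")
        bad_g = meta.loc[~meta["genotype"].isin(GENOTYPES)]
        if len(bad_g):
            raise ExpressionDataError(
                f"invalid genotype labels: {sorted(bad_g['genotype'].unique())}"
            )
        bad_e = meta.loc[~meta["environment"].isin(ENVIRONMENTS)]
        if len(bad_e):
            raise ExpressionDataError(
                f"invalid environment labels: {sorted(bad_e['environment'].unique())}"
            )
        for cell in DESIGN_CELLS:
            if len(self.samples_in_cell(*cell)) < 2:
                raise ExpressionDataError(
                    f"design cell {cell} has fewer than 2 samples"
                )

    # -- accessors -------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_cell(self, genotype: str, environment: str) -> list[str]:
        """Sample ids belonging to one (genotype, environment) cell."""
        meta = self.sample_meta
        mask = (meta["genotype"] == genotype) & (meta["environment"] == environment)
        return [s for s in self.values.columns if s in meta.index[mask]]


# ---------------------------------------------------------------------------
# File I/O: plain TSV with a header row, genes down the rows.
# ---------------------------------------------------------------------------

def read_expression_matrix(path, meta_path, scale: str = "raw") -> ExpressionMatrix:
    """Read an expression TSV plus a sample sheet and validate the join.

    The expression file has gene ids in the first column and one column per
    sample; the sample sheet has columns ``sample_id``, ``genotype``,
    ``environment``. Row and column order are preserved from the files.
    """
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ExpressionDataError(f"cannot parse {path}: {exc}") from exc
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = values.index[coerced.isna() & values[col].notna()]
            raise ExpressionDataError(
                f"non-numeric cell in {path}, sample {col!r}"
                + (f", gene {bad[0]!r}" if len(bad) else "")
            )
    meta = pd.read_csv(meta_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ExpressionDataError(f"{meta_path} lacks a sample_id column")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ExpressionDataError(f"duplicate sample_id in {meta_path}: {dups}")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values=values, sample_meta=meta, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path, meta_path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    meta = matrix.sample_meta.loc[list(matrix.sample_ids), ["genotype", "environment"]]
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_detection_calls(path) -> pd.DataFrame:
    """Read a P/M/A detection-call table laid out like the expression TSV."""
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = set(np.unique(calls.to_numpy())) - set(DETECTION_CALLS)
    if bad:
        raise ExpressionDataError(f"invalid detection calls: {sorted(bad)}")
    return calls


def write_detection_calls(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Filtering and transforms
# ---------------------------------------------------------------------------

def filter_absent(
    matrix: ExpressionMatrix,
    calls: pd.DataFrame | None = None,
    intensity_floor: float | None = None,
) -> ExpressionMatrix:
    """Drop genes undetected in every sample.

    With a detection-call table, a gene is removed when its call is absent
    (``"A"``) in all samples. Without calls, a positive ``intensity_floor``
    removes genes whose maximum intensity is below the floor; with neither,
    the matrix is returned unchanged. Surviving genes keep their order and
    values.
    """
    if calls is not None:
        if calls.shape != matrix.values.shape:
            raise ExpressionDataError(
                f"detection-call shape {calls.shape} != matrix shape {matrix.values.shape}"
            )
        if list(calls.index) != list(matrix.gene_ids) or list(calls.columns) != list(
            matrix.sample_ids
        ):
            raise ExpressionDataError("detection-call gene/sample ids do not match matrix")
        keep = ~(calls == "A").all(axis=1)
    elif intensity_floor is not None:
        if intensity_floor <= 0:
            raise ExpressionDataError(
                f"intensity_floor must be positive, got {intensity_floor}"
            )
        keep = matrix.values.max(axis=1) >= intensity_floor
    else:
        return matrix
    return replace(matrix, values=matrix.values.loc[keep])


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of a raw-scale matrix."""
    if matrix.scale != "raw":
        raise ExpressionDataError("log2_transform expects a raw-scale matrix")
    vals = matrix.values.to_numpy()
    if (vals <= 0).any():
        r, c = np.argwhere(vals <= 0)[0]
        raise ExpressionDataError(
            f"nonpositive value at gene {matrix.gene_ids[r]!r}, "
            f"sample {matrix.sample_ids[c]!r}"
        )
    return replace(matrix, values=np.log2(matrix.values), scale="log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to their common mean distribution.

    After normalization every sample's sorted values equal the across-sample
    mean of sorted values; within-sample rank order is preserved. Ties take
    the mean of the target quantiles they span (midrank convention).
    """
    if matrix.values.shape[1] < 2:
        raise ExpressionDataError("quantile normalization needs at least 2 samples")
    x = matrix.values.to_numpy(dtype=float)
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = scipy.stats.rankdata(x[:, j], method="average")  # 1-based, .5 at ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (target[lo] + target[hi])
    values = pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids)
    return replace(matrix, values=values)
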
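"""Term over-representation by the one-sided Fisher/hypergeometric test.

Singular enrichment analysis: for each annotation term, count its genes in
a query list (k of n) and in the background (K of N) and compute the
hypergeometric upper tail P(X >= k). Terms mapping fewer than ``min_mapped``
background genes are excluded before testing, and no multiple-testing
adjustment is applied by default; an optional BH switch is provided.
Under-representation is out of scope.
"""

from __future__ import annotations

from collections.abc import Collection, Mapping

import pandas as pd
import scipy.stats

from .detest import bh_adjust


def read_annotation(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT-style annotation file: term_id, description, then gene ids.

    One term per line, tab-separated. Returns term_id -> (description,
    gene set).
    """
    annotation: dict[str, tuple[str, set[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected term_id, description and >= 1 gene"
                )
            term, description, genes = parts[0], parts[1], set(parts[2:]) - {""}
            if term in annotation:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            annotation[term] = (description, genes)
    return annotation


def fisher_enrichment(
    gene_list: Collection[str],
    background: Collection[str],
    annotation: Mapping[str, tuple[str, set[str]]],
    min_mapped: int = 5,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Test every term for over-representation in ``gene_list``.

    ``gene_list`` must be a subset of ``background``. A term enters the
    table only if it maps at least ``min_mapped`` background genes (K >=
    min_mapped); ``significant`` flags p (or BH-adjusted p when ``adjust``)
    strictly below ``alpha``. Rows are ordered by ascending p.
    """
    if min_mapped < 1:
        raise ValueError(f"min_mapped must be >= 1, got {min_mapped}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    bg = set(background)
    query = set(gene_list)
    stray = sorted(query - bg)
    if stray:
        raise ValueError(f"gene list not contained in background: {stray[:10]}")
    N, n = len(bg), len(query)
    rows = []
    for term, (description, genes) in annotation.items():
        K = len(genes & bg)
        if K < min_mapped:
            continue
        k = len(genes & query)
        # Upper tail P(X >= k) of Hypergeometric(N, K, n).
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term, "description": description, "k": k, "K": K,
             "n": n, "N": N, "p": p}
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "K", "n", "N", "p"]
    )
    if len(result):
        p_eff = bh_adjust(result["p"].to_numpy()) if adjust else result["p"].to_numpy()
        if adjust:
            result["p_adj"] = p_eff
        result["significant"] = p_eff < alpha
        result = result.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        result["significant"] = pd.Series(dtype=bool)
    return result
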
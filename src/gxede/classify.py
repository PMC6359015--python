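"""Cross-comparison gene classification over the 2x2 design.

Every gene carries a 4-tuple of DE statuses, one per comparison, in the
canonical order

    (WT flight vs ground, KO flight vs ground,
     KO vs WT on the ground, KO vs WT in flight)

i.e. the two within-genotype "vertical" comparisons followed by the two
within-environment "horizontal" ones. The taxonomy below partitions the
significant patterns by which genotype had to adjust expression to reach
the flight-adapted state:

shared_same / shared_opposite
    Both genotypes respond to flight, in the same or opposite direction.
required
    WT responds to flight and differs from KO on the ground, while KO does
    not respond and the genotypes match in flight — KO already sat at the
    flight-adapted level, so the WT adjustment is required to reach it.
corrected
    Mirror image: KO responds to flight and differs from WT on the ground,
    WT does not respond and the genotypes match in flight — KO corrects its
    expression to the WT flight level.
genotype_dependent
    Only WT responds, the genotypes match on the ground but differ in
    flight: the flight adjustment needs the functional transcription factor.
compensated
    Only KO responds, with a flight-only genotype difference: genes the
    knockout engages to substitute for the missing factor.
persistent_genotype_difference
    The genotypes differ in the same direction both on the ground and in
    flight, a constitutive difference untouched by the environment.

Categories are applied in that precedence order; any other pattern with at
least one significant comparison falls into ``other_pattern``, and all-ns
genes into ``none``. Classification is a pure function of the 4-tuple.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import pandas as pd

from .detest import COMPARISON_ORDER

STATUSES = ("up", "down", "ns")

#: Named categories, in precedence order.
CATEGORIES = (
    "shared_same",
    "shared_opposite",
    "required",
    "corrected",
    "genotype_dependent",
    "compensated",
    "persistent_genotype_difference",
)

ALL_LABELS = CATEGORIES + ("other_pattern", "none")


def classify_gene(pattern: Sequence[str]) -> str:
    """Map one 4-tuple of statuses to its category label.

    No direction constraint is imposed inside required/corrected and the
    dependent/compensated pair: the criteria are significance patterns, and
    e.g. a corrected gene may move up or down to reach the WT flight level.
    """
    if len(pattern) != 4:
        raise ValueError(f"expected 4 statuses, got {len(pattern)}")
    for s in pattern:
        if s not in STATUSES:
            raise ValueError(f"invalid status token {s!r}")
    wt_vert, ko_vert, ground_horiz, flight_horiz = pattern

    if wt_vert != "ns" and ko_vert != "ns":
        return "shared_same" if wt_vert == ko_vert else "shared_opposite"
    if wt_vert != "ns" and ground_horiz != "ns" and ko_vert == "ns" and flight_horiz == "ns":
        return "required"
    if ko_vert != "ns" and ground_horiz != "ns" and wt_vert == "ns" and flight_horiz == "ns":
        return "corrected"
    if wt_vert != "ns" and flight_horiz != "ns" and ko_vert == "ns" and ground_horiz == "ns":
        return "genotype_dependent"
    if ko_vert != "ns" and flight_horiz != "ns" and wt_vert == "ns" and ground_horiz == "ns":
        return "compensated"
    if ground_horiz != "ns" and ground_horiz == flight_horiz:
        return "persistent_genotype_difference"
    if any(s != "ns" for s in pattern):
        return "other_pattern"
    return "none"


def build_comparison_groups(calls: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble the per-gene status 4-tuples from four DE-call tables.

    ``calls`` maps each comparison name to a DataFrame (indexed by gene id)
    with a ``status`` column, as produced by :func:`gxede.detest.call_de`.
    All four tables must cover exactly the same genes.
    """
    missing = [c for c in COMPARISON_ORDER if c not in calls]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    reference = calls[COMPARISON_ORDER[0]].index
    for name in COMPARISON_ORDER[1:]:
        idx = calls[name].index
        if not reference.equals(idx):
            offenders = sorted(reference.symmetric_difference(idx).tolist())
            raise ValueError(
                f"gene universe mismatch between {COMPARISON_ORDER[0]!r} and "
                f"{name!r}: {offenders[:10]}"
            )
    return pd.DataFrame(
        {name: calls[name]["status"] for name in COMPARISON_ORDER}, index=reference
    )


def classify_all(groups: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every gene and tabulate per-comparison and per-category counts.

    Returns ``(assignments, summary)``: the assignments frame carries the
    four statuses plus ``primary_category``; the summary lists, per
    comparison, the significant/up/down counts, then one row per category
    label with its gene count.
    """
    patterns = groups[list(COMPARISON_ORDER)]
    categories = [classify_gene(tuple(row)) for row in patterns.itertuples(index=False)]
    assignments = patterns.copy()
    assignments["primary_category"] = categories

    rows = []
    for name in COMPARISON_ORDER:
        status = groups[name]
        up, down = int((status == "up").sum()), int((status == "down").sum())
        rows.append(
            {"entry": name, "kind": "comparison", "significant": up + down, "up": up, "down": down}
        )
    counts = pd.Series(categories).value_counts()
    for label in ALL_LABELS:
        rows.append(
            {
                "entry": label,
                "kind": "category",
                "significant": int(counts.get(label, 0)),
                "up": pd.NA,
                "down": pd.NA,
            }
        )
    return assignments, pd.DataFrame(rows)


def attach_log2fc(
    assignments: pd.DataFrame, results: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Join the per-comparison log2 fold changes onto the assignment table."""
    out = assignments.copy()
    for name in COMPARISON_ORDER:
        out[f"log2FC_{name}"] = results[name].loc[out.index, "log2FC"]
    return out


def export_heatmap(log2fc: pd.DataFrame, path, title: str = "log2 fold change") -> None:
    """Write a plain (unclustered) heat map of log2FCs for the given genes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(6, max(2.0, 0.12 * len(log2fc))), constrained_layout=True
    )
    vmax = max(1.0, float(log2fc.abs().max().max()))
    im = ax.imshow(log2fc.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(log2fc.shape[1]), log2fc.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(log2fc)), log2fc.index, fontsize=5)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2FC")
    fig.savefig(path, dpi=150)
    plt.close(fig)
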
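"""Matrix-level expression scoring.

Two analyses that accompany the imaging assays:

* **Percent expressing** — for a cells-by-genes table with per-cell
  ontology (and tissue) labels, the percentage of cells in each group with
  expression value > 0 for a gene, and the Pearson correlation of those
  per-group percentages between two genes (e.g. a pathway gene against a
  proliferation marker).

* **Zone scores** — for a gene-by-cluster log-fold-change matrix from a
  one-vs-rest differential-expression run, each anatomical zone is scored
  by summing the log-fold changes of its marker genes per cluster; the
  clusters scoring within a percentage of the zone's maximum (50% or 75%,
  chosen by expected within-zone variance) are selected, capped at the top
  five, and gene scores are re-aggregated over the selected clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_expressing",
    "correlate_ontologies",
    "ZoneSelection",
    "zone_scores",
    "gene_zone_matrix",
]


def percent_expressing(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    gene: str,
    group_cols: tuple[str, ...] = ("ontology", "tissue"),
) -> pd.Series:
    """Percent of cells per group with expression > 0 for one gene.

    ``table`` is cells x genes; ``meta`` holds one row per cell with the
    grouping columns. Returns a Series indexed by group.
    """
    if gene not in table.columns:
        raise KeyError(f"gene {gene!r} not in the expression table")
    if len(table) != len(meta):
        raise ValueError("table and metadata row counts differ")
    positive = (table[gene].to_numpy() > 0).astype(float)
    df = meta.loc[:, list(group_cols)].copy()
    df["positive"] = positive
    return df.groupby(list(group_cols), sort=True)["positive"].mean() * 100.0


def correlate_ontologies(x_percents: pd.Series, y_percents: pd.Series) -> float:
    """Pearson r between two per-group percent-expressing vectors."""
    x, y = x_percents.align(y_percents, join="inner")
    if len(x) < 3:
        raise ValueError("need at least 3 matched groups")
    if np.std(x.to_numpy()) == 0 or np.std(y.to_numpy()) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x.to_numpy(), y.to_numpy())[0])


@dataclass
class ZoneSelection:
    zone: str
    scores: pd.Series  # per-cluster summed logFC over the zone's genes
    selected: list[str]  # cluster ids, empty if no cluster scores > 0
    flagged: bool = False


def zone_scores(
    logfc: pd.DataFrame,
    zone: str,
    gene_set: list[str],
    percentile: int = 50,
    top_k: int = 5,
) -> ZoneSelection:
    """Score clusters for a zone and select the best ones.

    Per cluster, score = sum of log-fold changes over the zone's marker
    genes. Eligible clusters score at least ``percentile`` percent of the
    maximum score; of those, the ``top_k`` highest scores are selected
    (ties broken by ascending cluster id). If no cluster scores above
    zero, the selection is empty and flagged.
    """
    if not gene_set:
        raise ValueError("zone gene set is empty")
    missing = [g for g in gene_set if g not in logfc.index]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing}")
    if percentile not in (50, 75):
        raise ValueError("percentile must be 50 or 75")
    scores = logfc.loc[gene_set].sum(axis=0)
    top = scores.max()
    if top <= 0:
        return ZoneSelection(zone, scores, [], flagged=True)
    eligible = scores[scores >= (percentile / 100.0) * top]
    # highest scores first; ties by ascending cluster id
    order = sorted(eligible.index, key=lambda c: (-eligible[c], str(c)))
    return ZoneSelection(zone, scores, [str(c) for c in order[:top_k]])


def gene_zone_matrix(
    logfc: pd.DataFrame,
    zone_selections: list[ZoneSelection],
    genes_of_interest: list[str] = ("Casp8", "Ripk1", "Ripk3", "Mlkl"),
) -> pd.DataFrame:
    """Heatmap-ready gene x zone table of aggregated log-fold changes.

    Per zone, a gene's score is the sum of its log-fold changes over that
    zone's selected clusters. Genes missing from the matrix appear as NaN.
    """
    out = {}
    for sel in zone_selections:
        col = []
        for g in genes_of_interest:
            if g in logfc.index and sel.selected:
                col.append(float(logfc.loc[g, sel.selected].sum()))
            else:
                col.append(np.nan)
        out[sel.zone] = col
    return pd.DataFrame(out, index=list(genes_of_interest))
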
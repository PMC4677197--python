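"""Pairwise Spearman correlation of per-gene motif-count profiles.

Two motifs that tend to occur in the same promoters (measured on their
per-gene site counts) have a high rank correlation; the analysis reports
rho, rho² and a two-sided p-value for every unordered motif pair.  Count
data are tie-heavy, so ranks are midranks (tied observations share their
average rank) and rho is the Pearson correlation of the midranks; p comes
from the t approximation t = rho * sqrt((n-2) / (1-rho²)), with rho = ±1
assigned p = 0 by convention.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

__all__ = ["spearman_rho", "correlation_matrix", "rho_matrix"]


def spearman_rho(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks; returns (rho, two-sided p).

    Requires at least 3 paired observations and at least two distinct
    values in each vector (a constant vector has no defined correlation).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation: constant vector")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    # exact perfect (anti-)concordance gets rho = +/-1 with p = 0 by convention
    if np.array_equal(rx, ry):
        return 1.0, 0.0
    if np.array_equal(rx, n + 1 - ry):
        return -1.0, 0.0
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if 1.0 - rho * rho <= 0.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def _subset(counts: pd.DataFrame, gene_subset: GeneSet | Iterable[str] | None) -> pd.DataFrame:
    if gene_subset is None:
        return counts
    wanted = set(gene_subset.gene_ids if isinstance(gene_subset, GeneSet) else gene_subset)
    missing = wanted - set(counts.index)
    if missing:
        raise ValueError(f"genes absent from count matrix: {sorted(missing)[:5]}")
    return counts.loc[[g for g in counts.index if g in wanted]]


def correlation_matrix(
    counts: pd.DataFrame,
    gene_subset: GeneSet | Iterable[str] | None = None,
) -> pd.DataFrame:
    """All unordered motif pairs, long format.

    Columns: motif_a, motif_b, rho, rho_squared, p_value, undefined.  A
    pair involving a constant count column is flagged ``undefined`` with
    NaN statistics rather than a number.
    """
    sub = _subset(counts, gene_subset)
    if len(sub.index) < 3:
        raise ValueError("need at least 3 genes to correlate")
    constant = {m: bool((sub[m] == sub[m].iloc[0]).all()) for m in sub.columns}
    rows = []
    for a, b in combinations(sub.columns, 2):
        if constant[a] or constant[b]:
            rows.append(
                {"motif_a": a, "motif_b": b, "rho": np.nan, "rho_squared": np.nan,
                 "p_value": np.nan, "undefined": True}
            )
            continue
        rho, p = spearman_rho(sub[a].to_numpy(), sub[b].to_numpy())
        rows.append(
            {"motif_a": a, "motif_b": b, "rho": rho, "rho_squared": rho * rho,
             "p_value": p, "undefined": False}
        )
    return pd.DataFrame(rows)


def rho_matrix(
    counts: pd.DataFrame,
    gene_subset: GeneSet | Iterable[str] | None = None,
) -> pd.DataFrame:
    """Square, symmetric matrix of rho with unit diagonal (NaN if undefined)."""
    pairs = correlation_matrix(counts, gene_subset)
    motifs = list(counts.columns)
    mat = pd.DataFrame(np.eye(len(motifs)), index=motifs, columns=motifs)
    for _, r in pairs.iterrows():
        v = np.nan if r["undefined"] else r["rho"]
        mat.loc[r["motif_a"], r["motif_b"]] = v
        mat.loc[r["motif_b"], r["motif_a"]] = v
    mat.index.name = "motif_id"
    return mat
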
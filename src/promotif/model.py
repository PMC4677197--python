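"""Model/Results interface for the motif over-representation analysis.

`MotifEnrichment` is built from a population gene x motif count matrix and
a foreground gene set (or directly from motif/FASTA/gene-list files via
:meth:`MotifEnrichment.from_files`); its :meth:`fit` runs the per-motif
hypergeometric test and returns a :class:`MotifEnrichmentResults` carrying
the estimates, the Bonferroni decision and a ``summary()`` table, in the
style of statsmodels results objects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cooccurrence import correlation_matrix
from .enrichment import bonferroni_threshold, enrich_motifs
from .io import GeneSet, read_gene_list, read_pfm_collection, read_promoters_fasta
from .matrices import pfm_to_pwm
from .scan import build_count_matrix

__all__ = ["MotifEnrichment", "MotifEnrichmentResults"]


class MotifEnrichment:
    """Hypergeometric motif over-representation model.

    Parameters
    ----------
    counts
        Population count matrix (genes as rows, motifs as columns), e.g.
        from :func:`promotif.scan.build_count_matrix`.
    foreground
        The gene set under test; every id must be a row of ``counts``.

    Examples
    --------
    >>> model = MotifEnrichment(counts, foreground=["g000001", "g000002"])
    >>> res = model.fit(alpha=0.05)
    >>> print(res.summary())
    """

    def __init__(self, counts: pd.DataFrame, foreground: GeneSet | Iterable[str]):
        fg_ids = (
            set(foreground.gene_ids) if isinstance(foreground, GeneSet) else set(foreground)
        )
        if not fg_ids:
            raise ValueError("foreground gene set is empty")
        missing = fg_ids - set(counts.index)
        if missing:
            raise ValueError(
                f"foreground genes absent from population: {sorted(missing)[:5]}"
            )
        self.counts = counts
        self.foreground_ids = [g for g in counts.index if g in fg_ids]

    @classmethod
    def from_files(
        cls,
        pfm_path: str | Path,
        population_fasta: str | Path,
        foreground: str | Path | Iterable[str],
        threshold: float = 0.95,
        strands: str = "both",
        pseudocount_total: float = 0.8,
        background: np.ndarray | None = None,
        skip_invalid: bool = True,
    ) -> "MotifEnrichment":
        """Scan promoters from files and build the model in one step."""
        pfms = read_pfm_collection(pfm_path, skip_invalid=skip_invalid)
        pwms = [pfm_to_pwm(p, pseudocount_total, background) for p in pfms]
        promoters = read_promoters_fasta(population_fasta)
        if isinstance(foreground, (str, Path)):
            fg = read_gene_list(foreground)
        else:
            fg = GeneSet(name="foreground", gene_ids=frozenset(foreground))
        counts = build_count_matrix(pwms, promoters, threshold=threshold, strands=strands)
        return cls(counts, fg)

    @property
    def fg_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.foreground_ids]

    def fit(self, alpha: float = 0.05) -> "MotifEnrichmentResults":
        """Run the per-motif hypergeometric test with Bonferroni control."""
        table = enrich_motifs(self.fg_counts, self.counts, alpha=alpha)
        return MotifEnrichmentResults(self, table, alpha)


class MotifEnrichmentResults:
    """Fitted enrichment results.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per motif: motif_id, k, K, n, N, p_value, p_bonferroni,
        significant; sorted by ascending p-value.
    alpha, m, threshold
        Family-wise error target, number of tests, and the per-test
        Bonferroni cut alpha / m.
    """

    def __init__(self, model: MotifEnrichment, table: pd.DataFrame, alpha: float):
        self.model = model
        self.table = table
        self.alpha = alpha
        self.m = len(table)
        self.threshold = bonferroni_threshold(alpha, self.m)

    @property
    def pvalues(self) -> pd.Series:
        return self.table.set_index("motif_id")["p_value"]

    @property
    def significant_motifs(self) -> list[str]:
        return self.table.loc[self.table["significant"], "motif_id"].tolist()

    def cooccurrence(self, foreground_only: bool = True) -> pd.DataFrame:
        """Pairwise Spearman correlation of motif-count profiles."""
        subset = self.model.foreground_ids if foreground_only else None
        return correlation_matrix(self.model.counts, subset)

    def summary(self) -> str:
        """Plain-text summary table of the fitted enrichment."""
        n = len(self.model.foreground_ids)
        N = len(self.model.counts.index)
        lines = [
            "Motif over-representation (hypergeometric, upper tail)",
            "=" * 70,
            f"promotif {_version}",
            f"Population genes (N): {N:>8d}    Foreground genes (n): {n}",
            f"Motifs tested (m):    {self.m:>8d}    alpha: {self.alpha}",
            f"Bonferroni cut (alpha/m): {self.threshold:.6g}",
            "-" * 70,
            f"{'motif_id':<12}{'k':>6}{'K':>8}{'p_value':>14}{'p_bonf':>12}  sig",
            "-" * 70,
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['motif_id']:<12}{r['k']:>6d}{r['K']:>8d}"
                f"{r['p_value']:>14.4g}{r['p_bonferroni']:>12.4g}"
                f"  {'*' if r['significant'] else ''}"
            )
        lines.append("-" * 70)
        lines.append(
            f"{len(self.significant_motifs)} motif(s) significant at "
            f"p < alpha/m = {self.threshold:.6g}"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MotifEnrichmentResults: m={self.m}, "
            f"{len(self.significant_motifs)} significant at alpha={self.alpha}>"
        )
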
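"""Hypergeometric over-representation of motifs in a foreground gene set.

A motif's *success* is gene-level presence: a promoter carrying at least
one retained binding site.  With N population genes of which K carry the
motif, drawing the n foreground genes without replacement makes the number
of foreground carriers k hypergeometric; the enrichment p-value is the
upper tail P(X >= k).  Bonferroni correction over the m motifs tested
gives the per-test significance threshold alpha / m (0.05 / 62 ≈ 8.06e-4
for a full JASPAR-2010-sized human panel).
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd

from .scan import presence_vector

__all__ = ["hypergeom_upper_tail", "enrich_motifs", "bonferroni_threshold"]


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


#: population size up to which the tail is summed in exact integer
#: arithmetic (correctly-rounded result); larger problems use log-gamma
_EXACT_N_MAX = 2000


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    For N up to 2000 the tail sum is evaluated in exact rational
    arithmetic and rounded once to float; beyond that it is computed in
    log-gamma space with a compensated (fsum) summation.  Exactly 1.0 when
    k == 0; symmetric in (K, n).
    """
    for name, val in (("k", k), ("N", N), ("K", K), ("n", n)):
        if not isinstance(val, (int, np.integer)):
            raise ValueError(f"{name} must be an integer, got {val!r}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"require 0 <= k <= min(n, K), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    if N <= _EXACT_N_MAX:
        numerator = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1))
        return float(Fraction(numerator, math.comb(N, n)))
    log_denom = _log_binom(N, n)
    lo = max(k, n - (N - K))  # below this C(N-K, n-i) is zero
    terms = [
        math.exp(_log_binom(K, i) + _log_binom(N - K, n - i) - log_denom)
        for i in range(lo, hi + 1)
    ]
    return min(1.0, math.fsum(terms))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m for m simultaneous tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def enrich_motifs(
    fg_counts: pd.DataFrame,
    bg_counts: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-motif hypergeometric enrichment of foreground vs population.

    ``fg_counts`` is the count matrix restricted to the foreground genes;
    ``bg_counts`` covers the whole population (which must contain the
    foreground).  Returns one row per motif with columns
    motif_id, k, K, n, N, p_value, p_bonferroni, significant — sorted by
    ascending p-value, ties broken by motif id.  ``significant`` applies
    the Bonferroni cut p < alpha / m with m the number of motifs tested.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if list(fg_counts.columns) != list(bg_counts.columns):
        raise ValueError("foreground and population motif panels differ")
    missing = set(fg_counts.index) - set(bg_counts.index)
    if missing:
        raise ValueError(
            f"foreground genes absent from population: {sorted(missing)[:5]}"
        )
    n = len(fg_counts.index)
    N = len(bg_counts.index)
    m = len(bg_counts.columns)
    cut = bonferroni_threshold(alpha, m)
    rows = []
    for motif_id in bg_counts.columns:
        k = int(presence_vector(fg_counts, motif_id).sum())
        K = int(presence_vector(bg_counts, motif_id).sum())
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append(
            {
                "motif_id": motif_id,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "p_bonferroni": min(1.0, m * p),
                "significant": p < cut,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(["p_value", "motif_id"], kind="mergesort").reset_index(drop=True)
    return out
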
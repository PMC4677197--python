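"""PWM scanning of promoter sequences and the gene x motif count matrix.

Every window of the motif's length, at every offset of every promoter, is
scored on the forward strand and (by default) against the reverse
complement; a window is a *hit* when its min-max relative score strictly
exceeds the threshold (0.95 by default, i.e. a "confidence" above 95%).
Windows containing N are skipped.  Overlapping and nested hits are all
retained — per-gene totals are raw site counts, not collapsed footprints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .io import PromoterSet
from .matrices import N_CODE, PWM, encode_sequence, reverse_complement_pwm

logger = logging.getLogger(__name__)

__all__ = ["MotifHit", "scan_sequence", "scan_promoters", "build_count_matrix", "presence_vector"]

Strands = Literal["both", "forward"]


@dataclass(frozen=True)
class MotifHit:
    """A retained match: promoter-relative, 0-based half-open window."""

    gene_id: str
    motif_id: str
    start: int
    length: int
    strand: str
    raw_score: float
    relative_score: float

    @property
    def end(self) -> int:
        return self.start + self.length


def _window_scores(weights: np.ndarray, codes: np.ndarray, length: int) -> np.ndarray:
    """Raw scores of all windows; NaN where the window contains an N."""
    # row 4 (N) scores NaN, poisoning any window that covers it
    extended = np.vstack([weights, np.full((1, length), np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)
    return extended[windows, np.arange(length)].sum(axis=1)


def _relative_profiles(
    pwm: PWM, codes: np.ndarray, strands: Strands
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Relative-score profiles (forward, reverse-or-None, raw forward)."""
    if pwm.s_max <= pwm.s_min:
        raise ValueError(f"uninformative motif {pwm.motif_id!r}: s_max == s_min")
    span = pwm.s_max - pwm.s_min
    raw_fwd = _window_scores(pwm.weights, codes, pwm.length)
    rel_fwd = (raw_fwd - pwm.s_min) / span
    rel_rev = None
    if strands == "both":
        rc = reverse_complement_pwm(pwm)
        raw_rev = _window_scores(rc.weights, codes, pwm.length)
        rel_rev = (raw_rev - pwm.s_min) / span
    return rel_fwd, rel_rev, raw_fwd


def scan_sequence(
    pwm: PWM,
    gene_id: str,
    sequence: str,
    threshold: float = 0.95,
    strands: Strands = "both",
) -> list[MotifHit]:
    """All hits of one motif in one promoter, above the relative threshold.

    Reverse-strand hits are reported at their forward-strand offset with
    strand '-'.  Hits are ordered by ascending start, '+' before '-' at
    equal start.  A sequence shorter than the motif yields no hits.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if pwm.length > len(sequence):
        return []
    codes = encode_sequence(sequence)
    rel_fwd, rel_rev, raw_fwd = _relative_profiles(pwm, codes, strands)
    span = pwm.s_max - pwm.s_min

    hits: list[MotifHit] = []
    with np.errstate(invalid="ignore"):
        keep_fwd = rel_fwd > threshold
        keep_rev = rel_rev > threshold if rel_rev is not None else None
    starts = np.nonzero(keep_fwd)[0] if keep_fwd.any() else np.empty(0, dtype=int)
    fwd = {
        int(i): MotifHit(gene_id, pwm.motif_id, int(i), pwm.length, "+",
                         float(raw_fwd[i]), float(rel_fwd[i]))
        for i in starts
    }
    rev: dict[int, MotifHit] = {}
    if keep_rev is not None and keep_rev.any():
        for i in np.nonzero(keep_rev)[0]:
            raw = float(rel_rev[i] * span + pwm.s_min)
            rev[int(i)] = MotifHit(
                gene_id, pwm.motif_id, int(i), pwm.length, "-", raw, float(rel_rev[i])
            )
    for i in sorted(set(fwd) | set(rev)):
        if i in fwd:
            hits.append(fwd[i])
        if i in rev:
            hits.append(rev[i])
    return hits


def scan_promoters(
    pwms: Sequence[PWM],
    promoters: PromoterSet | Iterable[tuple[str, str]],
    threshold: float = 0.95,
    strands: Strands = "both",
) -> Iterator[MotifHit]:
    """Stream hits gene by gene (memory stays proportional to one promoter)."""
    for gene_id, seq in promoters:
        for pwm in pwms:
            yield from scan_sequence(pwm, gene_id, seq, threshold, strands)


def build_count_matrix(
    pwms: Sequence[PWM],
    promoters: PromoterSet | Iterable[tuple[str, str]],
    threshold: float = 0.95,
    strands: Strands = "both",
) -> pd.DataFrame:
    """Gene x motif matrix of retained-hit counts.

    Rows follow promoter order, columns follow motif order; entries are the
    number of windows whose relative score strictly exceeds ``threshold``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    motif_ids = [p.motif_id for p in pwms]
    if len(set(motif_ids)) != len(motif_ids):
        raise ValueError("duplicate motif ids in panel")
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped_windows = 0
    for gene_id, seq in promoters:
        counts = np.zeros(len(pwms), dtype=np.int64)
        codes = encode_sequence(seq)
        has_n = (codes == N_CODE).any()
        for j, pwm in enumerate(pwms):
            if pwm.length > len(seq):
                continue
            rel_fwd, rel_rev, _ = _relative_profiles(pwm, codes, strands)
            with np.errstate(invalid="ignore"):
                c = int((rel_fwd > threshold).sum())
                if rel_rev is not None:
                    c += int((rel_rev > threshold).sum())
            if has_n:
                n_skipped_windows += int(np.isnan(rel_fwd).sum())
            counts[j] = c
        gene_ids.append(gene_id)
        rows.append(counts)
    if n_skipped_windows:
        logger.info("skipped %d windows containing N", n_skipped_windows)
    data = np.vstack(rows) if rows else np.zeros((0, len(pwms)), dtype=np.int64)
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"), columns=motif_ids)


def presence_vector(counts: pd.DataFrame, motif_id: str) -> pd.Series:
    """Per-gene boolean: does the gene's promoter carry >= 1 retained site?"""
    if motif_id not in counts.columns:
        raise ValueError(f"unknown motif id {motif_id!r}")
    return counts[motif_id] >= 1
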
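"""Position matrices: counts (PFM), probabilities (PPM) and log-odds (PWM).

A transcription-factor binding motif of length ``L`` is represented by a
4 x L matrix with rows fixed in the order A, C, G, T.  A *position
frequency matrix* (PFM) holds per-position nucleotide observation counts,
as catalogued by JASPAR.  Normalising each column (with a pseudocount
spread across the background distribution) gives a *position probability
matrix* (PPM); taking log2-odds against the background gives a *position
weight matrix* (PWM), under which a sequence window is scored by summing
the weight of the observed base at each position.

The *relative score* (the "confidence" of a match) min-max normalises a
raw PWM score into [0, 1] using the best and worst achievable scores, so a
95% threshold has the same meaning for motifs of any length or
information content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "PFM",
    "PPM",
    "PWM",
    "pfm_to_ppm",
    "ppm_to_pwm",
    "pfm_to_pwm",
    "score_window",
    "relative_score",
    "information_content",
    "logo_matrix",
    "reverse_complement_pwm",
    "encode_sequence",
    "UNIFORM_BACKGROUND",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: code used for the ambiguous base N in encoded sequences
N_CODE = 4

UNIFORM_BACKGROUND = np.full(4, 0.25)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# byte -> base code lookup (A/C/G/T -> 0..3, N -> 4, anything else -> 255)
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
_ENCODE_LUT[ord("N")] = N_CODE
_ENCODE_LUT[ord("n")] = N_CODE


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if codes.max(initial=0) == 255:
        bad = sequence[int(np.argmax(codes == 255))]
        raise ValueError(f"illegal character {bad!r} in sequence")
    return codes


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(sequence))


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: per-position base observation counts.

    Rows are fixed in the order A, C, G, T; ``counts`` has shape (4, L).
    """

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(
                f"PFM {self.motif_id!r}: counts must be a 4 x L matrix with L >= 1"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError(f"PFM {self.motif_id!r}: counts must be integers")
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError(f"PFM {self.motif_id!r}: negative count")
        if (counts.sum(axis=0) == 0).any():
            j = int(np.argmax(counts.sum(axis=0) == 0))
            raise ValueError(f"PFM {self.motif_id!r}: all-zero column at position {j}")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Highest-count base per column (ties broken A < C < G < T)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PPM:
    """Position probability matrix with its background model."""

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount_total: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError(f"PPM {self.motif_id!r}: probs must be 4 x L")
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError(f"PPM {self.motif_id!r}: probabilities outside [0, 1]")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"PPM {self.motif_id!r}: columns must each sum to 1")
        if background.shape != (4,) or not math.isclose(
            background.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValueError(f"PPM {self.motif_id!r}: background must sum to 1")
        if self.pseudocount_total < 0:
            raise ValueError(f"PPM {self.motif_id!r}: negative pseudocount")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", background)

    @property
    def length(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class PWM:
    """Log2-odds weight matrix with its score range.

    ``s_min``/``s_max`` are the worst/best achievable raw scores (sums of
    column minima/maxima); they turn raw scores into relative scores.
    """

    motif_id: str
    weights: np.ndarray
    s_min: float = 0.0
    s_max: float = 0.0

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != 4:
            raise ValueError(f"PWM {self.motif_id!r}: weights must be 4 x L")
        s_min = float(weights.min(axis=0).sum())
        s_max = float(weights.max(axis=0).sum())
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "s_min", s_min)
        object.__setattr__(self, "s_max", s_max)

    @property
    def length(self) -> int:
        return self.weights.shape[1]


def pfm_to_ppm(
    pfm: PFM,
    pseudocount_total: float = 0.8,
    background: np.ndarray | None = None,
) -> PPM:
    """Normalise a PFM into probabilities with background-weighted smoothing.

    Each column j becomes ``(counts[:, j] + pseudocount_total * background)
    / (colsum_j + pseudocount_total)``.  The default total pseudocount of
    0.8, spread proportionally to the background, is the convention widely
    used with JASPAR matrices.
    """
    if pseudocount_total < 0:
        raise ValueError("pseudocount_total must be non-negative")
    if background is None:
        background = UNIFORM_BACKGROUND
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or not math.isclose(background.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must be a length-4 probability vector")
    counts = pfm.counts.astype(float)
    colsums = counts.sum(axis=0)
    probs = (counts + pseudocount_total * background[:, None]) / (
        colsums + pseudocount_total
    )
    return PPM(
        motif_id=pfm.motif_id,
        probs=probs,
        background=background,
        pseudocount_total=pseudocount_total,
    )


def ppm_to_pwm(ppm: PPM) -> PWM:
    """Log2-odds of the PPM against its background."""
    if ((ppm.probs == 0) & (ppm.background[:, None] > 0)).any():
        raise ValueError(
            f"PPM {ppm.motif_id!r} contains a zero probability against a positive "
            "background; apply a pseudocount (pfm_to_ppm with pseudocount_total > 0)"
        )
    with np.errstate(divide="ignore"):
        weights = np.log2(ppm.probs / ppm.background[:, None])
    return PWM(motif_id=ppm.motif_id, weights=weights)


def pfm_to_pwm(
    pfm: PFM,
    pseudocount_total: float = 0.8,
    background: np.ndarray | None = None,
) -> PWM:
    """Convenience: PFM -> (pseudocounted) PPM -> PWM."""
    return ppm_to_pwm(pfm_to_ppm(pfm, pseudocount_total, background))


def score_window(pwm: PWM, window: str) -> float:
    """Raw log-odds score of a window of exactly the motif's length."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != motif length {pwm.length} "
            f"for {pwm.motif_id!r}"
        )
    codes = encode_sequence(window)
    if (codes == N_CODE).any():
        raise ValueError("window contains N; ambiguous windows are not scorable")
    return float(pwm.weights[codes, np.arange(pwm.length)].sum())


def relative_score(pwm: PWM, raw: float) -> float:
    """Min-max normalised score, (raw - s_min) / (s_max - s_min) in [0, 1]."""
    if pwm.s_max <= pwm.s_min:
        raise ValueError(f"uninformative motif {pwm.motif_id!r}: s_max == s_min")
    return (raw - pwm.s_min) / (pwm.s_max - pwm.s_min)


def information_content(ppm: PPM) -> np.ndarray:
    """Per-column information content in bits, 2 + sum_b p log2 p.

    Assumes the uniform-background 2-bit ceiling used by sequence logos;
    0 * log 0 is taken as 0.
    """
    p = ppm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=0)


def logo_matrix(ppm: PPM) -> pd.DataFrame:
    """Sequence-logo export: per-position base probabilities plus IC (bits).

    Consumable by any logo renderer; no graphics are produced here.
    """
    ic = information_content(ppm)
    data = {"position": np.arange(ppm.length)}
    for i, b in enumerate(BASES):
        data[b] = ppm.probs[i]
    data["ic_bits"] = ic
    return pd.DataFrame(data)


def reverse_complement_pwm(pwm: PWM) -> PWM:
    """PWM scoring the reverse complement: rows A<->T, C<->G, columns reversed.

    Scoring a forward window with the returned matrix equals scoring the
    window's reverse complement with the original; s_min/s_max are unchanged.
    """
    return PWM(motif_id=pwm.motif_id, weights=pwm.weights[::-1, ::-1].copy())
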
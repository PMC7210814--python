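"""Promoter scanning with position weight matrices.

PFMs (base-count matrices, JASPAR text format) are converted to log2-odds
PWMs with a background-distributed pseudocount, every window of each promoter
is scored on both strands, and the best window per (gene, TF) pair is kept.
Pair ranking uses the relative score — the best-window score rescaled between
the PWM's minimum and maximum achievable scores — so motifs of different
lengths are comparable; the top fraction of pairs becomes the predicted
mRNA-TF interaction set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["N"] = 4
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

__all__ = [
    "PFMRecord",
    "pfm_to_pwm",
    "consensus",
    "scan_promoter",
    "score_all_pairs",
    "select_top_pairs",
]


@dataclass(frozen=True)
class PFMRecord:
    """A position frequency matrix: 4 x L base counts over (A, C, G, T)."""

    tf_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if np.any(counts < 0) or np.any(counts.sum(axis=0) <= 0):
            raise ValueError("counts must be non-negative with positive column sums")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


def pfm_to_pwm(
    pfm: PFMRecord,
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Log2-odds PWM from a PFM.

    Column probabilities are (count + pseudocount * background) / (column sum
    + pseudocount); each cell is log2(p / background). The pseudocount is
    distributed over bases proportionally to the background, the Biostrings /
    TFBSTools convention.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if background.shape != (4,) or np.any(background <= 0) or not math.isclose(
        background.sum(), 1.0, abs_tol=1e-9
    ):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    col_sums = pfm.counts.sum(axis=0)
    if pseudocount == 0 and np.any(pfm.counts.min(axis=0) == 0):
        if np.any((pfm.counts == 0).any(axis=0)):
            raise ValueError("zero count with zero pseudocount gives -inf log-odds")
    p = (pfm.counts + pseudocount * background[:, None]) / (col_sums + pseudocount)
    return np.log2(p / background[:, None])


def consensus(pfm: PFMRecord) -> str:
    """Per-column argmax consensus sequence (ties to the earlier base)."""
    return "".join(ALPHABET[i] for i in np.argmax(pfm.counts, axis=0))


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in sequence.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"sequence contains invalid base {exc}") from exc


def _window_scores(codes: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N score -inf."""
    length = pwm.shape[1]
    padded = np.vstack([pwm, np.full((1, length), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)
    return padded[windows, np.arange(length)].sum(axis=1)


def scan_promoter(pwm: np.ndarray, sequence: str) -> tuple[float, int, str]:
    """Best-window PWM score over both strands of one promoter.

    Returns (score, position, strand); the position is the 0-based offset of
    the winning window on the forward coordinate system regardless of strand.
    Ties resolve to the smallest forward position, then the + strand.
    """
    length = pwm.shape[1]
    if len(sequence) < length:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif length {length}"
        )
    codes = _encode(sequence)
    fwd = _window_scores(codes, pwm)
    rc_codes = _COMPLEMENT_CODE[codes[::-1]]
    rc = _window_scores(rc_codes, pwm)
    # window starting at q on the reverse complement covers forward
    # positions [n - L - q, n - q); re-index to forward coordinates
    rev = rc[::-1]

    best = max(fwd.max(), rev.max())
    hits_fwd = np.nonzero(fwd == best)[0]
    hits_rev = np.nonzero(rev == best)[0]
    pos_fwd = hits_fwd[0] if hits_fwd.size else np.inf
    pos_rev = hits_rev[0] if hits_rev.size else np.inf
    if pos_fwd <= pos_rev:
        return float(best), int(pos_fwd), "+"
    return float(best), int(pos_rev), "-"


def _score_bounds(pwm: np.ndarray) -> tuple[float, float]:
    return float(pwm.min(axis=0).sum()), float(pwm.max(axis=0).sum())


def score_all_pairs(
    pfms: list[PFMRecord],
    promoters: dict[str, str],
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score every (gene, TF) pair: best window, relative score, position.

    Returns one row per pair with columns gene, tf, score, rel_score,
    position, strand.
    """
    if not pfms or not promoters:
        raise ValueError("need at least one PFM and one promoter")
    rows = []
    for pfm in pfms:
        pwm = pfm_to_pwm(pfm, pseudocount=pseudocount, background=background)
        lo, hi = _score_bounds(pwm)
        for gene_id, seq in promoters.items():
            score, pos, strand = scan_promoter(pwm, seq)
            rel = (score - lo) / (hi - lo) if hi > lo else 1.0
            rows.append(
                {
                    "gene": gene_id,
                    "tf": pfm.tf_id,
                    "score": score,
                    "rel_score": rel,
                    "position": pos,
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows)


def select_top_pairs(pairs: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Retain the top fraction of pairs by relative score, ties inclusive.

    Retains ceil(fraction * N) pairs; any pair tied with the last retained
    score is also kept.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(pairs) == 0:
        return pairs.copy()
    ranked = pairs.sort_values(
        ["rel_score", "gene", "tf"], ascending=[False, True, True], kind="mergesort"
    )
    n_keep = math.ceil(fraction * len(ranked))
    cutoff = ranked["rel_score"].iloc[n_keep - 1]
    return ranked[ranked["rel_score"] >= cutoff].reset_index(drop=True)
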
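"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition with plain
loops, staying independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def bh_oracle(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg from the definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        q_i = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, q_i)
        q[i] = min(running_min, 1.0)
    return q


def tom_oracle(adj: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap from the formula."""
    n = adj.shape[0]
    k = adj.sum(axis=0)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n))
            denom = min(k[i], k[j]) + 1.0 - adj[i, j]
            tom[i, j] = (shared + adj[i, j]) / denom if denom > 0 else 0.0
    return tom


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def scan_oracle(pwm: np.ndarray, sequence: str) -> tuple[float, int, str]:
    """Exhaustive best-window scan over both strands with the documented tie rules."""
    length = pwm.shape[1]

    def window_score(seq: str, start: int) -> float:
        total = 0.0
        for offset in range(length):
            base = seq[start + offset]
            if base == "N":
                return -np.inf
            total += pwm[BASES.index(base), offset]
        return total

    best = (-np.inf, None, None)
    n = len(sequence)
    rc = revcomp(sequence)
    for pos in range(n - length + 1):
        for strand, score in (
            ("+", window_score(sequence, pos)),
            ("-", window_score(rc, n - length - pos)),
        ):
            # ties: smallest forward position, then + strand
            if score > best[0] + 1e-12:
                best = (score, pos, strand)
    return best


def hypergeom_mc(N: int, m: int, n: int, k: int, draws: int, rng) -> tuple[float, float]:
    """Permutation estimate of P(shared >= k) plus its binomial SE."""
    x = rng.hypergeometric(m, N - m, n, size=draws)
    p_hat = float(np.mean(x >= k))
    se = float(np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / draws))
    return p_hat, se
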
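"""Two-group differential expression screening.

Per-feature pooled-variance two-sample t-tests on log2 expression, with
Benjamini-Hochberg control of the false discovery rate. logFC is the tumor
minus non-tumor difference of group means, so positive values mean
up-regulation in tumors. Features are called significant when fdr < fdr_max
and |logFC| > logfc_min, both strict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirtfnet.preprocess import ExpressionProfile

__all__ = ["differential_expression", "bh_adjust", "select_features"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (classic FDR).

    Order-preserving with respect to the input indexing; output in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    profile: ExpressionProfile,
    variance_floor: float = 0.0,
) -> pd.DataFrame:
    """Screen every feature with a pooled two-sample t-test.

    Parameters
    ----------
    profile
        Expression with 0/1 group labels; each group needs >= 2 samples.
    variance_floor
        Lower clamp on the pooled variance, guarding zero-variance features.

    Returns
    -------
    DataFrame indexed by feature with columns ``logFC`` (mean group1 - mean
    group0), ``t_stat``, ``p_value``, ``fdr``.
    """
    g = profile.group.to_numpy()
    x1 = profile.values.loc[:, g == 1].to_numpy(dtype=float)
    x0 = profile.values.loc[:, g == 0].to_numpy(dtype=float)
    n1, n0 = x1.shape[1], x0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} and {n0})")

    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    logfc = m1 - m0
    s1 = x1.var(axis=1, ddof=1)
    s0 = x0.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2)
    pooled = np.maximum(pooled, variance_floor)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    df = n1 + n0 - 2
    # zero pooled variance: identical constant groups -> t=0/p=1, any
    # nonzero difference -> infinite t, p=0
    degenerate = np.where(logfc == 0, 0.0, np.where(logfc > 0, np.inf, -np.inf))
    t = np.where(se == 0, degenerate, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "t_stat": t,
            "p_value": p,
            "fdr": bh_adjust(p),
        },
        index=profile.values.index,
    )


def select_features(
    results: pd.DataFrame,
    fdr_max: float = 0.01,
    logfc_min: float = 1.0,
) -> set[str]:
    """Feature ids with fdr < fdr_max and |logFC| > logfc_min (both strict)."""
    if fdr_max < 0 or logfc_min < 0:
        raise ValueError("thresholds must be non-negative")
    mask = (results["fdr"] < fdr_max) & (results["logFC"].abs() > logfc_min)
    return set(results.index[mask])


def flag_significant(
    results: pd.DataFrame,
    fdr_max: float = 0.01,
    logfc_min: float = 1.0,
) -> pd.DataFrame:
    """Return a copy with a boolean ``significant`` column added."""
    out = results.copy()
    out["significant"] = (out["fdr"] < fdr_max) & (out["logFC"].abs() > logfc_min)
    return out
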
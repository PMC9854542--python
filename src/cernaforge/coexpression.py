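"""Co-expression screening between differential mRNAs and differential
lncRNAs/circRNAs.

Pearson correlation is computed on log2(normalized counts + 1); the two-sided
p-value comes from t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.
Significant pairs (raw p < alpha) are optionally restricted to positive r,
ranked by |r| descending (ties by p ascending, then lexicographic ids), and
the top_k kept — the "top 100" relationship list that feeds network assembly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def pearson_with_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("vectors must have equal length")
    if n < 3:
        raise ValueError("need at least three observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(min(1.0, p))


def log_transform(norm_counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing log2(x + 1) used for all correlation work."""
    return np.log2(norm_counts + 1.0)


def screen_pairs(
    mrna: pd.DataFrame,
    other: pd.DataFrame,
    alpha: float = 0.05,
    top_k: int = 100,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Test all cross-class pairs and keep the top-ranked significant ones.

    ``mrna`` and ``other`` are expression matrices (features x samples, already
    normalized and log-transformed) sharing sample columns. Pairs with a
    constant vector are skipped with a logged reason. Returns columns
    feature_a (mRNA), feature_b, r, p_value, n, rank.
    """
    shared = [s for s in mrna.columns if s in set(other.columns)]
    if not shared:
        raise ValueError("no shared samples between the two matrices")
    a_mat = mrna[shared]
    b_mat = other[shared]
    n = len(shared)

    # vectorized all-pairs Pearson on standardized rows
    def _standardize(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        arr = df.to_numpy(dtype=float)
        sd = arr.std(axis=1, ddof=1)
        keep = sd > 0
        z = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        return z, keep

    za, keep_a = _standardize(a_mat)
    zb, keep_b = _standardize(b_mat)
    n_dropped = int((~keep_a).sum() + (~keep_b).sum())
    if n_dropped:
        logger.info("skipped %d constant features in co-expression screening", n_dropped)
    ids_a = a_mat.index[keep_a]
    ids_b = b_mat.index[keep_b]
    r_mat = za @ zb.T / (n - 1)
    r_mat = np.clip(r_mat, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mat = r_mat * np.sqrt((n - 2) / (1.0 - r_mat**2))
    p_mat = 2.0 * stats.t.sf(np.abs(t_mat), n - 2)
    p_mat = np.where(np.abs(r_mat) == 1.0, 0.0, np.minimum(p_mat, 1.0))

    ii, jj = np.nonzero(p_mat < alpha)
    pairs = pd.DataFrame(
        {
            "feature_a": ids_a[ii],
            "feature_b": ids_b[jj],
            "r": r_mat[ii, jj],
            "p_value": p_mat[ii, jj],
            "n": n,
        }
    )
    if positive_only:
        pairs = pairs[pairs["r"] > 0]
    pairs = pairs.sort_values(
        by=["r", "p_value", "feature_a", "feature_b"],
        key=lambda col: -col.abs() if col.name == "r" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    pairs = pairs.head(max(0, int(top_k))).copy()
    pairs["rank"] = np.arange(1, len(pairs) + 1)
    return pairs
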
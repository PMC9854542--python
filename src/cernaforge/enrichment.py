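"""Hypergeometric over-representation analysis and qPCR relative expression.

A gene list of size n drawn from a universe of N ids, K of which belong to a
gene set, is scored by the upper-tail hypergeometric probability P(X >= k) of
observing at least the k overlapping ids. q-values are Benjamini-Hochberg
across the tested sets. Only enrichment (never depletion) is tested.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k = hits in the list, n = list size, K = set size in the universe,
    N = universe size.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k > K:
        raise ValueError(f"more hits ({k}) than set members ({K})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_list: list[str] | set[str],
    gene_sets: dict[str, list[str]],
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """One result row per gene set intersecting the universe, sorted by
    p ascending (ties by set id), with BH q-values across the tested sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    listed = set(gene_list) & universe
    if set(gene_list) - universe:
        extra = sorted(set(gene_list) - universe)
        raise ValueError(f"gene list ids outside the universe: {extra[:5]}")
    N = len(universe)
    n = len(listed)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        if not members:
            continue
        K = len(members)
        k = len(listed & members)
        rows.append(
            {
                "set_id": set_id,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": hypergeom_p(k, n, K, N),
            }
        )
    df = pd.DataFrame(rows, columns=["set_id", "k", "n", "K", "N", "p_value"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = []
    return df.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)


def relative_expression_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Comparative 2^-ddCt relative expression of a target gene.

    Each sample's target Ct is normalized to an endogenous reference gene
    (e.g. GAPDH); the fold change of treated vs control is 2^-ddCt with
    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    for ct in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not (ct == ct and abs(ct) != float("inf")):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
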
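"""Differential expression of count matrices in a two-group design.

Counts are modelled as negative binomial with Var = mu + alpha*mu^2. Libraries are
normalized by median-of-ratios size factors, per-gene dispersion is estimated by
method of moments with a small-sample floor, and the log2 fold change (treatment
over control) is tested with a Wald statistic. A feature is called differential
when p < alpha AND |log2FC| >= lfc (defaults 0.05 / 2; the p cut is strict, the
fold-change cut inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: pseudocount (normalized counts) added to group means in fold-change computation
FC_PSEUDOCOUNT = 0.5
#: floor for the method-of-moments dispersion estimate
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample: the median over features expressed in *all* samples of
    count / geometric-mean-across-samples. Identical samples receive equal
    factors; doubling a sample doubles its factor.
    """
    mat = counts.to_numpy(dtype=float)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "size factors undefined: no feature has nonzero counts in every sample"
        )
    sub = mat[expressed]
    log_geo_mean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo_mean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def _split_groups(groups: pd.Series) -> tuple[str, str]:
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, found {levels}")
    # CON (control) is the reference if present; otherwise first level sorts as reference
    if "CON" in levels:
        ref = "CON"
        alt = [g for g in levels if g != "CON"][0]
    else:
        ref, alt = levels
    return ref, alt


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    lfc: float = 2.0,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-feature NB Wald test of treatment vs control.

    Returns a table (feature_id index) with baseMean, log2FC, pvalue, significant,
    direction ('up'/'down'/'none'), and qvalue when ``bh`` is set. Significance
    uses raw p by default; ``bh=True`` swaps the Benjamini-Hochberg q-value into
    the p-arm of the rule.
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    ref, alt = _split_groups(groups)
    n_ref = int((groups == ref).sum())
    n_alt = int((groups == alt).sum())
    if min(n_ref, n_alt) < 2:
        raise ValueError("need at least two samples per group")

    norm = normalize_counts(counts).to_numpy(dtype=float)
    ref_mat = norm[:, (groups == ref).to_numpy()]
    alt_mat = norm[:, (groups == alt).to_numpy()]

    mean_ref = ref_mat.mean(axis=1)
    mean_alt = alt_mat.mean(axis=1)
    base_mean = norm.mean(axis=1)

    log2fc = np.log2((mean_alt + FC_PSEUDOCOUNT) / (mean_ref + FC_PSEUDOCOUNT))
    # zero/zero: no evidence either way
    log2fc[(mean_ref == 0) & (mean_alt == 0)] = 0.0

    # method-of-moments dispersion pooled across the two groups:
    # alpha_hat = (s^2 - mu) / mu^2, averaged group-wise, floored
    disp = np.full(counts.shape[0], DISPERSION_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_ref = (ref_mat.var(axis=1, ddof=1) - mean_ref) / np.square(mean_ref)
        d_alt = (alt_mat.var(axis=1, ddof=1) - mean_alt) / np.square(mean_alt)
    for d in (d_ref, d_alt):
        np.nan_to_num(d, copy=False, nan=0.0, posinf=0.0, neginf=0.0)
    disp = np.maximum((d_ref + d_alt) / 2.0, DISPERSION_FLOOR)

    # Wald SE of log2FC by the delta method on log group means,
    # Var(mean) = (mu + alpha*mu^2)/n
    mu_ref = mean_ref + FC_PSEUDOCOUNT
    mu_alt = mean_alt + FC_PSEUDOCOUNT
    var_ref = (mu_ref + disp * mu_ref**2) / n_ref
    var_alt = (mu_alt + disp * mu_alt**2) / n_alt
    se_log2fc = np.sqrt(var_ref / mu_ref**2 + var_alt / mu_alt**2) / np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se_log2fc > 0, log2fc / se_log2fc, 0.0)
    # t reference with the two-group residual df absorbs the moment-estimation
    # noise of the dispersion at small n (normal reference is anti-conservative)
    df = n_ref + n_alt - 2
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df)
    pvalue = np.clip(pvalue, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "pvalue": pvalue,
        },
        index=counts.index.rename("feature_id"),
    )
    p_arm = table["pvalue"]
    if bh:
        from statsmodels.stats.multitest import multipletests

        table["qvalue"] = multipletests(pvalue, method="fdr_bh")[1]
        p_arm = table["qvalue"]
    table["significant"] = (p_arm < alpha) & (np.abs(table["log2FC"]) >= lfc)
    table["direction"] = np.where(
        ~table["significant"], "none", np.where(table["log2FC"] > 0, "up", "down")
    )
    return table


def summarize_de(table: pd.DataFrame) -> dict[str, int]:
    """Counts of significant features: total = n_up + n_down."""
    if len(table) == 0:
        return {"total": 0, "n_up": 0, "n_down": 0}
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    return {"total": n_up + n_down, "n_up": n_up, "n_down": n_down}


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (column total * feature length in bp)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero column total for samples: {bad}")
    return counts * 1e9 / totals / lengths.to_numpy()[:, None]
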
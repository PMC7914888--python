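"""Per-miRNA two-condition differential expression on negative-binomial counts.

The model is NB(mu, alpha) with variance mu + alpha * mu^2.  Dispersion is
estimated per miRNA by method of moments on normalized counts; the null of
equal group means is tested with a Wald statistic on the log2 fold change,
whose standard error comes from the delta method.  This is a deliberate
simplification of the DESeq2 machinery: no dispersion shrinkage across genes,
no independent filtering, no outlier handling.  Multiple testing is handled
with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, normalize

#: pseudocount added to group means before taking log2, bounding fold changes
#: of genes with zero counts in one group
LFC_EPS = 0.5


@dataclass
class DERecord:
    """One row of a differential-expression table."""

    mirna_id: str
    baseMean: float
    log2FoldChange: float
    p_value: float
    p_adj: float = np.nan
    flagged: bool = False


def mom_dispersion(norm_counts: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion from normalized counts.

    alpha_hat = max(0, (pooled within-group variance - pooled mean) /
    pooled mean^2); 0 when the gene is under-dispersed or all zero.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    groups = np.asarray(groups)
    mean = norm_counts.mean()
    if mean <= 0:
        return 0.0
    num = 0.0
    den = 0
    for g in np.unique(groups):
        x = norm_counts[groups == g]
        if len(x) < 2:
            raise ValueError("need >=2 samples per group for dispersion")
        num += (len(x) - 1) * x.var(ddof=1)
        den += len(x) - 1
    pooled_var = num / den
    return max(0.0, (pooled_var - mean) / mean**2)


def nb_wald_test(
    gene_counts: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray,
    reference: str,
    test: str,
) -> tuple[float, float, float, bool]:
    """Wald test of equal means between two conditions for one miRNA.

    Returns ``(baseMean, log2FoldChange, p_value, flagged)``.  The fold change
    is log2((mean_test + eps) / (mean_ref + eps)) of normalized counts with
    eps = 0.5; its standard error follows from the delta method under
    NB(mu_hat per group, alpha_hat), with the per-sample variance divided by
    the squared size factor to account for normalization.
    """
    gene_counts = np.asarray(gene_counts, dtype=float)
    size_factors = np.asarray(size_factors, dtype=float)
    groups = np.asarray(groups)
    norm = gene_counts / size_factors

    sel = np.isin(groups, [reference, test])
    norm2, groups2, sf2 = norm[sel], groups[sel], size_factors[sel]
    for g in (reference, test):
        if (groups2 == g).sum() < 2:
            raise ValueError(f"need >=2 samples in group {g!r}")

    base_mean = norm2.mean()
    mean_ref = norm2[groups2 == reference].mean()
    mean_test = norm2[groups2 == test].mean()
    lfc = float(np.log2((mean_test + LFC_EPS) / (mean_ref + LFC_EPS)))

    if mean_ref == 0 and mean_test == 0:
        return 0.0, 0.0, 1.0, True

    alpha = mom_dispersion(norm2, groups2)

    # Var(mean of normalized counts) per group; K_s ~ NB(f_s mu, alpha), and
    # the normalized value K_s/f_s has variance (f_s mu + alpha f_s^2 mu^2)/f_s^2.
    def var_of_group_mean(mu: float, g: str) -> float:
        f = sf2[groups2 == g]
        per_sample = (f * mu + alpha * (f * mu) ** 2) / f**2
        return float(per_sample.sum() / len(f) ** 2)

    ln2sq = np.log(2.0) ** 2
    var_lfc = (
        var_of_group_mean(mean_test, test) / ((mean_test + LFC_EPS) ** 2 * ln2sq)
        + var_of_group_mean(mean_ref, reference) / ((mean_ref + LFC_EPS) ** 2 * ln2sq)
    )
    if var_lfc <= 0:
        p = 1.0 if lfc == 0 else 0.0
        return float(base_mean), lfc, max(p, np.finfo(float).tiny), lfc != 0
    z = lfc / np.sqrt(var_lfc)
    # t reference with within-group degrees of freedom: the plug-in variance
    # is itself estimated from very few replicates, and normal tails are
    # badly anticonservative at n=3 per group
    df = (groups2 == reference).sum() + (groups2 == test).sum() - 2
    p = float(2.0 * stats.t.sf(abs(z), df))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return float(base_mean), lfc, p, False


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(m: CountMatrix, reference: str, test: str) -> pd.DataFrame:
    """Run the NB Wald test for every miRNA of a two-condition contrast.

    Returns a table with columns mirna_id, baseMean, log2FoldChange, pvalue,
    padj (the classic DESeq2-results layout), one row per miRNA, in input
    order.
    """
    nm = normalize(m)
    sf = nm.size_factors.to_numpy()
    groups = np.array([m.groups[s] for s in m.sample_ids])
    rows = []
    for mid in m.mirna_ids:
        counts = m.counts.loc[mid].to_numpy()
        base, lfc, p, flagged = nb_wald_test(counts, sf, groups, reference, test)
        rows.append((mid, base, lfc, p, flagged))
    df = pd.DataFrame(
        rows, columns=["mirna_id", "baseMean", "log2FoldChange", "pvalue", "flagged"]
    )
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    return df[["mirna_id", "baseMean", "log2FoldChange", "pvalue", "padj", "flagged"]]


def de_table(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Filter to padj < alpha and sort under-expressed first.

    Rows are ordered by sign of log2FoldChange (negative first), then by
    baseMean descending, mirroring the usual published-table layout.
    """
    kept = records[records["padj"] < alpha].copy()
    kept["_sign"] = np.sign(kept["log2FoldChange"])
    kept = kept.sort_values(
        ["_sign", "baseMean"], ascending=[True, False], kind="stable"
    ).drop(columns="_sign")
    return kept.reset_index(drop=True)


def de_mirnas(records: pd.DataFrame, alpha: float = 0.05, block: str = "all") -> list[str]:
    """Ids of significant miRNAs, optionally restricted to a direction block.

    ``block`` is one of ``all``, ``over`` (log2FC > 0) or ``under``
    (log2FC < 0).
    """
    sig = records[records["padj"] < alpha]
    if block == "over":
        sig = sig[sig["log2FoldChange"] > 0]
    elif block == "under":
        sig = sig[sig["log2FoldChange"] < 0]
    elif block != "all":
        raise ValueError(f"unknown block {block!r}")
    return sig["mirna_id"].tolist()
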
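"""Immune-related lncRNA screening.

Two filters applied in order:

1. coexpression — a lncRNA is "immune-related" if its expression correlates
   with at least one immune gene (Pearson r above a threshold with a small
   test p), computed on tumor samples by default;
2. differential expression — immune-related lncRNAs are tested tumor vs
   normal with the unpaired Wilcoxon rank-sum test and kept below a
   Benjamini-Hochberg FDR ceiling computed within the candidate set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import ExpressionMatrix

logger = logging.getLogger("pairrisk")

# exact rank-sum null is enumerable at these sizes; beyond, the normal
# approximation with tie and continuity corrections is accurate
EXACT_RANKSUM_MAX_N = 12


def immune_coexpression(expr: ExpressionMatrix, annotation: pd.DataFrame,
                        config: PipelineConfig | None = None):
    """Identify immune-related lncRNAs by correlation with immune genes.

    Returns ``(ids, hits)``: the set of retained lncRNA ids and a DataFrame
    of every passing (lncrna_id, immune_gene_id, rho, p) correlation.
    Constant genes have no defined correlation and are excluded with a
    warning.
    """
    config = config or PipelineConfig()
    lnc_ids = [g for g in expr.gene_ids
               if g in annotation.index and annotation.loc[g, "biotype"] == "lncRNA"]
    imm_ids = [g for g in expr.gene_ids
               if g in annotation.index
               and annotation.loc[g, "biotype"] == "protein_coding"
               and bool(annotation.loc[g, "is_immune"])]
    if not imm_ids:
        raise ValueError("no immune genes present in the expression matrix")
    if not lnc_ids:
        raise ValueError("no lncRNAs present in the expression matrix")

    if config.corr_tumor_only and "tumor" in set(expr.group):
        samples = expr.samples_in_group("tumor")
    else:
        samples = expr.sample_ids
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for the coexpression screen")

    L = expr.values.loc[lnc_ids, samples].to_numpy(float)
    M = expr.values.loc[imm_ids, samples].to_numpy(float)
    n = len(samples)

    def standardize(A):
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        const = sd[:, 0] == 0
        sd[const] = np.nan
        return (A - mu) / sd, const

    Lz, l_const = standardize(L)
    Mz, m_const = standardize(M)
    if l_const.any():
        logger.warning("%d constant lncRNAs excluded from coexpression screen",
                       int(l_const.sum()))
    if m_const.any():
        logger.warning("%d constant immune genes excluded from coexpression screen",
                       int(m_const.sum()))

    rho = (Lz @ Mz.T) / n  # lncRNA x immune gene Pearson matrix
    rho = np.clip(rho, -1.0, 1.0)
    # two-sided t test for zero correlation, n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pval[np.abs(rho) >= 1.0] = 0.0

    strength = np.abs(rho) if config.corr_absolute else rho
    passing = (strength > config.corr_min) & (pval < config.corr_p_max)
    passing &= ~np.isnan(rho)

    li, mi = np.nonzero(passing)
    hits = pd.DataFrame({
        "lncrna_id": [lnc_ids[i] for i in li],
        "immune_gene_id": [imm_ids[j] for j in mi],
        "rho": rho[li, mi],
        "p": pval[li, mi],
    })
    ids = sorted(set(hits["lncrna_id"]), key=lnc_ids.index)
    return ids, hits


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p for samples ``x`` vs ``y``.

    Exact null when both groups are small with no ties across the pooled
    sample; otherwise normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if (len(x) <= EXACT_RANKSUM_MAX_N and len(y) <= EXACT_RANKSUM_MAX_N
            and not has_ties):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def differential_expression(expr: ExpressionMatrix, candidates,
                            config: PipelineConfig | None = None) -> pd.DataFrame:
    """Tumor-vs-normal rank-sum screen over candidate genes.

    Returns a DataFrame indexed by gene_id with ``log2fc`` (tumor mean minus
    normal mean on the log2 scale), raw ``p``, BH ``fdr`` over the candidate
    set, ``direction`` and a ``significant`` flag (fdr below the configured
    ceiling).
    """
    config = config or PipelineConfig()
    tumor = expr.samples_in_group("tumor")
    normal = expr.samples_in_group("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("differential expression needs >= 2 samples per group")
    candidates = [g for g in candidates]
    missing = [g for g in candidates if g not in expr.values.index]
    if missing:
        raise KeyError(f"candidate genes missing from matrix: {missing[:5]}")

    T = expr.values.loc[candidates, tumor].to_numpy(float)
    N = expr.values.loc[candidates, normal].to_numpy(float)
    log2fc = T.mean(axis=1) - N.mean(axis=1)
    pvals = np.array([rank_sum_test(T[i], N[i]) for i in range(len(candidates))])

    if len(pvals):
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        fdr = pvals
    out = pd.DataFrame({
        "log2fc": log2fc,
        "p": pvals,
        "fdr": fdr,
        "direction": np.where(log2fc > 0, "up", "down"),
    }, index=pd.Index(candidates, name="gene_id"))
    out["significant"] = out["fdr"] < config.de_fdr_max
    return out


def de_gene_ids(de_table: pd.DataFrame) -> list:
    """Gene ids passing the FDR screen, in table order."""
    return list(de_table.index[de_table["significant"]])
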
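"""Yin/Yang gene calling and per-tumor response vectors.

Yin genes are significantly upregulated in tumors versus normals
(logFC >= 1, FDR < 0.05); Yang genes the mirror image (logFC <= -1).
Differential testing uses a per-gene Welch t-test with Benjamini-Hochberg
adjustment over the full tested gene universe. The per-tumor response
``y_{g,k}`` is the tumor's log2 expression minus the mean normal log2
expression of the gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

FDR_CUT = 0.05
LFC_CUT = 1.0


def test_differential(
    tumor_expr: ExpressionMatrix, normal_expr: ExpressionMatrix
) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs. normal log2 expression.

    Returns a DataFrame indexed by gene with columns ``logFC`` (tumor mean
    minus normal mean on the log2 scale), ``p``, ``fdr`` and ``yclass``.
    Genes with fewer than two non-missing values in either group are
    excluded as untestable.
    """
    common = tumor_expr.values.index.intersection(normal_expr.values.index)
    t = tumor_expr.values.loc[common].to_numpy(dtype=float)
    n = normal_expr.values.loc[common].to_numpy(dtype=float)
    testable = (np.sum(~np.isnan(t), axis=1) >= 2) & (np.sum(~np.isnan(n), axis=1) >= 2)
    genes = common[testable]
    t, n = t[testable], n[testable]
    logfc = np.nanmean(t, axis=1) - np.nanmean(n, axis=1)
    res = stats.ttest_ind(t, n, axis=1, equal_var=False, nan_policy="omit")
    pvals = np.asarray(res.pvalue, dtype=float)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    records = pd.DataFrame(
        {"logFC": logfc, "p": pvals, "fdr": fdr}, index=pd.Index(genes, name="gene")
    )
    records["yclass"] = "none"
    records.loc[(records["fdr"] < FDR_CUT) & (records["logFC"] >= LFC_CUT), "yclass"] = "Yin"
    records.loc[(records["fdr"] < FDR_CUT) & (records["logFC"] <= -LFC_CUT), "yclass"] = "Yang"
    return records


def select_yin_yang(
    records: pd.DataFrame, fdr_cut: float = FDR_CUT, lfc_cut: float = LFC_CUT
) -> tuple[set[str], set[str]]:
    """Split differential records into (yin, yang) gene sets.

    Yin: fdr < ``fdr_cut`` and logFC >= ``lfc_cut`` (boundary included);
    Yang: fdr < ``fdr_cut`` and logFC <= -``lfc_cut``. The sets are disjoint.
    """
    sig = records["fdr"] < fdr_cut
    yin = set(records.index[sig & (records["logFC"] >= lfc_cut)])
    yang = set(records.index[sig & (records["logFC"] <= -lfc_cut)])
    return yin, yang


def tumor_fold_changes(
    tumor_expr: ExpressionMatrix,
    normal_expr: ExpressionMatrix,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per (gene, tumor) response y_{g,k} = expr_{g,k} - mean_normal(expr_g).

    The normal reference is the mean over all normal samples. Also used for
    miRNA fold changes (rows are then miRNAs).
    """
    if genes is None:
        genes = list(tumor_expr.values.index)
    missing = set(genes) - set(normal_expr.values.index)
    if missing:
        raise ValueError(f"genes absent from normal samples: {sorted(missing)[:5]}")
    missing_t = set(genes) - set(tumor_expr.values.index)
    if missing_t:
        raise ValueError(f"genes absent from tumor samples: {sorted(missing_t)[:5]}")
    normal_mean = normal_expr.values.loc[genes].mean(axis=1)
    return tumor_expr.values.loc[genes].sub(normal_mean, axis=0)
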
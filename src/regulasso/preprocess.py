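"""Reading, transforming and aligning the multi-platform inputs.

File dialect is Xena-like throughout: tab-separated, header row, first
column the feature id (genes x samples for expression/CNV/methylation,
genes x regulators for binding matrices).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr

from .containers import (
    SUBTYPES,
    UNCLASSIFIED,
    BindingMatrix,
    ExpressionMatrix,
    OmicsDataset,
)

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200


# ---------------------------------------------------------------------------
# Plain TSV matrix IO


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("id").to_csv(path, sep="\t")


def read_subtype_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("subtype")


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"patient", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# Transforms


def log_transform(raw: pd.DataFrame, unit: str = "gene-RSEM") -> ExpressionMatrix:
    """Elementwise log2(x+1); refuses input already tagged as log scale."""
    if unit.endswith("-log2"):
        raise ValueError(f"input tagged {unit!r} is already log2 transformed")
    arr = raw.to_numpy(dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("raw expression must be non-negative")
    return ExpressionMatrix(np.log2(raw.astype(float) + 1.0), unit + "-log2")


def aggregate_mirna_isoforms(isoform_rpm: pd.DataFrame) -> ExpressionMatrix:
    """Sum isoform RPM per mature strand and sample, then log2(total+1).

    Expects a long table with columns ``isoform``, ``mature_id``, ``sample``,
    ``rpm``. Duplicate (isoform, sample) rows are an input error.
    """
    required = {"isoform", "mature_id", "sample", "rpm"}
    if not required.issubset(isoform_rpm.columns):
        raise ValueError(f"isoform table needs columns {sorted(required)}")
    if isoform_rpm["rpm"].min() < 0:
        raise ValueError("RPM values must be non-negative")
    if isoform_rpm.duplicated(subset=["isoform", "sample"]).any():
        raise ValueError("duplicate (isoform, sample) rows in isoform table")
    total = (
        isoform_rpm.groupby(["mature_id", "sample"])["rpm"]
        .sum()
        .unstack("sample")
        .fillna(0.0)
    )
    total.index.name = None
    total.columns.name = None
    return ExpressionMatrix(np.log2(total + 1.0), "miRNA-RPM-log2")


def filter_missing(
    matrix: ExpressionMatrix, max_missing_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop features missing in strictly more than the given sample fraction."""
    if matrix.values.empty:
        raise ValueError("cannot filter an empty matrix")
    frac = matrix.values.isna().mean(axis=1)
    return ExpressionMatrix(matrix.values.loc[frac <= max_missing_fraction], matrix.unit)


def average_gene_methylation(probe_betas: pd.DataFrame) -> pd.DataFrame:
    """Average probe-level beta values per (gene, sample).

    Expects a long table with columns ``probe``, ``gene``, ``sample``,
    ``beta``; the probe-to-gene map is taken as given.
    """
    required = {"probe", "gene", "sample", "beta"}
    if not required.issubset(probe_betas.columns):
        raise ValueError(f"methylation table needs columns {sorted(required)}")
    beta = probe_betas["beta"]
    if beta.min() < 0 or beta.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    out = probe_betas.groupby(["gene", "sample"])["beta"].mean().unstack("sample")
    out.index.name = None
    out.columns.name = None
    return out


def mean_impute(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean imputation across samples (lasso needs complete rows)."""
    row_means = matrix.mean(axis=1)
    return matrix.apply(lambda col: col.fillna(row_means))


# ---------------------------------------------------------------------------
# Subtype assignment


def assign_subtype(er: str, pr_status: str, her2: str) -> str:
    """IHC receptor status to molecular subtype.

    LumA: (ER+ or PR+) and HER2-; LumB: (ER+ or PR+) and HER2+;
    Her2: ER- and PR- and HER2+; TN: all three negative. Anything involving
    missing/equivocal status that no rule covers is ``unclassified``.
    """
    hr_positive = er == "+" or pr_status == "+"
    hr_both_negative = er == "-" and pr_status == "-"
    if her2 == "-":
        if hr_positive:
            return "LumA"
        if hr_both_negative:
            return "TN"
    elif her2 == "+":
        if hr_positive:
            return "LumB"
        if hr_both_negative:
            return "Her2"
    return UNCLASSIFIED


def assign_subtypes(ihc: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`assign_subtype` over a table with er/pr/her2 columns."""
    return pd.Series(
        [assign_subtype(r.er, r.pr, r.her2) for r in ihc.itertuples()],
        index=ihc.index,
        name="subtype",
    )


# ---------------------------------------------------------------------------
# ChIP-seq peaks -> promoter binding matrix


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


def map_peaks_to_promoters(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> BindingMatrix:
    """Average ChIP peak scores over promoter windows per (gene, regulator).

    The promoter is ``[TSS - upstream, TSS + downstream)`` on the + strand
    and ``[TSS - downstream, TSS + upstream)`` on the - strand (0-based
    half-open). A peak counts if it overlaps the window by >= 1 bp; the cell
    value is the mean score of overlapping peaks, 0 if none.

    ``peaks``: columns chrom, start, end, name (regulator id), score, strand.
    ``tss``: columns gene, chrom, position, strand.
    """
    strands = set(tss["strand"].unique())
    if not strands.issubset({"+", "-"}):
        raise ValueError(f"unknown strand value(s): {sorted(strands - {'+', '-'})}")
    prom_start = np.where(
        tss["strand"] == "+", tss["position"] - upstream, tss["position"] - downstream
    )
    prom_end = np.where(
        tss["strand"] == "+", tss["position"] + downstream, tss["position"] + upstream
    )
    promoters = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": tss["chrom"].to_numpy(),
                "Start": np.maximum(prom_start, 0),
                "End": prom_end,
                "gene": tss["gene"].to_numpy(),
            }
        )
    )
    peak_ranges = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": peaks["chrom"].to_numpy(),
                "Start": peaks["start"].to_numpy(),
                "End": peaks["end"].to_numpy(),
                "regulator": peaks["name"].to_numpy(),
                "score": peaks["score"].to_numpy(dtype=float),
            }
        )
    )
    joined = promoters.join(peak_ranges).df
    genes = sorted(tss["gene"].unique())
    regulators = sorted(peaks["name"].unique())
    matrix = pd.DataFrame(0.0, index=genes, columns=regulators)
    if not joined.empty:
        means = joined.groupby(["gene", "regulator"])["score"].mean()
        for (g, r), v in means.items():
            matrix.loc[g, r] = v
    return BindingMatrix(matrix)


# ---------------------------------------------------------------------------
# Alignment


def intersect_common(
    tumor_expression: ExpressionMatrix,
    normal_expression: ExpressionMatrix,
    mirna_expression: ExpressionMatrix,
    mirna_normal_expression: ExpressionMatrix,
    cnv: pd.DataFrame,
    methylation: pd.DataFrame,
    tf_binding: BindingMatrix,
    mirna_binding: BindingMatrix,
    subtype: pd.Series,
) -> OmicsDataset:
    """Subset everything to the common tumors / genes / miRNAs, sorted.

    The gene universe is the intersection across expression, CNV,
    methylation and both binding matrices; tumors must carry expression,
    CNV, methylation, miRNA expression and a subtype label; miRNAs must
    have tumor and normal expression and a binding column.
    """
    genes = sorted(
        set(tumor_expression.values.index)
        & set(normal_expression.values.index)
        & set(cnv.index)
        & set(methylation.index)
        & set(tf_binding.counts.index)
        & set(mirna_binding.counts.index)
    )
    tumors = sorted(
        set(tumor_expression.values.columns)
        & set(cnv.columns)
        & set(methylation.columns)
        & set(mirna_expression.values.columns)
        & set(subtype.index)
    )
    mirnas = sorted(
        set(mirna_expression.values.index)
        & set(mirna_normal_expression.values.index)
        & set(mirna_binding.counts.columns)
    )
    if not genes:
        raise ValueError("no common genes across platforms")
    if not tumors:
        raise ValueError("no common tumor samples across platforms")
    if not mirnas:
        raise ValueError("no common miRNAs across platforms")
    normals = sorted(normal_expression.values.columns)
    mirna_normals = sorted(mirna_normal_expression.values.columns)
    tfs = sorted(tf_binding.counts.columns)
    return OmicsDataset(
        tumor_expression=ExpressionMatrix(
            tumor_expression.values.loc[genes, tumors], tumor_expression.unit
        ),
        normal_expression=ExpressionMatrix(
            normal_expression.values.loc[genes, normals], normal_expression.unit
        ),
        mirna_expression=ExpressionMatrix(
            mirna_expression.values.loc[mirnas, tumors], mirna_expression.unit
        ),
        mirna_normal_expression=ExpressionMatrix(
            mirna_normal_expression.values.loc[mirnas, mirna_normals],
            mirna_normal_expression.unit,
        ),
        cnv=cnv.loc[genes, tumors],
        methylation=methylation.loc[genes, tumors],
        tf_binding=BindingMatrix(tf_binding.counts.loc[genes, tfs]),
        mirna_binding=BindingMatrix(mirna_binding.counts.loc[genes, mirnas]),
        subtype=subtype.loc[tumors],
    )


def read_dataset(indir: str | Path) -> OmicsDataset:
    """Read a directory written by :func:`regulasso.simulate.write_dataset`."""
    indir = Path(indir)
    return intersect_common(
        tumor_expression=ExpressionMatrix(
            read_matrix_tsv(indir / "expression_tumor.tsv"), "gene-RSEM-log2"
        ),
        normal_expression=ExpressionMatrix(
            read_matrix_tsv(indir / "expression_normal.tsv"), "gene-RSEM-log2"
        ),
        mirna_expression=ExpressionMatrix(
            read_matrix_tsv(indir / "mirna_tumor.tsv"), "miRNA-RPM-log2"
        ),
        mirna_normal_expression=ExpressionMatrix(
            read_matrix_tsv(indir / "mirna_normal.tsv"), "miRNA-RPM-log2"
        ),
        cnv=read_matrix_tsv(indir / "cnv.tsv"),
        methylation=read_matrix_tsv(indir / "methylation.tsv"),
        tf_binding=BindingMatrix(read_matrix_tsv(indir / "tf_binding.tsv")),
        mirna_binding=BindingMatrix(read_matrix_tsv(indir / "mirna_binding.tsv")),
        subtype=read_subtype_tsv(indir / "subtypes.tsv"),
    )
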
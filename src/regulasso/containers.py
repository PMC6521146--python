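"""Aligned multi-omics containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical breast-cancer IHC subtype labels, in fixed report order.
SUBTYPES = ("LumA", "LumB", "Her2", "TN")

#: Sentinel label for tumors whose receptor status does not match any rule.
UNCLASSIFIED = "unclassified"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Feature x sample expression on the log2(x+1) scale.

    ``unit`` records provenance (``gene-RSEM`` or ``miRNA-RPM``) and whether
    the log2 transform has been applied (``-log2`` suffix), which guards
    against double transformation.
    """

    values: pd.DataFrame
    unit: str = "gene-RSEM-log2"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "row")
        _check_unique(self.values.columns, "column")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def is_log(self) -> bool:
        return self.unit.endswith("-log2")

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.unit)


@dataclass
class BindingMatrix:
    """Target-gene x regulator matrix of binding-site counts or ChIP scores."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "target")
        _check_unique(self.counts.columns, "regulator")
        arr = self.counts.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("binding matrix must be finite")
        if arr.min(initial=0.0) < 0:
            raise ValueError("binding matrix must be non-negative")

    @property
    def regulators(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class OmicsDataset:
    """All platforms aligned on common tumors, genes and miRNAs.

    Matrices are pandas DataFrames: expression genes x samples (log2 scale),
    ``cnv`` genes x tumors (GISTIC2-style scores in {-2..2}), ``methylation``
    genes x tumors (beta values in [0, 1]), binding matrices genes x
    regulators, and ``subtype`` a per-tumor label Series.
    """

    tumor_expression: ExpressionMatrix
    normal_expression: ExpressionMatrix
    mirna_expression: ExpressionMatrix
    mirna_normal_expression: ExpressionMatrix
    cnv: pd.DataFrame
    methylation: pd.DataFrame
    tf_binding: BindingMatrix
    mirna_binding: BindingMatrix
    subtype: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        genes = self.tumor_expression.values.index
        tumors = self.tumor_expression.values.columns
        mirnas = self.mirna_expression.values.index
        for name, idx in [
            ("normal expression genes", self.normal_expression.values.index),
            ("cnv genes", self.cnv.index),
            ("methylation genes", self.methylation.index),
            ("tf_binding genes", self.tf_binding.counts.index),
            ("mirna_binding genes", self.mirna_binding.counts.index),
        ]:
            if not idx.equals(genes):
                raise ValueError(f"{name} not aligned with tumor expression genes")
        for name, idx in [
            ("cnv tumors", self.cnv.columns),
            ("methylation tumors", self.methylation.columns),
            ("mirna expression tumors", self.mirna_expression.values.columns),
            ("subtype tumors", self.subtype.index),
        ]:
            if not idx.equals(tumors):
                raise ValueError(f"{name} not aligned with tumor expression samples")
        if not self.mirna_binding.counts.columns.equals(mirnas):
            raise ValueError("mirna_binding regulators not aligned with miRNA ids")
        if not self.mirna_normal_expression.values.index.equals(mirnas):
            raise ValueError("normal miRNA ids not aligned")
        beta = self.methylation.to_numpy(dtype=float)
        finite = beta[np.isfinite(beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("methylation beta values must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.tumor_expression.values.index)

    @property
    def tumors(self) -> list[str]:
        return list(self.tumor_expression.values.columns)

    @property
    def mirnas(self) -> list[str]:
        return list(self.mirna_expression.values.index)

    @property
    def tfs(self) -> list[str]:
        return list(self.tf_binding.counts.columns)

    def tumors_of(self, subtype: str) -> list[str]:
        return list(self.subtype.index[self.subtype == subtype])
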
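"""Hypergeometric gene-set enrichment and regulator-target network export.

Enrichment of a regulator's target list against a GMT collection uses the
hypergeometric upper tail P(X >= k) with X ~ Hypergeometric(N, K, n):
N genes in the universe, K in the gene set, n targets, k in the overlap.
Gene sets outside the size window are skipped (pathway mode: 2..500;
GO mode: 10..500) and p-values are BH adjusted over the tested sets.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from gseapy import read_gmt as _gseapy_read_gmt
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import BindingMatrix

PATHWAY_MIN_SIZE, PATHWAY_MAX_SIZE = 2, 500
GO_MIN_SIZE, GO_MAX_SIZE = 10, 500
PATHWAY_FDR_CUT = 0.01
GO_FDR_CUT = 0.05


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file (name, description, tab-separated gene ids)."""
    return {name: list(genes) for name, genes in _gseapy_read_gmt(str(path)).items()}


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def hypergeom_enrich(
    targets: set[str],
    collection: dict[str, list[str]],
    min_size: int = PATHWAY_MIN_SIZE,
    max_size: int = PATHWAY_MAX_SIZE,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``targets`` in each gene set.

    The universe defaults to all genes appearing anywhere in the collection;
    target genes outside the universe are dropped with a warning. Returns a
    DataFrame with columns set, k, n, K, N, p, fdr sorted by p.
    """
    if universe is None:
        universe = set().union(*collection.values()) if collection else set()
    stray = set(targets) - universe
    if stray:
        warnings.warn(
            f"{len(stray)} target gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    targets_in = set(targets) & universe
    N, n = len(universe), len(targets_in)
    rows = []
    for name, genes in collection.items():
        members = set(genes) & universe
        K = len(members)
        if K < min_size or K > max_size:
            continue
        k = len(targets_in & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "n": n, "K": K, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "p"])
    if not out.empty:
        _, fdr, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["fdr"] = fdr
        out = out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def regulator_targets(
    regulator: str,
    binding: BindingMatrix | pd.DataFrame,
    yin_yang: set[str],
) -> set[str]:
    """Genes with a nonzero binding entry for the regulator, restricted to
    the identified yin/yang genes."""
    df = binding.counts if isinstance(binding, BindingMatrix) else binding
    if regulator not in df.columns:
        raise KeyError(f"unknown regulator {regulator!r}")
    hit = set(df.index[df[regulator] > 0])
    return hit & yin_yang


def build_network_table(
    regulators: set[str] | list[str],
    tf_binding: BindingMatrix | pd.DataFrame,
    mirna_binding: BindingMatrix | pd.DataFrame,
    pathway_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Regulator-target edge table restricted to pathway-member targets.

    Rows are (source regulator, target gene, hits = binding-site count) for
    every selected regulator and every gene with nonzero hits that belongs
    to at least one of the pathway sets; ordered by (source, target).
    """
    tf_df = tf_binding.counts if isinstance(tf_binding, BindingMatrix) else tf_binding
    mir_df = (
        mirna_binding.counts
        if isinstance(mirna_binding, BindingMatrix)
        else mirna_binding
    )
    pathway_genes: set[str] = set()
    for genes in pathway_sets.values():
        pathway_genes.update(genes)
    rows = []
    for r in sorted(regulators):
        if r in tf_df.columns:
            col = tf_df[r]
        elif r in mir_df.columns:
            col = mir_df[r]
        else:
            continue
        hits = col[(col > 0) & col.index.isin(pathway_genes)]
        for g in sorted(hits.index):
            rows.append({"source": r, "target": g, "hits": float(hits[g])})
    return pd.DataFrame(rows, columns=["source", "target", "hits"])


def write_sif(edge_table: pd.DataFrame, path: str | Path, interaction: str = "targets") -> None:
    """Write the edge table in SIF format for Cytoscape import."""
    with open(path, "w") as fh:
        for row in edge_table.itertuples(index=False):
            fh.write(f"{row.source}\t{interaction}\t{row.target}\n")
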
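"""End-to-end orchestration: dataset -> models -> regulators -> outputs.

Thin glue over the analysis modules, used by the command-line interface
and by reproducibility checks. All outputs are plain TSV and fully
determined by the dataset and the seed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import OmicsDataset
from .enrichment import build_network_table, hypergeom_enrich, regulator_targets
from .lasso import fit_all_tumors, model_matrix
from .selection import classify_shared, select_regulators, selected_sets
from .yinyang import select_yin_yang, test_differential, tumor_fold_changes


def run_pipeline(
    dataset: OmicsDataset,
    outdir: str | Path | None = None,
    n_permutations: int = 200,
    n_folds: int = 10,
    n_lambdas: int = 100,
    seed: int = 0,
    n_workers: int = 1,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
    pathway_sets: dict[str, list[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run differential expression, per-tumor lasso fits, regulator
    selection, and (optionally) the pathway-filtered network export.

    Returns the result tables; writes them as TSVs when ``outdir`` is given.
    """
    degs = test_differential(dataset.tumor_expression, dataset.normal_expression)
    yin, yang = select_yin_yang(degs, fdr_cut=fdr_cut, lfc_cut=lfc_cut)
    genes = sorted(yin | yang)
    if len(genes) < n_folds:
        # Too few differential genes to cross-validate on; fall back to the
        # full gene universe so the models remain fittable.
        genes = sorted(dataset.genes)
    responses = tumor_fold_changes(
        dataset.tumor_expression, dataset.normal_expression, genes
    )
    models, designs = fit_all_tumors(
        dataset, genes, responses, n_folds=n_folds, n_lambdas=n_lambdas, seed=seed
    )
    coef_matrix = model_matrix(models, dataset)
    metrics = pd.DataFrame(
        {
            "tumor": list(models),
            "lambda": [m.lam for m in models.values()],
            "cv_spearman": [m.cv_spearman for m in models.values()],
        }
    ).set_index("tumor")
    scores = select_regulators(
        dataset,
        genes,
        responses,
        models,
        designs,
        n_permutations=n_permutations,
        seed=seed,
        n_workers=n_workers,
        fdr_cut=fdr_cut,
    )
    shared = classify_shared(selected_sets(scores))
    results: dict[str, pd.DataFrame] = {
        "degs": degs,
        "model_matrix": coef_matrix,
        "tumor_metrics": metrics,
        "regulator_scores": scores,
        "shared_regulators": shared,
    }
    if pathway_sets:
        selected = sorted(set(scores.loc[scores["selected"], "regulator"]))
        yin_yang = yin | yang
        tf_sub = dataset.tf_binding.counts.loc[
            dataset.tf_binding.counts.index.isin(yin_yang)
        ]
        mir_sub = dataset.mirna_binding.counts.loc[
            dataset.mirna_binding.counts.index.isin(yin_yang)
        ]
        network = build_network_table(selected, tf_sub, mir_sub, pathway_sets)
        results["network"] = network
        enrich_rows = []
        for r in selected:
            binding = (
                dataset.tf_binding
                if r in dataset.tf_binding.counts.columns
                else dataset.mirna_binding
            )
            targets = regulator_targets(r, binding, yin_yang)
            if not targets:
                continue
            enr = hypergeom_enrich(targets, pathway_sets)
            enr.insert(0, "regulator", r)
            enrich_rows.append(enr)
        results["enrichment"] = (
            pd.concat(enrich_rows, ignore_index=True)
            if enrich_rows
            else pd.DataFrame(
                columns=["regulator", "set", "k", "n", "K", "N", "p", "fdr"]
            )
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t")
    return results
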
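"""Leave-regulator-out scoring and permutation-based key-regulator calls.

For a subtype S and regulator r (TF or miRNA), the score is the increase in
total squared loss over all genes and all tumors of S when r's fitted
coefficient is set to zero in every model, without refitting:

    score(r, S) = sum_g sum_{k in S} [ (y_gk - W_k^{r->0} . X_gk)^2
                                       - (y_gk - W_k . X_gk)^2 ]

Significance comes from a permutation null: each draw permutes every
binding-matrix column independently over genes, retrains every tumor's
lasso on the permuted design, and recomputes all scores. Empirical
p-values use the add-one correction and are Benjamini-Hochberg adjusted
within subtype across the combined TF+miRNA regulator list; regulators
with FDR < 0.05 are selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from .containers import SUBTYPES, BindingMatrix, OmicsDataset
from .lasso import TumorModel, _fit_at, _standardize, fit_tumor_lasso

FDR_CUT = 0.05


def _tumor_contributions(
    model: TumorModel, design: pd.DataFrame, y: pd.Series, regulators: list[str]
) -> np.ndarray:
    """Per-regulator loss increase for one tumor, vectorized.

    Zeroing coefficient w_r adds w_r * x_r back into the residual, so the
    loss change is 2 w_r (x_r . e) + w_r^2 ||x_r||^2 with e the residual of
    the full model.
    """
    X = design.to_numpy(dtype=float)
    w = model.coefficients.to_numpy()
    e = y.to_numpy(dtype=float) - (X @ w + model.intercept)
    delta = 2.0 * w * (X.T @ e) + w**2 * np.einsum("ij,ij->j", X, X)
    by_col = pd.Series(delta, index=design.columns)
    return by_col.reindex(regulators, fill_value=0.0).to_numpy()


def score_regulator(
    models: list[TumorModel],
    designs: list[pd.DataFrame],
    responses: list[pd.Series],
    regulator: str,
) -> float:
    """Total loss increase over the given tumors when zeroing one regulator."""
    known = set()
    for d in designs:
        known.update(d.columns)
    if regulator not in known:
        raise KeyError(f"unknown regulator {regulator!r}")
    total = 0.0
    for m, d, y in zip(models, designs, responses):
        total += float(_tumor_contributions(m, d, y, [regulator])[0])
    return total


def score_all_regulators(
    models: dict[str, TumorModel],
    designs: dict[str, pd.DataFrame],
    responses: pd.DataFrame,
    subtype: pd.Series,
    regulators: list[str],
) -> pd.DataFrame:
    """Regulators x subtypes matrix of leave-one-out loss increases."""
    subtypes = [s for s in SUBTYPES if (subtype == s).any()]
    out = pd.DataFrame(0.0, index=regulators, columns=subtypes)
    for t, model in models.items():
        s = subtype[t]
        y = responses.loc[designs[t].index, t]
        out[s] += _tumor_contributions(model, designs[t], y, regulators)
    return out


def permute_binding(
    binding: BindingMatrix | pd.DataFrame, seed: int | np.random.Generator = 0
) -> BindingMatrix | pd.DataFrame:
    """Permute each regulator column independently over genes.

    Column multisets are preserved; each column gets an independent draw.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    df = binding.counts if isinstance(binding, BindingMatrix) else binding
    arr = df.to_numpy().copy()
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        arr[:, j] = arr[rng.permutation(n), j]
    out = pd.DataFrame(arr, index=df.index, columns=df.columns)
    return BindingMatrix(out) if isinstance(binding, BindingMatrix) else out


@dataclass
class _TumorPlan:
    """Precomputed per-tumor arrays for fast permutation refits."""

    tumor: str
    X: np.ndarray
    y: np.ndarray
    lam: float
    tf_cols: np.ndarray  # design col idx of TF columns
    tf_src: np.ndarray  # matching column idx into the TF binding matrix
    mir_cols: np.ndarray
    mir_src: np.ndarray
    columns: pd.Index


def _make_plans(
    models: dict[str, TumorModel],
    designs: dict[str, pd.DataFrame],
    responses: pd.DataFrame,
    tf_names: list[str],
    mir_names: list[str],
) -> list[_TumorPlan]:
    tf_pos = {n: i for i, n in enumerate(tf_names)}
    mir_pos = {n: i for i, n in enumerate(mir_names)}
    plans = []
    for t, model in models.items():
        d = designs[t]
        cols = list(d.columns)
        tf_cols, tf_src, mir_cols, mir_src = [], [], [], []
        for j, c in enumerate(cols):
            if c in tf_pos:
                tf_cols.append(j)
                tf_src.append(tf_pos[c])
            elif c in mir_pos:
                mir_cols.append(j)
                mir_src.append(mir_pos[c])
        plans.append(
            _TumorPlan(
                tumor=t,
                X=d.to_numpy(dtype=float).copy(),
                y=responses.loc[d.index, t].to_numpy(dtype=float),
                lam=model.lam,
                tf_cols=np.array(tf_cols, dtype=int),
                tf_src=np.array(tf_src, dtype=int),
                mir_cols=np.array(mir_cols, dtype=int),
                mir_src=np.array(mir_src, dtype=int),
                columns=d.columns,
            )
        )
    return plans


def _one_permutation(
    plans: list[_TumorPlan],
    tf_arr: np.ndarray,
    mir_arr: np.ndarray,
    subtype_idx: np.ndarray,
    n_sub: int,
    reg_index: pd.Index,
    seed: np.random.SeedSequence,
    retune_lambda: bool = False,
    n_folds: int = 10,
) -> np.ndarray:
    """Permute both binding matrices, retrain every tumor, and return the
    regulators x subtypes score matrix for this draw."""
    rng = np.random.default_rng(seed)
    n_genes = tf_arr.shape[0]
    tf_perm = np.empty_like(tf_arr)
    for j in range(tf_arr.shape[1]):
        tf_perm[:, j] = tf_arr[rng.permutation(n_genes), j]
    mir_perm = np.empty_like(mir_arr)
    for j in range(mir_arr.shape[1]):
        mir_perm[:, j] = mir_arr[rng.permutation(n_genes), j]
    scores = np.zeros((len(reg_index), n_sub))
    pos = {c: i for i, c in enumerate(reg_index)}
    for plan, s_idx in zip(plans, subtype_idx):
        X = plan.X
        if plan.tf_cols.size:
            X[:, plan.tf_cols] = tf_perm[:, plan.tf_src]
        if plan.mir_cols.size:
            X[:, plan.mir_cols] = mir_perm[:, plan.mir_src]
        if retune_lambda:
            model = fit_tumor_lasso(
                pd.DataFrame(X, columns=plan.columns),
                pd.Series(plan.y),
                n_folds=n_folds,
                seed=0,
            )
            w = model.coefficients.to_numpy()
            e = plan.y - (X @ w + model.intercept)
        else:
            Xs, mu, sd = _standardize(X)
            ym = plan.y.mean()
            w_std = _fit_at(Xs, plan.y - ym, plan.lam)
            w = w_std / sd
            e = plan.y - (X @ w + (ym - mu @ w))
        delta = 2.0 * w * (X.T @ e) + w**2 * np.einsum("ij,ij->j", X, X)
        for j, c in enumerate(plan.columns):
            i = pos.get(c)
            if i is not None:
                scores[i, s_idx] += delta[j]
    return scores


def null_distribution(
    dataset: OmicsDataset,
    genes: list[str],
    responses: pd.DataFrame,
    models: dict[str, TumorModel],
    designs: dict[str, pd.DataFrame],
    n_permutations: int = 200,
    seed: int = 0,
    n_workers: int = 1,
    retune_lambda: bool = False,
    n_folds: int = 10,
) -> tuple[np.ndarray, pd.Index, list[str]]:
    """Null score samples from binding-permutation retraining.

    One draw permutes all TF and miRNA binding columns independently over
    the model genes, refits every tumor's lasso, and scores every regulator
    in every subtype. By default each tumor is refit at its already-chosen
    penalty; ``retune_lambda`` re-runs the full cross-validated penalty
    search per draw instead (far costlier). Returns ``(samples,
    regulators, subtypes)`` with ``samples`` of shape (n_permutations,
    n_regulators, n_subtypes). Per-permutation random substreams make the
    result identical for any worker count.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    tf_names = sorted(dataset.tfs)
    mir_names = sorted(dataset.mirnas)
    reg_index = pd.Index(tf_names + mir_names)
    subtypes = [s for s in SUBTYPES if (dataset.subtype == s).any()]
    sub_pos = {s: i for i, s in enumerate(subtypes)}
    plans = _make_plans(models, designs, responses, tf_names, mir_names)
    subtype_idx = np.array([sub_pos[dataset.subtype[p.tumor]] for p in plans])
    tf_arr = dataset.tf_binding.counts.loc[genes, tf_names].to_numpy(dtype=float)
    mir_arr = dataset.mirna_binding.counts.loc[genes, mir_names].to_numpy(dtype=float)
    seeds = np.random.SeedSequence(seed).spawn(n_permutations)
    if n_workers == 1:
        draws = [
            _one_permutation(
                plans, tf_arr, mir_arr, subtype_idx, len(subtypes), reg_index, s,
                retune_lambda=retune_lambda, n_folds=n_folds,
            )
            for s in seeds
        ]
    else:
        draws = Parallel(n_jobs=n_workers)(
            delayed(_one_permutation)(
                plans, tf_arr, mir_arr, subtype_idx, len(subtypes), reg_index, s,
                retune_lambda=retune_lambda, n_folds=n_folds,
            )
            for s in seeds
        )
    return np.stack(draws), reg_index, subtypes


def empirical_fdr(
    observed: pd.DataFrame,
    nulls: np.ndarray,
    fdr_cut: float = FDR_CUT,
) -> pd.DataFrame:
    """Empirical p-values and BH FDR per (regulator, subtype).

    ``observed`` is regulators x subtypes; ``nulls`` has shape
    (n_perm, n_regulators, n_subtypes) aligned to it. The p-value uses the
    add-one correction p = (1 + #{null >= obs}) / (1 + n_perm); BH runs
    within each subtype over all regulators.
    """
    n_perm = nulls.shape[0]
    rows = []
    for j, s in enumerate(observed.columns):
        obs = observed[s].to_numpy()
        exceed = (nulls[:, :, j] >= obs[None, :]).sum(axis=0)
        p = (1.0 + exceed) / (1.0 + n_perm)
        _, fdr, _, _ = multipletests(p, method="fdr_bh")
        for i, r in enumerate(observed.index):
            rows.append(
                {
                    "regulator": r,
                    "subtype": s,
                    "score": obs[i],
                    "p": p[i],
                    "fdr": fdr[i],
                    "selected": fdr[i] < fdr_cut,
                }
            )
    return pd.DataFrame(rows)


def selected_sets(scores: pd.DataFrame) -> dict[str, set[str]]:
    """Selected regulator set per subtype from an :func:`empirical_fdr` table."""
    return {
        s: set(scores.loc[(scores["subtype"] == s) & scores["selected"], "regulator"])
        for s in scores["subtype"].unique()
    }


def classify_shared(sets_by_subtype: dict[str, set[str]]) -> pd.DataFrame:
    """Cross-classify selected regulators by the exact subtype combination
    selecting them (common / shared / subtype-specific groups)."""
    membership: dict[str, tuple[str, ...]] = {}
    order = [s for s in SUBTYPES if s in sets_by_subtype] + [
        s for s in sets_by_subtype if s not in SUBTYPES
    ]
    for s in order:
        for r in sets_by_subtype[s]:
            membership.setdefault(r, ())
    for r in membership:
        membership[r] = tuple(s for s in order if r in sets_by_subtype[s])
    groups: dict[tuple[str, ...], list[str]] = {}
    for r, combo in membership.items():
        groups.setdefault(combo, []).append(r)
    rows = [
        {
            "subtypes": ",".join(combo),
            "n_regulators": len(regs),
            "regulators": ",".join(sorted(regs)),
        }
        for combo, regs in sorted(
            groups.items(), key=lambda kv: (-len(kv[0]), kv[0])
        )
    ]
    return pd.DataFrame(rows, columns=["subtypes", "n_regulators", "regulators"])


def select_regulators(
    dataset: OmicsDataset,
    genes: list[str],
    responses: pd.DataFrame,
    models: dict[str, TumorModel],
    designs: dict[str, pd.DataFrame],
    n_permutations: int = 200,
    seed: int = 0,
    n_workers: int = 1,
    fdr_cut: float = FDR_CUT,
) -> pd.DataFrame:
    """Observed scores + permutation null + BH selection in one call."""
    tf_names = sorted(dataset.tfs)
    mir_names = sorted(dataset.mirnas)
    observed = score_all_regulators(
        models, designs, responses, dataset.subtype, tf_names + mir_names
    )
    nulls, reg_index, subtypes = null_distribution(
        dataset,
        genes,
        responses,
        models,
        designs,
        n_permutations=n_permutations,
        seed=seed,
        n_workers=n_workers,
    )
    observed = observed.loc[reg_index, subtypes]
    return empirical_fdr(observed, nulls, fdr_cut=fdr_cut)
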
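"""Per-tumor lasso models of gene expression fold changes.

For each tumor k the model explains the response y_{g,k} (log2 fold change
of gene g versus the normal mean) from the gene's copy-number score C_g,
methylation D_g, TF promoter binding counts N_{g,TF} and miRNA 3'UTR
binding counts N_{g,miR}:

    y_g = W_CN C_g + W_DM D_g + sum_TF W_TF N_{g,TF} + sum_miR W_miR N_{g,miR}

fitted with an L1 penalty. The penalty lambda is chosen per tumor by K-fold
cross-validation over genes (CV-minimum rule on squared error) on a
glmnet-style log-spaced grid from lambda_max down four decades. Features
are standardized internally for fitting; reported coefficients are on the
original scale. An intercept is included by default because the response is
a fold change with a nonzero mean.

Only miRNAs whose own expression changes in the tumor (absolute log2 fold
change above a threshold, default 0) are admitted as explanatory variables
for that tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path

from .containers import OmicsDataset
from .yinyang import tumor_fold_changes

N_LAMBDAS = 100
LAMBDA_DECADES = 4.0
MIRNA_THRESHOLD = 0.0

FEATURE_SUBSETS = {
    "miRNA": ("mirna",),
    "miRNA+TF": ("mirna", "tf"),
    "miRNA+TF+CNV": ("mirna", "tf", "cnv"),
    "miRNA+TF+CNV+DM": ("mirna", "tf", "cnv", "dm"),
}


@dataclass
class TumorModel:
    """One tumor's fitted model: original-scale coefficients, chosen lambda
    and mean held-out Spearman correlation."""

    tumor: str
    coefficients: pd.Series
    intercept: float
    lam: float
    cv_spearman: float


def build_design(
    dataset: OmicsDataset,
    tumor: str,
    genes: list[str],
    mirna_restriction_threshold: float = MIRNA_THRESHOLD,
    mirna_fold_changes: pd.DataFrame | None = None,
    blocks: tuple[str, ...] = ("cnv", "dm", "tf", "mirna"),
) -> pd.DataFrame:
    """Assemble the genes x features design matrix for one tumor.

    Columns are ordered [CNV, DM, TFs sorted, admitted miRNAs sorted]; a
    miRNA is admitted iff the absolute value of its expression fold change
    in this tumor strictly exceeds the threshold. ``blocks`` restricts the
    feature families included (used for model comparison).
    """
    if tumor not in dataset.subtype.index:
        raise KeyError(f"unknown tumor {tumor!r}")
    cols: list[pd.Series] = []
    if "cnv" in blocks:
        cols.append(dataset.cnv.loc[genes, tumor].rename("CNV"))
    if "dm" in blocks:
        cols.append(dataset.methylation.loc[genes, tumor].rename("DM"))
    if "tf" in blocks:
        tfb = dataset.tf_binding.counts.loc[genes]
        for tf in sorted(tfb.columns):
            cols.append(tfb[tf])
    if "mirna" in blocks:
        if mirna_fold_changes is None:
            mirna_fold_changes = tumor_fold_changes(
                dataset.mirna_expression, dataset.mirna_normal_expression
            )
        fc = mirna_fold_changes[tumor]
        admitted = sorted(
            m
            for m in dataset.mirnas
            if np.isfinite(fc[m]) and abs(fc[m]) > mirna_restriction_threshold
        )
        mib = dataset.mirna_binding.counts.loc[genes]
        for m in admitted:
            cols.append(mib[m])
    if not cols:
        raise ValueError(f"no admitted features for tumor {tumor!r}")
    design = pd.concat(cols, axis=1)
    if design.shape[1] == 0:
        raise ValueError(f"no admitted features for tumor {tumor!r}")
    return design


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = N_LAMBDAS) -> np.ndarray:
    """Log-spaced grid from lambda_max (empty model) down four decades."""
    Xs, _, _ = _standardize(X)
    yc = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ yc)) / len(y)
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * 10 ** (-LAMBDA_DECADES), n_lambdas)


def _fit_at(Xs: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    """Single lasso fit on standardized/centered data at one penalty."""
    gram = Xs.T @ Xs
    _, coefs, _ = lasso_path(
        Xs,
        yc,
        alphas=[lam],
        precompute=gram,
        Xy=Xs.T @ yc,
        check_input=False,
        tol=1e-10,
        max_iter=10000,
    )
    return coefs[:, 0]


def fit_lasso_fixed(design: pd.DataFrame, y: pd.Series, lam: float, tumor: str = "") -> TumorModel:
    """Refit at a fixed penalty (no CV); used for permutation nulls."""
    X = design.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    Xs, mu, sd = _standardize(X)
    ym = yv.mean()
    w_std = _fit_at(Xs, yv - ym, lam)
    w = w_std / sd
    intercept = ym - float(mu @ w)
    return TumorModel(
        tumor=tumor,
        coefficients=pd.Series(w, index=design.columns),
        intercept=intercept,
        lam=lam,
        cv_spearman=np.nan,
    )


def _fold_indices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[i::n_folds] for i in range(n_folds)]


def fit_tumor_lasso(
    design: pd.DataFrame,
    y: pd.Series,
    n_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    tumor: str = "",
    fit_intercept: bool = True,
) -> TumorModel:
    """Fit one tumor's lasso with the penalty chosen by K-fold CV over genes.

    Returns original-scale coefficients (zeros for shrunk-out features), the
    chosen lambda (CV-minimum of mean squared error) and the mean held-out
    Spearman correlation at that lambda.
    """
    X = design.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if n < n_folds:
        raise ValueError(f"{n} genes is fewer than {n_folds} folds")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, yv)
    folds = _fold_indices(n, n_folds, seed)
    mask = np.ones(n, dtype=bool)
    sq_err = np.zeros((n_folds, len(lambda_grid)))
    fold_preds: list[np.ndarray] = []
    fold_obs: list[np.ndarray] = []
    for i, val_idx in enumerate(folds):
        mask[:] = True
        mask[val_idx] = False
        Xtr, ytr = X[mask], yv[mask]
        Xval, yval = X[val_idx], yv[val_idx]
        Xs, mu, sd = _standardize(Xtr)
        ym = ytr.mean() if fit_intercept else 0.0
        gram = Xs.T @ Xs
        _, coefs, _ = lasso_path(
            Xs,
            ytr - ym,
            alphas=lambda_grid,
            precompute=gram,
            Xy=Xs.T @ (ytr - ym),
            check_input=False,
            tol=1e-10,
            max_iter=10000,
        )
        preds = ((Xval - mu) / sd) @ coefs + ym  # n_val x n_lambdas
        sq_err[i] = np.mean((preds - yval[:, None]) ** 2, axis=0)
        fold_preds.append(preds)
        fold_obs.append(yval)
    best = int(np.argmin(sq_err.mean(axis=0)))
    lam = float(lambda_grid[best])
    rho_best = np.zeros(n_folds)
    for i in range(n_folds):
        p, yval = fold_preds[i][:, best], fold_obs[i]
        if np.ptp(p) == 0 or np.ptp(yval) == 0:
            rho_best[i] = 0.0
        else:
            rho_best[i] = stats.spearmanr(p, yval).statistic
    Xs, mu, sd = _standardize(X)
    ym = yv.mean() if fit_intercept else 0.0
    w_std = _fit_at(Xs, yv - ym, lam)
    w = w_std / sd
    intercept = ym - float(mu @ w) if fit_intercept else 0.0
    return TumorModel(
        tumor=tumor,
        coefficients=pd.Series(w, index=design.columns),
        intercept=intercept,
        lam=lam,
        cv_spearman=float(rho_best.mean()),
    )


def fit_all_tumors(
    dataset: OmicsDataset,
    genes: list[str],
    responses: pd.DataFrame,
    n_folds: int = 10,
    n_lambdas: int = N_LAMBDAS,
    mirna_restriction_threshold: float = MIRNA_THRESHOLD,
    seed: int = 0,
) -> tuple[dict[str, TumorModel], dict[str, pd.DataFrame]]:
    """Fit every tumor's model; returns (models, designs) keyed by tumor id.

    ``responses`` is the genes x tumors fold-change matrix (y_{g,k}).
    """
    mir_fc = tumor_fold_changes(
        dataset.mirna_expression, dataset.mirna_normal_expression
    )
    models: dict[str, TumorModel] = {}
    designs: dict[str, pd.DataFrame] = {}
    for t in dataset.tumors:
        design = build_design(
            dataset,
            t,
            genes,
            mirna_restriction_threshold=mirna_restriction_threshold,
            mirna_fold_changes=mir_fc,
        )
        X = design.to_numpy(dtype=float)
        yv = responses.loc[genes, t]
        grid = default_lambda_grid(X, yv.to_numpy(dtype=float), n_lambdas)
        models[t] = fit_tumor_lasso(
            design, yv, n_folds=n_folds, lambda_grid=grid, seed=seed, tumor=t
        )
        designs[t] = design
    return models, designs


def model_matrix(models: dict[str, TumorModel], dataset: OmicsDataset) -> pd.DataFrame:
    """Tumors x features coefficient matrix with structural zeros for the
    miRNA columns a tumor's restriction rule excluded."""
    features = ["CNV", "DM"] + sorted(dataset.tfs) + sorted(dataset.mirnas)
    out = pd.DataFrame(0.0, index=list(models), columns=features)
    for t, m in models.items():
        out.loc[t, m.coefficients.index] = m.coefficients.to_numpy()
    return out


def predictions(model: TumorModel, design: pd.DataFrame) -> np.ndarray:
    return design.to_numpy(dtype=float) @ model.coefficients.to_numpy() + model.intercept


def cross_validate_features(
    dataset: OmicsDataset,
    genes: list[str],
    responses: pd.DataFrame,
    feature_subsets: dict[str, tuple[str, ...]] | None = None,
    n_folds: int = 10,
    n_lambdas: int = N_LAMBDAS,
    mirna_restriction_threshold: float = MIRNA_THRESHOLD,
    seed: int = 0,
    permute_responses: bool = False,
) -> pd.DataFrame:
    """Held-out Spearman correlation per (tumor, feature subset).

    For each tumor and subset, genes are split into seeded folds (identical
    across subsets so comparisons are paired); the model is trained on 90%
    of genes and evaluated by Spearman correlation between predicted and
    observed fold changes on the held-out 10%, averaged over folds. With
    ``permute_responses`` the gene labels of y are shuffled per tumor first
    (the randomized baseline).
    """
    if feature_subsets is None:
        feature_subsets = FEATURE_SUBSETS
    mir_fc = tumor_fold_changes(
        dataset.mirna_expression, dataset.mirna_normal_expression
    )
    rng = np.random.default_rng(seed)
    rows = {}
    for t in dataset.tumors:
        yv = responses.loc[genes, t].to_numpy(dtype=float)
        if permute_responses:
            yv = yv[rng.permutation(len(yv))]
        y_series = pd.Series(yv, index=genes)
        rows[t] = {}
        for name, blocks in feature_subsets.items():
            design = build_design(
                dataset,
                t,
                genes,
                mirna_restriction_threshold=mirna_restriction_threshold,
                mirna_fold_changes=mir_fc,
                blocks=blocks,
            )
            grid = default_lambda_grid(
                design.to_numpy(dtype=float), yv, n_lambdas
            )
            model = fit_tumor_lasso(
                design, y_series, n_folds=n_folds, lambda_grid=grid, seed=seed, tumor=t
            )
            rows[t][name] = model.cv_spearman
    return pd.DataFrame.from_dict(rows, orient="index").loc[dataset.tumors]


def randomized_baseline(
    dataset: OmicsDataset,
    genes: list[str],
    responses: pd.DataFrame,
    n_folds: int = 10,
    n_lambdas: int = N_LAMBDAS,
    seed: int = 0,
) -> pd.Series:
    """Per-tumor CV correlation after permuting the response gene labels."""
    out = cross_validate_features(
        dataset,
        genes,
        responses,
        feature_subsets={"full": ("cnv", "dm", "tf", "mirna")},
        n_folds=n_folds,
        n_lambdas=n_lambdas,
        seed=seed,
        permute_responses=True,
    )
    return out["full"]


def compare_models(corrs_a: pd.Series, corrs_b: pd.Series) -> float:
    """Two-sided Wilcoxon signed-rank p for paired per-tumor correlations."""
    a = np.asarray(corrs_a, dtype=float)
    b = np.asarray(corrs_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired comparison requires equal-length vectors")
    if np.allclose(a, b):
        return 1.0
    return float(stats.wilcoxon(a, b).pvalue)
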
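"""Synthetic multi-omics datasets with planted regulatory ground truth.

The generator emulates the statistical shape of a TCGA-style breast-cancer
cohort: log2-scale tumor and normal expression, discrete gene-level
copy-number scores, beta-distributed promoter methylation, sparse
non-negative binding-site count matrices, IHC subtype labels, and censored
survival times tied to an arbitrary risk score.

Per-tumor gene expression fold changes follow the same linear generative
model the pipeline fits:

    y_g = W_CN * C_g + W_DM * D_g + sum_TF W_TF * N_{g,TF}
          + sum_miR W_miR * N_{g,miR} + eps,   eps ~ N(0, noise_sd^2)

where regulator coefficients W_TF / W_miR are constant within a subtype
(the planted "key regulators") and the copy-number / methylation weights
are per-tumor scalars. Differentially expressed ("yin"/"yang") genes are
planted through the copy-number and methylation channels themselves so the
identity above holds exactly when ``noise_sd`` is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import SUBTYPES, BindingMatrix, ExpressionMatrix, OmicsDataset


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for :func:`generate_dataset`.

    Defaults produce 4 subtypes x 25 tumors with 300 genes, 20 TFs and
    30 miRNAs, 5 planted regulators per subtype at coefficient magnitude 1,
    response noise 0.5 and binding density 0.1.
    """

    n_tumors_per_subtype: int = 25
    n_normals: int = 20
    n_genes: int = 300
    n_tfs: int = 20
    n_mirnas: int = 30
    n_active_per_subtype: int = 5
    effect_size: float = 1.0
    noise_sd: float = 0.5
    binding_density: float = 0.1
    max_binding_count: int = 5
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_tumors_per_subtype",
            "n_normals",
            "n_genes",
            "n_tfs",
            "n_mirnas",
            "n_active_per_subtype",
            "max_binding_count",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if not 0 < self.binding_density <= 1:
            raise ValueError(
                f"binding_density must be in (0, 1], got {self.binding_density!r}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if not 0 <= self.censor_rate < 1:
            raise ValueError(
                f"censor_rate must be in [0, 1), got {self.censor_rate!r}"
            )
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size!r}")
        if self.n_active_per_subtype > self.n_tfs + self.n_mirnas:
            raise ValueError(
                "n_active_per_subtype exceeds the number of regulators"
            )


@dataclass
class GroundTruth:
    """What was planted: regulator coefficients, per-tumor CN/DM weights,
    up/down gene sets, and pathway gene sets for enrichment fixtures."""

    planted_coefficients: dict[tuple[str, str], float]
    true_cnv_weight: pd.Series
    true_dm_weight: pd.Series
    yin_genes: set[str]
    yang_genes: set[str]
    pathways: dict[str, list[str]] = field(default_factory=dict)

    def regulators_of(self, subtype: str) -> set[str]:
        return {r for (s, r) in self.planted_coefficients if s == subtype}


def _ids(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _binding_counts(
    rng: np.random.Generator, n_genes: int, n_cols: int, density: float, max_count: int
) -> np.ndarray:
    mask = rng.random((n_genes, n_cols)) < density
    counts = 1 + rng.poisson(1.0, size=(n_genes, n_cols))
    return np.minimum(counts, max_count) * mask


def generate_dataset(config: SimConfig) -> tuple[OmicsDataset, GroundTruth]:
    """Generate a complete aligned dataset plus its ground truth.

    The same seed yields a bit-identical dataset. One global seed fans out
    into independent substreams per component so that, e.g., the binding
    matrices do not change when ``n_normals`` does.
    """
    ss = np.random.SeedSequence(config.seed)
    (
        ss_bind,
        ss_plant,
        ss_cnv,
        ss_meth,
        ss_weights,
        ss_mirna,
        ss_noise,
        ss_baseline,
        ss_pathway,
    ) = ss.spawn(9)

    G, T, M = config.n_genes, config.n_tfs, config.n_mirnas
    genes = _ids("g", G)
    tfs = _ids("TF", T)
    mirnas = [f"miR-{i:03d}" for i in range(1, M + 1)]
    # Sorted sample order so that re-aligning the written files is a no-op.
    tumors = sorted(
        f"{s}-{i:03d}"
        for s in SUBTYPES
        for i in range(1, config.n_tumors_per_subtype + 1)
    )
    normals = _ids("N", config.n_normals)
    subtype = pd.Series(
        [t.rsplit("-", 1)[0] for t in tumors], index=tumors, name="subtype"
    )

    rng = np.random.default_rng(ss_bind)
    tf_bind = pd.DataFrame(
        _binding_counts(rng, G, T, config.binding_density, config.max_binding_count),
        index=genes,
        columns=tfs,
        dtype=float,
    )
    mir_bind = pd.DataFrame(
        _binding_counts(rng, G, M, config.binding_density, config.max_binding_count),
        index=genes,
        columns=mirnas,
        dtype=float,
    )

    # Planted regulator coefficients: per subtype a draw of TFs/miRNAs with
    # coefficient +/- effect_size.
    rng = np.random.default_rng(ss_plant)
    regulators = tfs + mirnas
    planted: dict[tuple[str, str], float] = {}
    for s in SUBTYPES:
        chosen = rng.choice(regulators, size=config.n_active_per_subtype, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_active_per_subtype)
        for r, sgn in zip(chosen, signs):
            planted[(s, str(r))] = sgn * config.effect_size

    # Yin / yang genes are planted through copy number and methylation:
    # yin genes are amplified and hypomethylated, yang genes deleted and
    # hypermethylated, so the linear model itself produces the up/down shift.
    n_de = max(1, G // 10)
    rng_c = np.random.default_rng(ss_cnv)
    de_genes = rng_c.choice(G, size=min(2 * n_de, G), replace=False)
    yin_idx, yang_idx = de_genes[:n_de], de_genes[n_de : 2 * n_de]
    yin_genes = {genes[i] for i in yin_idx}
    yang_genes = {genes[i] for i in yang_idx}

    n_tum = len(tumors)
    cnv = rng_c.choice(
        [-2, -1, 0, 1, 2], size=(G, n_tum), p=[0.05, 0.2, 0.5, 0.2, 0.05]
    ).astype(float)
    cnv[yin_idx] = rng_c.choice([1, 2], size=(n_de, n_tum), p=[0.2, 0.8])
    cnv[yang_idx] = rng_c.choice([-2, -1], size=(n_de, n_tum), p=[0.8, 0.2])
    cnv_df = pd.DataFrame(cnv, index=genes, columns=tumors)

    rng_m = np.random.default_rng(ss_meth)
    meth = rng_m.beta(2.0, 2.0, size=(G, n_tum))
    meth[yin_idx] = rng_m.beta(2.0, 12.0, size=(n_de, n_tum))
    meth[yang_idx] = rng_m.beta(12.0, 2.0, size=(n_de, n_tum))
    meth_df = pd.DataFrame(meth, index=genes, columns=tumors)

    rng_w = np.random.default_rng(ss_weights)
    wcn = pd.Series(rng_w.normal(1.0, 0.1, size=n_tum), index=tumors)
    wdm = pd.Series(rng_w.normal(-1.0, 0.1, size=n_tum), index=tumors)

    # miRNA expression fold changes; planted miRNAs kept at |fc| >= 0.5 in
    # their subtype so a fold-change admission rule cannot drop them.
    rng_fc = np.random.default_rng(ss_mirna)
    mir_fc = pd.DataFrame(
        rng_fc.normal(0.0, 1.0, size=(M, n_tum)), index=mirnas, columns=tumors
    )
    for (s, r), _ in planted.items():
        if r in mir_fc.index:
            cols = subtype.index[subtype == s]
            v = mir_fc.loc[r, cols].to_numpy()
            v = np.sign(np.where(v == 0, 1.0, v)) * np.maximum(np.abs(v), 0.5)
            mir_fc.loc[r, cols] = v

    # Response: Eq.-style linear predictor plus Gaussian noise.
    w_tf = pd.DataFrame(0.0, index=tfs, columns=list(SUBTYPES))
    w_mir = pd.DataFrame(0.0, index=mirnas, columns=list(SUBTYPES))
    for (s, r), coef in planted.items():
        if r in w_tf.index:
            w_tf.loc[r, s] = coef
        else:
            w_mir.loc[r, s] = coef
    rng_n = np.random.default_rng(ss_noise)
    y = np.empty((G, n_tum))
    for j, t in enumerate(tumors):
        s = subtype[t]
        y[:, j] = (
            wcn[t] * cnv[:, j]
            + wdm[t] * meth[:, j]
            + tf_bind.to_numpy() @ w_tf[s].to_numpy()
            + mir_bind.to_numpy() @ w_mir[s].to_numpy()
        )
    if config.noise_sd > 0:
        y += rng_n.normal(0.0, config.noise_sd, size=y.shape)

    # Expression matrices: normals around a per-gene baseline; tumors are the
    # realized normal mean plus the generated fold change, so recomputing
    # tumor-vs-normal fold changes recovers y.
    rng_b = np.random.default_rng(ss_baseline)
    base_g = rng_b.uniform(9.0, 14.0, size=G)
    # Log2 expression cannot be negative: raise the baseline of any gene
    # whose planted downshift would otherwise push a tumor below zero.
    base_g = np.maximum(base_g, 1.5 - y.min(axis=1))
    normal_expr = pd.DataFrame(
        base_g[:, None] + rng_b.normal(0.0, 0.3, size=(G, config.n_normals)),
        index=genes,
        columns=normals,
    )
    tumor_expr = pd.DataFrame(
        normal_expr.mean(axis=1).to_numpy()[:, None] + y, index=genes, columns=tumors
    )

    base_m = rng_b.uniform(5.0, 10.0, size=M)
    mir_normal = pd.DataFrame(
        base_m[:, None] + rng_b.normal(0.0, 0.3, size=(M, config.n_normals)),
        index=mirnas,
        columns=normals,
    )
    mir_tumor = pd.DataFrame(
        mir_normal.mean(axis=1).to_numpy()[:, None] + mir_fc.to_numpy(),
        index=mirnas,
        columns=tumors,
    )

    # Pathway gene sets for enrichment fixtures: one set per planted DE class
    # plus background sets drawn from the full gene universe.
    rng_p = np.random.default_rng(ss_pathway)
    pathways: dict[str, list[str]] = {
        "PLANTED_YIN_PATHWAY": sorted(yin_genes),
        "PLANTED_YANG_PATHWAY": sorted(yang_genes),
    }
    for i in range(1, 5):
        size = int(rng_p.integers(15, 40))
        members = rng_p.choice(genes, size=size, replace=False)
        pathways[f"RANDOM_PATHWAY_{i}"] = sorted(str(g) for g in members)

    dataset = OmicsDataset(
        tumor_expression=ExpressionMatrix(tumor_expr, "gene-RSEM-log2"),
        normal_expression=ExpressionMatrix(normal_expr, "gene-RSEM-log2"),
        mirna_expression=ExpressionMatrix(mir_tumor, "miRNA-RPM-log2"),
        mirna_normal_expression=ExpressionMatrix(mir_normal, "miRNA-RPM-log2"),
        cnv=cnv_df,
        methylation=meth_df,
        tf_binding=BindingMatrix(tf_bind),
        mirna_binding=BindingMatrix(mir_bind),
        subtype=subtype,
    )
    truth = GroundTruth(
        planted_coefficients=planted,
        true_cnv_weight=wcn,
        true_dm_weight=wdm,
        yin_genes=yin_genes,
        yang_genes=yang_genes,
        pathways=pathways,
    )
    return dataset, truth


def linear_predictor(dataset: OmicsDataset, truth: GroundTruth) -> pd.DataFrame:
    """Recompute the noiseless linear predictor from the ground truth."""
    genes, tumors = dataset.genes, dataset.tumors
    tfb = dataset.tf_binding.counts.to_numpy()
    mib = dataset.mirna_binding.counts.to_numpy()
    w_tf = pd.DataFrame(0.0, index=dataset.tfs, columns=list(SUBTYPES))
    w_mir = pd.DataFrame(0.0, index=dataset.mirnas, columns=list(SUBTYPES))
    for (s, r), coef in truth.planted_coefficients.items():
        (w_tf if r in w_tf.index else w_mir).loc[r, s] = coef
    out = np.empty((len(genes), len(tumors)))
    for j, t in enumerate(tumors):
        s = dataset.subtype[t]
        out[:, j] = (
            truth.true_cnv_weight[t] * dataset.cnv[t].to_numpy()
            + truth.true_dm_weight[t] * dataset.methylation[t].to_numpy()
            + tfb @ w_tf[s].to_numpy()
            + mib @ w_mir[s].to_numpy()
        )
    return pd.DataFrame(out, index=genes, columns=tumors)


def generate_survival(
    scores: pd.Series,
    hazard_scale: float = 0.1,
    censor_rate: float = 0.3,
    seed: int = 0,
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Exponential survival times with per-patient rate ``hazard_scale * exp(score)``.

    Censoring is independent exponential with its rate chosen so the expected
    censored fraction matches ``censor_rate``. Returns a table with columns
    ``patient``, ``time``, ``event``, ``endpoint``.
    """
    scores = pd.Series(scores)
    vals = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("risk scores must be finite")
    if hazard_scale <= 0:
        raise ValueError("hazard_scale must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rates = hazard_scale * np.exp(vals)
    event_times = rng.exponential(1.0 / rates)
    if censor_rate == 0:
        times, events = event_times, np.ones(len(vals), dtype=int)
    else:
        # P(censored | rate lam, censor rate mu) = mu / (mu + lam)
        def expected_censored(mu: float) -> float:
            return float(np.mean(mu / (mu + rates))) - censor_rate

        lo, hi = rates.min() * 1e-9, rates.max() * 1e9
        mu = brentq(expected_censored, lo, hi)
        censor_times = rng.exponential(1.0 / mu, size=len(vals))
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    return pd.DataFrame(
        {
            "patient": scores.index.astype(str),
            "time": times,
            "event": events,
            "endpoint": endpoint,
        }
    )


# ---------------------------------------------------------------------------
# Writers: same TSV/GMT layouts the preprocessing readers consume.

def write_dataset(dataset: OmicsDataset, truth: GroundTruth, outdir: str | Path) -> None:
    """Write every component as the TSV matrix layout the readers consume."""
    from .preprocess import write_matrix_tsv
    from .enrichment import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(dataset.tumor_expression.values, outdir / "expression_tumor.tsv")
    write_matrix_tsv(dataset.normal_expression.values, outdir / "expression_normal.tsv")
    write_matrix_tsv(dataset.mirna_expression.values, outdir / "mirna_tumor.tsv")
    write_matrix_tsv(
        dataset.mirna_normal_expression.values, outdir / "mirna_normal.tsv"
    )
    write_matrix_tsv(dataset.cnv, outdir / "cnv.tsv")
    write_matrix_tsv(dataset.methylation, outdir / "methylation.tsv")
    write_matrix_tsv(dataset.tf_binding.counts, outdir / "tf_binding.tsv")
    write_matrix_tsv(dataset.mirna_binding.counts, outdir / "mirna_binding.tsv")
    dataset.subtype.rename_axis("sample").to_frame().to_csv(
        outdir / "subtypes.tsv", sep="\t"
    )
    if truth.pathways:
        write_gmt(truth.pathways, outdir / "pathways.gmt")
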
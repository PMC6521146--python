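"""Prognostic signatures (YMR, CRS) and survival evaluation.

YMR is the per-patient ratio of the mean log2 expression of the yin
(up) gene set to the mean of the yang (down) gene set; patients are
stratified at the cohort mean (strictly above -> high risk). CRS is the
per-patient sum of regulator expression times its univariate Cox
log-hazard coefficient, binarized at an empirical quantile cutoff
(xtile-style, default probability 0.65). Group separation is evaluated
with Kaplan-Meier curves and the two-group log-rank test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sksurv.linear_model import CoxPHSurvivalAnalysis

from .containers import ExpressionMatrix

XTILE_PROBABILITY = 0.65


def _expr_values(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def ymr_score(
    expr: ExpressionMatrix | pd.DataFrame, yin: set[str], yang: set[str]
) -> pd.Series:
    """Per-patient yin-mean / yang-mean expression ratio."""
    values = _expr_values(expr)
    yin_l, yang_l = sorted(yin), sorted(yang)
    if not yin_l or not yang_l:
        raise ValueError("yin and yang gene sets must be non-empty")
    missing = (set(yin_l) | set(yang_l)) - set(values.index)
    if missing:
        raise KeyError(f"genes absent from expression matrix: {sorted(missing)[:5]}")
    yin_mean = values.loc[yin_l].mean(axis=0)
    yang_mean = values.loc[yang_l].mean(axis=0)
    bad = yang_mean <= 0
    if bad.any():
        raise ValueError(
            f"non-positive yang mean for patient(s) {list(yang_mean.index[bad])[:5]}"
        )
    return (yin_mean / yang_mean).rename("ymr")


def stratify_by_mean(scores: pd.Series) -> pd.Series:
    """High-risk iff score strictly above the cohort mean; ties go low."""
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least two patients to stratify")
    cutoff = scores.mean()
    groups = pd.Series(
        np.where(scores > cutoff, "High", "Low"), index=scores.index, name="group"
    )
    if (groups == "Low").all() or (groups == "High").all():
        warnings.warn("degenerate stratification: all patients in one group", stacklevel=2)
    return groups


def xtile_binarize(scores: pd.Series, probability: float = XTILE_PROBABILITY) -> pd.Series:
    """High-risk iff score strictly above the empirical quantile cutoff.

    The cutoff is the linear-interpolation (type-7) quantile at
    ``probability``; tied values at the cutoff go to the low-risk side.
    """
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least two patients to stratify")
    cutoff = float(np.quantile(scores.to_numpy(dtype=float), probability))
    return pd.Series(
        np.where(scores > cutoff, "High", "Low"), index=scores.index, name="group"
    )


def univariate_cox(x: pd.Series, survival: pd.DataFrame) -> float:
    """Univariate Cox proportional-hazards log-hazard-ratio (Breslow ties).

    ``survival`` must carry columns ``patient``, ``time``, ``event`` and
    cover every patient in ``x``.
    """
    surv = survival.set_index("patient").loc[x.index.astype(str)]
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least two events for a Cox fit")
    xv = x.to_numpy(dtype=float)
    if np.isnan(xv).any():
        raise ValueError("missing covariate values")
    y = np.array(
        list(zip(surv["event"].astype(bool), surv["time"].astype(float))),
        dtype=[("event", bool), ("time", float)],
    )
    model = CoxPHSurvivalAnalysis(ties="breslow")
    try:
        model.fit(xv[:, None], y)
    except Exception as exc:  # pragma: no cover - sksurv raises on divergence
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    return float(model.coef_[0])


def crs_score(
    expr: ExpressionMatrix | pd.DataFrame, coefs: pd.Series
) -> pd.Series:
    """Combined risk score: sum_i x_i * coef_i per patient."""
    values = _expr_values(expr)
    missing = set(coefs.index) - set(values.index)
    if missing:
        raise KeyError(f"regulators absent from expression: {sorted(missing)[:5]}")
    sub = values.loc[coefs.index]
    return sub.mul(coefs, axis=0).sum(axis=0).rename("crs")


def fit_crs(
    expr: ExpressionMatrix | pd.DataFrame,
    regulators: list[str],
    survival: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Fit per-regulator univariate Cox coefficients, then the CRS.

    Returns (coefs, scores)."""
    values = _expr_values(expr)
    coefs = pd.Series(
        {r: univariate_cox(values.loc[r], survival) for r in regulators},
        name="coef",
    )
    return coefs, crs_score(values, coefs)


def administrative_censor(survival: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Censor all follow-up at a fixed horizon (e.g. five-year analyses)."""
    out = survival.copy()
    over = out["time"] > horizon
    out.loc[over, "time"] = horizon
    out.loc[over, "event"] = 0
    return out


def km_estimate(survival: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curve per group.

    Returns per group a DataFrame with columns ``time`` and ``survival``
    (the step function evaluated at the observed event times; S(0) = 1).
    """
    surv = survival.set_index("patient")
    out: dict[str, pd.DataFrame] = {}
    for g in sorted(groups.unique()):
        ids = groups.index[groups == g].astype(str)
        if len(ids) == 0:
            continue
        sub = surv.loc[ids]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        out[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank_test(survival: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic and p-value."""
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {labels}")
    surv = survival.set_index("patient")
    parts = []
    for g in labels:
        ids = groups.index[groups == g].astype(str)
        if len(ids) == 0:
            raise ValueError(f"group {g!r} is empty")
        parts.append(surv.loc[ids])
    res = _ll_logrank(
        parts[0]["time"],
        parts[1]["time"],
        event_observed_A=parts[0]["event"],
        event_observed_B=parts[1]["event"],
    )
    return float(res.test_statistic), float(res.p_value)
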
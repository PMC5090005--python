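"""Brain–behavior association: inverse efficiency, feature selection, OLS.

The behavioral score is the inverse efficiency (IE): mean correct-trial
response time divided by accuracy, in ms — lower is better, and the ratio
corrects the speed–accuracy trade-off.  Association proceeds in two stages,
both on the same subjects (a deliberately circular design that mirrors
common practice and is annotated as such in every report): (1) per-node
Pearson correlation of a nodal metric with IE, selecting nodes at
uncorrected p < α; (2) multiple linear regression of IE on the selected
nodes, overall and within each sub-network, with Benjamini–Hochberg FDR on
the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class BehavioralRecord:
    """Per-condition behavioral summary for one subject."""

    subject_id: str
    condition: str
    mean_rt_correct: float  # ms
    accuracy: float
    ie: float  # ms


@dataclass
class RegressionModel:
    """OLS fit of IE on selected nodal metrics."""

    predictors: list[int]
    coef_standardized: np.ndarray
    coef_raw: np.ndarray
    intercept: float
    F: float
    df1: int
    df2: int
    r2: float
    p_model: float
    coef_p: np.ndarray
    coef_fdr_flag: np.ndarray
    coef_p_adjusted: np.ndarray
    near_saturated: bool = False
    dropped_collinear: list[int] = field(default_factory=list)


def inverse_efficiency(
    trials: pd.DataFrame,
    subject_id: str = "",
    condition: str = "",
) -> BehavioralRecord:
    """Roll a per-trial (rt_ms, correct) table up to an IE score.

    accuracy = correct / total; IE = mean correct-trial RT / accuracy.
    """
    if "rt_ms" not in trials or "correct" not in trials:
        raise ValueError("trial table needs rt_ms and correct columns")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    correct = trials["correct"].astype(bool)
    n_correct = int(correct.sum())
    if n_correct == 0:
        raise ValueError(f"{subject_id}: no correct trials, IE undefined")
    accuracy = n_correct / len(trials)
    mean_rt = float(trials.loc[correct, "rt_ms"].mean())
    return BehavioralRecord(
        subject_id=subject_id,
        condition=condition,
        mean_rt_correct=mean_rt,
        accuracy=accuracy,
        ie=mean_rt / accuracy,
    )


def select_features(
    metric_matrix: np.ndarray,
    ie: np.ndarray,
    alpha: float = 0.05,
    node_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-node Pearson correlation with IE and uncorrected-p selection.

    Returns a table with columns node_id, r, p, selected.  Zero-variance
    node columns are excluded (r = NaN, selected False) with a warning.
    """
    x = np.asarray(metric_matrix, dtype=float)
    y = np.asarray(ie, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ids = np.arange(x.shape[1]) if node_ids is None else np.asarray(node_ids)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    dead = sx == 0
    if dead.any():
        warnings.warn(
            f"zero-variance metric column(s) excluded: {ids[dead].tolist()}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    r[dead] = np.nan
    p[dead] = np.nan
    selected = np.where(dead, False, p < alpha)
    return pd.DataFrame(
        {"node_id": ids, "r": r, "p": p, "selected": selected.astype(bool)}
    )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at the two-tailed level for n subjects."""
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if alpha >= 1:
        return 0.0
    df = n - 2
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(t / np.sqrt(t**2 + df))


def f_to_r2(F: float, df1: int, df2: int) -> float:
    """Coefficient of determination implied by an overall F statistic."""
    if F < 0:
        raise ValueError("F must be nonnegative")
    return df1 * F / (df1 * F + df2)


def fdr_adjust(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


def fit_regression(
    X: np.ndarray,
    y: np.ndarray,
    predictors: list[int] | None = None,
    fdr_q: float = 0.05,
) -> RegressionModel:
    """Multiple linear regression of IE on selected nodal metrics.

    The fit includes an intercept; coefficients are reported both on the
    raw scale and standardized (predictors and response z-scored — F, R²
    and p-values are invariant to that rescaling).  Collinear columns are
    dropped with a warning; models with predictors >= n/2 are flagged as
    near-saturated but fitted faithfully.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(y) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    ids = list(range(k)) if predictors is None else list(predictors)

    keep: list[int] = []
    dropped: list[int] = []
    design = np.ones((n, 1))
    for j in range(k):
        cand = np.column_stack([design, X[:, j]])
        if np.linalg.matrix_rank(cand) > design.shape[1]:
            design = cand
            keep.append(j)
        else:
            dropped.append(ids[j])
    if dropped:
        warnings.warn(f"dropped collinear predictor(s): {dropped}", stacklevel=2)
    Xk = X[:, keep]
    df1 = len(keep)
    df2 = n - df1 - 1
    if df1 == 0:
        raise ValueError("no usable predictors")
    if df2 < 1:
        raise ValueError(f"insufficient residual df (n={n}, predictors={df1})")
    near_saturated = df1 >= n / 2
    if near_saturated:
        warnings.warn(
            f"model nearly saturated: {df1} predictors for {n} subjects",
            stacklevel=2,
        )

    fit = sm.OLS(y, sm.add_constant(Xk, has_constant="add")).fit()
    coef_raw = fit.params[1:]
    coef_p = fit.pvalues[1:]
    sx = Xk.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    coef_std = coef_raw * sx / sy
    reject, adjusted = fdr_adjust(coef_p, q=fdr_q)
    return RegressionModel(
        predictors=[ids[j] for j in keep],
        coef_standardized=np.asarray(coef_std),
        coef_raw=np.asarray(coef_raw),
        intercept=float(fit.params[0]),
        F=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        r2=float(fit.rsquared),
        p_model=float(fit.f_pvalue),
        coef_p=np.asarray(coef_p),
        coef_fdr_flag=reject,
        coef_p_adjusted=adjusted,
        near_saturated=near_saturated,
        dropped_collinear=dropped,
    )


def subnetwork_models(
    selection: pd.DataFrame,
    atlas: pd.DataFrame,
    metric_matrix: np.ndarray,
    ie: np.ndarray,
    fdr_q: float = 0.05,
) -> dict[str, RegressionModel]:
    """One regression per sub-network, restricted to its selected nodes.

    Sub-networks with no selected node are skipped.  Coefficient FDR is
    applied within each model.
    """
    sel = selection[selection["selected"]]
    if sel.empty:
        raise ValueError("no selected nodes")
    node_to_net = dict(zip(atlas["node_id"], atlas["subnetwork"]))
    models: dict[str, RegressionModel] = {}
    for net in atlas["subnetwork"].unique():
        nodes = [int(n) for n in sel["node_id"] if node_to_net[int(n)] == net]
        if not nodes:
            continue
        models[net] = fit_regression(
            metric_matrix[:, nodes], ie, predictors=nodes, fdr_q=fdr_q
        )
    return models
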
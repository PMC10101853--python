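"""Cox proportional-hazards association of factors with overall survival.

Fits are delegated to lifelines (partial likelihood, Efron tie
handling); the model-level "logrank" significance is the score test of
the partial likelihood at beta = 0, computed here analytically, which
for a single binary covariate reduces to the classical logrank test.
Model comparison reports Harrell's concordance and the IPCW
cumulative/dynamic AUC at a horizon (scikit-survival).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .datatypes import SurvivalResult


def _score_test_at_zero(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Score (logrank) test of the Cox partial likelihood at beta = 0
    with Efron handling of tied event times.  Returns the chi-square
    p-value on X.shape[1] degrees of freedom."""
    n, p = X.shape
    order = np.argsort(time, kind="mergesort")
    X, time, event = X[order], time[order], event[order]
    U = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(time[event == 1])
    for t in event_times:
        risk = time >= t
        D = (time == t) & (event == 1)
        m = int(D.sum())
        Xr = X[risk]
        Xd = X[D]
        nr = Xr.shape[0]
        s_r = Xr.sum(axis=0)
        ss_r = Xr.T @ Xr
        s_d = Xd.sum(axis=0)
        ss_d = Xd.T @ Xd
        for l in range(m):
            f = l / m
            denom = nr - f * m
            mean_l = (s_r - f * s_d) / denom
            U += Xd[l] - mean_l
            ex2 = (ss_r - f * ss_d) / denom
            info += ex2 - np.outer(mean_l, mean_l)
    try:
        stat = float(U @ np.linalg.solve(info, U))
    except np.linalg.LinAlgError:
        return np.nan
    return float(stats.chi2.sf(stat, df=p))


def cox_association(
    covariates: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    standardize: bool = True,
) -> SurvivalResult:
    """Cox PH fit of survival on the covariates.

    Covariates are standardized to unit sd by default so hazard ratios
    are per-sd (forest-plot convention).  Rows with missing values are
    dropped (counted).  Non-convergence is flagged, not raised.
    """
    df = covariates.copy()
    df["time"] = time.loc[df.index]
    df["event"] = event.loc[df.index]
    n0 = len(df)
    df = df.dropna()
    n_dropped = n0 - len(df)
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    covs = [c for c in covariates.columns]
    if standardize:
        for c in covs:
            sd = df[c].std(ddof=1)
            if sd > 0:
                df[c] = (df[c] - df[c].mean()) / sd

    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-12, "max_steps": 500})
        except Exception:
            converged = False
    if converged:
        summ = cph.summary
        out = pd.DataFrame(
            {
                "coef": summ["coef"],
                "hr": summ["exp(coef)"],
                "hr_lower": summ["exp(coef) lower 95%"],
                "hr_upper": summ["exp(coef) upper 95%"],
                "wald_p": summ["p"],
            }
        )
        concordance = float(cph.concordance_index_)
    else:
        out = pd.DataFrame(
            {"coef": np.nan, "hr": np.nan, "hr_lower": np.nan,
             "hr_upper": np.nan, "wald_p": np.nan},
            index=covs,
        )
        concordance = np.nan
    logrank_p = _score_test_at_zero(
        df[covs].to_numpy(dtype=float),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
    )
    return SurvivalResult(
        summary=out,
        logrank_p=logrank_p,
        concordance=concordance,
        n_used=len(df),
        n_dropped=n_dropped,
        converged=converged,
    )


def _ipcw_auc(covariates: pd.DataFrame, time: pd.Series, event: pd.Series,
              risk_score: np.ndarray, horizon: float) -> float:
    from sksurv.metrics import cumulative_dynamic_auc

    y = np.empty(len(time), dtype=[("event", bool), ("time", float)])
    y["event"] = event.to_numpy().astype(bool)
    y["time"] = time.to_numpy(dtype=float)
    auc, _ = cumulative_dynamic_auc(y, y, risk_score, [horizon])
    return float(auc[0])


def compare_models(
    factor_sets: dict[str, list[str]],
    covariates: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    horizon: float,
) -> pd.DataFrame:
    """Fit one Cox model per covariate set and report concordance and the
    IPCW cumulative/dynamic AUC at ``horizon`` for each."""
    tmax = float(time[event.astype(bool)].max()) if event.astype(bool).any() else float(time.max())
    if horizon >= tmax:
        raise ValueError(f"horizon {horizon} is beyond the last observed event time {tmax}")
    rows = []
    for name, cols in factor_sets.items():
        res = cox_association(covariates[cols], time, event)
        risk = np.zeros(len(covariates))
        if res.converged:
            Xs = covariates[cols].copy()
            for c in cols:
                sd = Xs[c].std(ddof=1)
                if sd > 0:
                    Xs[c] = (Xs[c] - Xs[c].mean()) / sd
            risk = Xs.to_numpy(dtype=float) @ res.summary["coef"].to_numpy()
        auc = _ipcw_auc(covariates, time, event, risk, horizon)
        rows.append({"model": name, "n_covariates": len(cols),
                     "concordance": res.concordance, "auc": auc,
                     "logrank_p": res.logrank_p})
    return pd.DataFrame(rows).set_index("model")
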
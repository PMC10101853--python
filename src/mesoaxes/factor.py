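"""Shared-factor multi-view linear model and variance decomposition.

The model is Y_v ~ Z W_v^T per view v with a shared samples x K factor
matrix Z, fitted by alternating least squares on the weighted objective

    sum_v 1/(sigma2_v * p_v) || Y_v - Z W_v^T ||_F^2 ,

where p_v is the view's feature count (so large views do not dominate)
and sigma2_v is the view's noise variance, estimated from the residuals
of the SVD initialization and held fixed during ALS so the objective is
provably non-increasing.  This is a deterministic surrogate for
variational multi-omics factor analysis: the quantity of interest here
is factor recovery and per-view variance explained, not posterior
uncertainty.

Missing entries are permitted and masked out of the normal equations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datatypes import FactorModel, OmicsView


def _as_matrix(view) -> tuple[np.ndarray, list, list]:
    if isinstance(view, OmicsView):
        return view.values.to_numpy(dtype=float), list(view.values.index), list(view.values.columns)
    df = pd.DataFrame(view)
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def fit_multiview_factors(
    views: dict[str, OmicsView],
    K: int = 10,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = 0,
    balance_views: bool = True,
) -> FactorModel:
    """Fit the shared-factor model by alternating least squares.

    Views must share the sample axis and be per-feature centered.
    Factors are ordered by total variance explained (descending) and
    sign-fixed so each factor's largest-magnitude loading is positive.
    NaN entries are treated as missing and masked.
    """
    if not views:
        raise ValueError("at least one view required")
    names = list(views)
    mats, masks = {}, {}
    sample_ids = None
    for v in names:
        Y, sids, fids = _as_matrix(views[v])
        if Y.shape[1] == 0:
            raise ValueError(f"view {v!r} has zero features")
        if sample_ids is None:
            sample_ids = sids
        elif sids != sample_ids:
            raise ValueError(f"view {v!r} does not share the sample axis")
        mask = np.isfinite(Y)
        mats[v] = np.where(mask, Y, 0.0)
        masks[v] = mask
    n = len(sample_ids)
    if K > n:
        raise ValueError(f"K={K} exceeds n_samples={n}")

    # init: left singular vectors of the column-concatenated,
    # per-view variance-normalized matrix
    concat = []
    for v in names:
        Y = mats[v]
        tot = np.sum(Y**2) / max(masks[v].sum(), 1)
        scale = np.sqrt(tot) if tot > 0 else 1.0
        concat.append(Y / (scale * np.sqrt(Y.shape[1])))
    C = np.concatenate(concat, axis=1)
    U, s, _ = linalg.svd(C, full_matrices=False)
    Z = U[:, :K] * s[:K]

    weights = {v: 1.0 / mats[v].shape[1] if balance_views else 1.0 for v in names}
    W = {v: _update_loadings(mats[v], masks[v], Z) for v in names}
    sigma2 = {}
    for v in names:
        resid = mats[v] - (Z @ W[v].T) * masks[v]
        dof = max(masks[v].sum(), 1)
        sigma2[v] = max(np.sum(resid**2) / dof, 1e-12)

    def objective() -> float:
        tot = 0.0
        for v in names:
            resid = (mats[v] - Z @ W[v].T) * masks[v]
            tot += weights[v] / sigma2[v] * np.sum(resid**2)
        return tot

    trace = [objective()]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Z-step: per-sample weighted normal equations across views
        any_missing = any(not masks[v].all() for v in names)
        if not any_missing:
            G = np.zeros((K, K))
            R = np.zeros((n, K))
            for v in names:
                wv = weights[v] / sigma2[v]
                G += wv * (W[v].T @ W[v])
                R += wv * (mats[v] @ W[v])
            ridge = 1e-9 * max(np.trace(G) / K, 1e-12)
            Z = linalg.solve(G + ridge * np.eye(K), R.T, assume_a="pos").T
        else:
            Z = _update_factors_masked(mats, masks, W, weights, sigma2, names, n, K)
        # W-step: per-view least squares (weights cancel within a view)
        for v in names:
            W[v] = _update_loadings(mats[v], masks[v], Z)
        trace.append(objective())
        if abs(trace[-2] - trace[-1]) <= tol * max(trace[-2], 1e-300):
            converged = True
            break

    # order factors by total variance explained, fix signs
    r2 = _r2_matrix(mats, masks, Z, W, names)
    order = np.argsort(-r2.sum(axis=0))
    Z = Z[:, order]
    for v in names:
        W[v] = W[v][:, order]
    r2 = r2[:, order]
    for k in range(K):
        allw = np.concatenate([W[v][:, k] for v in names])
        if len(allw) and allw[np.argmax(np.abs(allw))] < 0:
            Z[:, k] *= -1
            for v in names:
                W[v][:, k] *= -1

    factor_names = [f"LF{k + 1}" for k in range(K)]
    model = FactorModel(
        Z=pd.DataFrame(Z, index=sample_ids, columns=factor_names),
        W={
            v: pd.DataFrame(W[v], index=views[v].values.columns if isinstance(views[v], OmicsView) else pd.DataFrame(views[v]).columns, columns=factor_names)
            for v in names
        },
        sigma2=sigma2,
        r2=pd.DataFrame(r2, index=names, columns=factor_names),
        iterations=it,
        converged=converged,
        objective_trace=np.asarray(trace),
    )
    return model


def _update_loadings(Y: np.ndarray, mask: np.ndarray, Z: np.ndarray) -> np.ndarray:
    K = Z.shape[1]
    if mask.all():
        G = Z.T @ Z
        G += 1e-9 * max(np.trace(G) / K, 1e-12) * np.eye(K)
        return linalg.solve(G, Z.T @ Y, assume_a="pos").T
    p = Y.shape[1]
    W = np.empty((p, K))
    for j in range(p):
        m = mask[:, j]
        Zm = Z[m]
        G = Zm.T @ Zm
        G += 1e-9 * max(np.trace(G) / K, 1e-12) * np.eye(K)
        W[j] = linalg.solve(G, Zm.T @ Y[m, j], assume_a="pos")
    return W


def _update_factors_masked(mats, masks, W, weights, sigma2, names, n, K):
    Z = np.empty((n, K))
    for i in range(n):
        G = np.zeros((K, K))
        r = np.zeros(K)
        for v in names:
            m = masks[v][i]
            Wm = W[v][m]
            wv = weights[v] / sigma2[v]
            G += wv * (Wm.T @ Wm)
            r += wv * (Wm.T @ mats[v][i, m])
        G += 1e-9 * max(np.trace(G) / K, 1e-12) * np.eye(K)
        Z[i] = linalg.solve(G, r, assume_a="pos")
    return Z


def _r2_matrix(mats, masks, Z, W, names) -> np.ndarray:
    K = Z.shape[1]
    r2 = np.zeros((len(names), K))
    for vi, v in enumerate(names):
        Y = mats[v]
        tot = np.sum(Y**2)
        if tot == 0:
            continue
        for k in range(K):
            recon = np.outer(Z[:, k], W[v][:, k]) * masks[v]
            r2[vi, k] = max(1.0 - np.sum((Y - recon) ** 2) / tot, 0.0)
    return r2


def variance_explained(model: FactorModel, view: str) -> pd.Series:
    """Per-factor fraction of the (centered) view variance explained,
    one factor at a time: r2_k = 1 - ||Y - z_k w_k^T||^2 / ||Y||^2."""
    if view not in model.r2.index:
        raise ValueError(f"view {view!r} not in fitted model")
    return model.r2.loc[view]


def covariate_variance_explained(view, covariate: pd.Series) -> float:
    """Pooled fraction of a view's variance explained by a categorical
    covariate: R2 = 1 - sum_f SS_res(f) / sum_f SS_tot(f) after a
    group-mean fit per feature.  Constant features are excluded."""
    Y, sids, _ = _as_matrix(view)
    cov = covariate.loc[sids] if hasattr(covariate, "loc") else pd.Series(covariate, index=sids)
    levels = pd.unique(cov)
    if len(levels) < 2:
        raise ValueError("covariate must have at least 2 levels")
    Yc = Y - Y.mean(axis=0)
    ss_tot = np.sum(Yc**2, axis=0)
    keep = ss_tot > 0
    resid = Yc.copy()
    for lev in levels:
        m = (cov == lev).to_numpy()
        resid[m] -= Yc[m].mean(axis=0)
    ss_res = np.sum(resid**2, axis=0)
    denom = ss_tot[keep].sum()
    if denom == 0:
        return 0.0
    return float(1.0 - ss_res[keep].sum() / denom)


def select_major_factors(model: FactorModel, threshold: float = 0.10) -> list[str]:
    """Factors explaining more than ``threshold`` of the variance in at
    least one molecular layer."""
    hit = (model.r2 > threshold).any(axis=0)
    return [f for f in model.r2.columns if hit[f]]


def correlate_factor_with_covariate(
    Z: pd.DataFrame, covariate: pd.Series, adjust: bool = False
) -> pd.DataFrame:
    """Two-sided Pearson correlation of each factor with a continuous
    covariate; optional BH adjustment across factors."""
    cov = covariate.loc[Z.index].to_numpy(dtype=float)
    if np.std(cov) == 0:
        raise ValueError("constant covariate")
    rows = []
    for f in Z.columns:
        r, p = stats.pearsonr(Z[f].to_numpy(), cov)
        rows.append({"factor": f, "r": r, "p": p})
    out = pd.DataFrame(rows).set_index("factor")
    if adjust:
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
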
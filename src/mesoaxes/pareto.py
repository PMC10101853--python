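"""Archetypal analysis (principal convex hull) on factor coordinates.

Fits the minimal k-vertex polytope enclosing the samples in factor
space: each sample is approximated as a convex combination (rows of A)
of k archetypes, themselves convex combinations (rows of B) of the
samples.  Fit quality is summarized by the reconstruction SSE, variance
explained, and — in two dimensions — the t-ratio (polytope area over
data convex-hull area).  Significance of a triangular (k = 3) fit is a
one-sided randomization test that permutes each coordinate column
independently, destroying the multivariate shape while preserving the
marginals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import linalg
from scipy.optimize import linear_sum_assignment, nnls
from scipy.spatial import ConvexHull

from .datatypes import ArchetypeFit, FactorModel


def order_factor_axes(
    model: FactorModel, expression_view_name: str, factor_subset: list[str]
) -> np.ndarray:
    """Selected factor columns sorted by decreasing variance explained in
    the expression layer (ties broken by factor index ascending).

    Returns the samples x d coordinate matrix; the chosen order is
    available as ``order_factor_axes.last_order`` on the result via the
    companion function :func:`ordered_factor_names`.
    """
    names = ordered_factor_names(model, expression_view_name, factor_subset)
    return model.Z[names].to_numpy(dtype=float)


def ordered_factor_names(
    model: FactorModel, expression_view_name: str, factor_subset: list[str]
) -> list[str]:
    if not factor_subset:
        raise ValueError("empty factor subset")
    missing = [f for f in factor_subset if f not in model.r2.columns]
    if missing:
        raise ValueError(f"factors not in model: {missing}")
    r2 = model.r2.loc[expression_view_name]
    idx = {f: i for i, f in enumerate(model.r2.columns)}
    return sorted(factor_subset, key=lambda f: (-r2[f], idx[f]))


def _simplex_lsq(E: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Exact simplex-constrained least squares, vectorized over samples.

    For each row x of X solve min ||x - a^T E||^2 over a >= 0,
    sum(a) = 1, with E the k x d archetype matrix.  The optimum's active
    set is some support subset, so for k <= ~8 we enumerate supports,
    solve the equality-constrained problem on each via a precomputed KKT
    inverse, and keep the best feasible solution per sample.
    """
    k, d = E.shape
    n = X.shape[0]
    best_obj = np.full(n, np.inf)
    best_A = np.zeros((n, k))
    for size in range(1, k + 1):
        for S in combinations(range(k), size):
            Es = E[list(S)]  # size x d
            if size == 1:
                a = np.ones((n, 1))
                resid = X - Es
                obj = np.einsum("ij,ij->i", resid, resid)
                feas = np.ones(n, dtype=bool)
            else:
                G = Es @ Es.T
                KKT = np.zeros((size + 1, size + 1))
                KKT[:size, :size] = G
                KKT[:size, size] = 1.0
                KKT[size, :size] = 1.0
                # degenerate supports (duplicate archetypes) are covered by
                # their smaller subsets; skip them
                if np.linalg.cond(KKT) > 1e12:
                    continue
                KKT_inv = linalg.inv(KKT)
                rhs = np.concatenate([Es @ X.T, np.ones((1, n))], axis=0)
                sol = KKT_inv @ rhs  # (size+1) x n
                a = sol[:size].T
                feas = (a >= -1e-10).all(axis=1)
                recon = a @ Es
                resid = X - recon
                obj = np.einsum("ij,ij->i", resid, resid)
            upd = feas & (obj < best_obj - 1e-15)
            if upd.any():
                best_obj[upd] = obj[upd]
                best_A[upd] = 0.0
                cols = list(S)
                best_A[np.ix_(upd, cols)] = np.clip(a[upd], 0.0, None)
    # renormalize away the tiny negative clips
    best_A /= best_A.sum(axis=1, keepdims=True)
    return best_A


def _furthest_sum(X: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """Furthest-sum seeding: greedily pick points maximizing the summed
    distance to the already-chosen set; the random first pick is dropped
    and re-chosen once the set is full."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(k - 1):
        dists = np.zeros(n)
        for j in idx:
            dists += np.linalg.norm(X - X[j], axis=1)
        dists[idx] = -np.inf
        idx.append(int(np.argmax(dists)))
    if k > 1:  # replace the random seed point
        first = idx.pop(0)
        dists = np.zeros(n)
        for j in idx:
            dists += np.linalg.norm(X - X[j], axis=1)
        dists[idx] = -np.inf
        idx.append(int(np.argmax(dists)))
    return idx


def _update_B(X: np.ndarray, A: np.ndarray, B_old: np.ndarray) -> np.ndarray:
    """Archetype update: unconstrained optimum Y* = (A^T A)^-1 A^T X, then
    per archetype the closest convex combination of samples (penalty NNLS
    on the d+1 augmented system, coefficients renormalized)."""
    k = A.shape[1]
    G = A.T @ A + 1e-12 * np.eye(k)
    Y_star = linalg.solve(G, A.T @ X, assume_a="pos")  # k x d
    n, d = X.shape
    # rotation-invariant penalty scale so rigid motions leave the fit unchanged
    scale = max(float(np.linalg.norm(X, axis=1).mean()), 1e-6)
    rho = 10.0 * scale
    M = np.concatenate([X.T, rho * np.ones((1, n))], axis=0)  # (d+1) x n
    B = np.empty((k, n))
    for j in range(k):
        rhs = np.concatenate([Y_star[j], [rho]])
        b, _ = nnls(M, rhs)
        s = b.sum()
        B[j] = b / s if s > 0 else np.full(n, 1.0 / n)
    return B


def fit_archetypes(
    X: np.ndarray,
    k: int,
    delta: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | np.random.Generator = 0,
    init_B: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> ArchetypeFit:
    """Fit k archetypes to the samples x d coordinate matrix X.

    Alternates exact simplex-constrained least squares for A with a
    safeguarded archetype update for B (an update that would increase the
    objective is rejected), so the SSE is non-increasing by construction.
    Initialization is furthest-sum vertex seeding unless ``init_B`` is
    given (used by the bootstrap for warm starts).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if delta != 0.0:
        raise NotImplementedError("archetype relaxation (delta != 0) is not supported")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # fit in centered coordinates: makes the algorithm exactly equivariant
    # under rigid rotation + translation of X
    center = X.mean(axis=0)
    X_orig = X
    X = X - center

    if init_B is not None:
        B = np.asarray(init_B, dtype=float).copy()
    else:
        B = np.zeros((k, n))
        for j, i in enumerate(_furthest_sum(X, k, rng)):
            B[j, i] = 1.0

    E = B @ X
    A = _simplex_lsq(E, X)
    sse = float(np.sum((X - A @ E) ** 2))
    trace = [sse]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        B_new = _update_B(X, A, B)
        E_new = B_new @ X
        A_new = _simplex_lsq(E_new, X)
        sse_new = float(np.sum((X - A_new @ E_new) ** 2))
        if sse_new <= sse + 1e-15:
            B, E, A = B_new, E_new, A_new
        else:  # safeguarded: keep old B, refresh A only
            A_new = _simplex_lsq(E, X)
            sse_new = float(np.sum((X - A_new @ E) ** 2))
            if sse_new < sse:
                A = A_new
            else:
                converged = True
                break
        trace.append(sse_new)
        if abs(sse - sse_new) <= tol * max(sse, 1e-300):
            sse = sse_new
            converged = True
            break
        sse = sse_new

    sst = float(np.sum(X**2))
    var_expl = 1.0 - sse / sst if sst > 0 else 1.0
    E = E + center  # back to the original coordinate frame
    t_ratio = polytope_hull_ratio(E, X_orig) if d == 2 and k >= 3 else None
    return ArchetypeFit(
        X=X_orig, k=k, archetypes=E, A=A, B=B, sse=sse, var_expl=var_expl,
        t_ratio=t_ratio, iterations=it, converged=converged, sample_ids=sample_ids,
        sse_trace=np.asarray(trace),
    )


def _polygon_area(P: np.ndarray) -> float:
    """Shoelace area of the polygon through the points in angular order."""
    c = P.mean(axis=0)
    ang = np.arctan2(P[:, 1] - c[1], P[:, 0] - c[0])
    Q = P[np.argsort(ang)]
    x, y = Q[:, 0], Q[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polytope_hull_ratio(archetypes: np.ndarray, X: np.ndarray) -> float:
    """2-D t-ratio: fitted polytope area over the data convex-hull area."""
    hull = ConvexHull(X)
    hull_area = hull.volume  # in 2-D, .volume is the area
    if hull_area <= 0:
        raise ValueError("degenerate convex hull (zero area)")
    return _polygon_area(archetypes) / hull_area


def bootstrap_archetypes(
    X: np.ndarray,
    k: int,
    n_boot: int = 200,
    frac: float = 0.75,
    seed: int = 0,
    reference: ArchetypeFit | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
):
    """Bootstrap variability of archetype positions.

    Each replicate subsamples ceil(frac * n) samples without
    replacement, refits warm-started from the reference archetypes, and
    aligns its archetypes to the reference by minimal-total-distance
    bipartite matching.  Returns (mean positions, per-archetype
    positional sd, aligned positions array of shape n_boot x k x d).
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = fit_archetypes(X, k, seed=rng, tol=tol, max_iter=max_iter)
    m = int(np.ceil(frac * n))
    positions = np.empty((n_boot, k, d))
    for b in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        Xb = X[idx]
        # warm start: archetypes as convex combos of the nearest subsample points
        initB = np.zeros((k, m))
        for j in range(k):
            nearest = np.argmin(np.linalg.norm(Xb - reference.archetypes[j], axis=1))
            initB[j, nearest] = 1.0
        if frac == 1.0:
            fit = fit_archetypes(Xb, k, seed=rng, tol=tol, max_iter=max_iter,
                                 init_B=_reference_B_on(idx, reference, m))
        else:
            fit = fit_archetypes(Xb, k, seed=rng, tol=tol, max_iter=max_iter, init_B=initB)
        positions[b] = align_archetypes(fit.archetypes, reference.archetypes)
    mean_pos = positions.mean(axis=0)
    sd = np.sqrt(((positions - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    return mean_pos, sd, positions


def _reference_B_on(idx: np.ndarray, reference: ArchetypeFit, m: int) -> np.ndarray:
    """Restrict the reference B to the subsample (only valid for frac=1,
    where idx is a permutation of all samples)."""
    B = reference.B[:, idx]
    s = B.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return B / s


def align_archetypes(candidate: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute candidate archetypes to minimize total distance to the
    reference (Hungarian matching); invariant to label permutations."""
    cost = np.linalg.norm(candidate[:, None, :] - reference[None, :, :], axis=2)
    row, col = linear_sum_assignment(cost)
    out = np.empty_like(candidate)
    out[col] = candidate[row]
    return out


def fit_significance(
    X: np.ndarray,
    k: int = 3,
    n_perm: int = 999,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[float, float, np.ndarray]:
    """One-sided randomization test of the k-archetype fit.

    Observed statistic: the t-ratio for d = 2 (polytope area over hull
    area); for d > 2 the variance explained.  The null permutes each
    coordinate column independently across samples and refits.  Returns
    ``(p, observed, null_statistics)`` with
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if k < 3 and d >= 2:
        raise ValueError("k must be >= 3 for a 2-D polytope")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def statistic(M: np.ndarray) -> float:
        fit = fit_archetypes(M, k, seed=rng, tol=tol, max_iter=max_iter)
        if d == 2:
            return fit.t_ratio
        return fit.var_expl

    obs = statistic(X)
    null = np.empty(n_perm)
    for b in range(n_perm):
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(d)])
        null[b] = statistic(Xp)
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return p, obs, null


def archetype_proportions(fit: ArchetypeFit) -> np.ndarray:
    """Per-sample convex weights on the archetypes (rows of A); for k = 3
    these double as ternary-plot coordinates."""
    return fit.A.copy()
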
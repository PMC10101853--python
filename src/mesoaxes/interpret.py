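"""Archetype characterization and alteration effect vectors.

Covers three questions: which genes and gene sets characterize each
archetype (directional ordered-hypergeometric enrichment on genes ranked
by correlation with the archetype proportion); which clinical covariates
associate with the archetypes; and how Boolean genomic alterations
displace carriers on the factor plane (effect vectors, per-alteration
MANOVA, and a global joint-permutation test of specialization tuning).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests

from .datatypes import EffectVector, OmicsView

logger = logging.getLogger(__name__)


def correlate_features_with_archetypes(
    expression_view: OmicsView, proportions: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Two-sided Pearson correlation of every gene with each archetype's
    proportion column.  Constant genes are excluded (counted in the log).
    Returns a mapping archetype -> DataFrame(gene_id -> r, p)."""
    vals = expression_view.values.loc[proportions.index]
    X = vals.to_numpy(dtype=float)
    n = X.shape[0]
    sd = X.std(axis=0)
    keep = sd > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.info("correlate_features_with_archetypes: %d constant genes excluded", n_const)
    Xc = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    genes = vals.columns[keep]
    out = {}
    for arch in proportions.columns:
        y = proportions[arch].to_numpy(dtype=float)
        ys = y.std()
        if ys == 0:
            raise ValueError(f"constant proportion column {arch!r}")
        yc = (y - y.mean()) / ys
        r = (Xc * yc[:, None]).sum(axis=0) / n
        r = np.clip(r, -1.0, 1.0)
        # two-sided p via the t transform, matching scipy.stats.pearsonr
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        out[arch] = pd.DataFrame({"r": r, "p": p}, index=genes)
    return out


def _min_ordered_hypergeom(positions: np.ndarray, N: int) -> float:
    """Minimum over cutoffs of the one-sided hypergeometric tail p for a
    set whose members sit at the given 1-based ranks of an N-gene list.

    The tail p at cutoff r is P(X >= c_r) with c_r the number of members
    at rank <= r; the minimum over all cutoffs is attained at a member
    position, so only |set| cutoffs are evaluated.
    """
    pos = np.sort(positions)
    K = len(pos)
    counts = np.arange(1, K + 1)
    return float(stats.hypergeom.sf(counts - 1, N, K, pos).min())


def _null_min_p(N: int, K: int, n_cal: int, rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the cutoff-scan minimum p for a random size-K
    subset of N ranked genes (vectorized over replicates)."""
    # positions of K random members among N ranks, per replicate
    pos = np.empty((n_cal, K), dtype=int)
    for b in range(n_cal):
        pos[b] = np.sort(rng.choice(N, size=K, replace=False) + 1)
    counts = np.arange(1, K + 1)[None, :]
    tails = stats.hypergeom.sf(counts - 1, N, K, pos)
    return tails.min(axis=1)


def enrich_gene_sets(
    gene_stats: pd.DataFrame,
    sets: dict[str, list[str]],
    direction: str,
    min_size: int = 20,
    max_size: int = 1000,
    n_cal: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Directional ordered-hypergeometric gene-set enrichment.

    Genes with the requested sign of r are ranked by ascending p; per
    set, the minimum hypergeometric tail p over all rank cutoffs is
    computed and calibrated against ``n_cal`` random subsets of the same
    size (the permutation tail probability of the minimum), then
    BH-adjusted across sets.  ``direction`` is 'positive' or 'negative'.
    """
    if direction not in {"positive", "negative"}:
        raise ValueError("direction must be 'positive' or 'negative'")
    sign = gene_stats["r"] > 0 if direction == "positive" else gene_stats["r"] < 0
    # ascending p, ties broken by gene id (stable sort after an index sort)
    ranked = gene_stats[sign].sort_index(kind="mergesort").sort_values("p", kind="mergesort")
    genes = list(ranked.index)
    N = len(genes)
    if N == 0:
        return pd.DataFrame(columns=["set_id", "n_overlap", "min_p", "p", "q"]).set_index("set_id")
    rank_of = {g: i + 1 for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for set_id, members in sets.items():
        members = [g for g in set(members) if g in rank_of]
        K = len(members)
        if not min_size <= K <= max_size:
            continue
        positions = np.array([rank_of[g] for g in members])
        obs = _min_ordered_hypergeom(positions, N)
        if K not in null_cache:
            null_cache[K] = _null_min_p(N, K, n_cal, rng)
        null = null_cache[K]
        p_cal = (1.0 + np.sum(null <= obs)) / (1.0 + n_cal)
        rows.append({"set_id": set_id, "n_overlap": K, "min_p": obs, "p": p_cal})
    if not rows:
        return pd.DataFrame(columns=["set_id", "n_overlap", "min_p", "p", "q"]).set_index("set_id")
    out = pd.DataFrame(rows).set_index("set_id")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def archetype_covariate_association(
    proportions: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Association between each archetype proportion and each covariate:
    two-sided Pearson for continuous covariates, one-way ANOVA across
    levels for categoricals; BH adjustment across covariates (within
    archetype)."""
    rows = []
    for arch in proportions.columns:
        y = proportions[arch]
        for cov in covariates.columns:
            x = covariates[cov].loc[y.index]
            if x.dtype.kind in "OUSb" or isinstance(x.dtype, pd.CategoricalDtype):
                levels = x.unique()
                if len(levels) < 2:
                    raise ValueError(f"single-level categorical covariate {cov!r}")
                groups = [y[x == lev].to_numpy() for lev in levels]
                stat, p = stats.f_oneway(*groups)
                rows.append({"archetype": arch, "covariate": cov,
                             "kind": "categorical", "statistic": stat, "p": p})
            else:
                r, p = stats.pearsonr(y.to_numpy(dtype=float), x.to_numpy(dtype=float))
                rows.append({"archetype": arch, "covariate": cov,
                             "kind": "continuous", "statistic": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for arch in proportions.columns:
        m = out["archetype"] == arch
        out.loc[m, "q"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    return out


def effect_vectors(
    coords: np.ndarray,
    alteration_matrix: pd.DataFrame,
    min_group: int = 3,
) -> list[EffectVector]:
    """Per-alteration displacement on the factor plane.

    vector = mean(coords | altered) - mean(coords | wild-type); the
    per-alteration p is a one-way MANOVA (Pillai trace) of the
    coordinates on carrier status, BH-adjusted across alterations.
    Alterations with a carrier or wild-type group below ``min_group``
    are skipped.
    """
    X = np.asarray(coords, dtype=float)
    results = []
    for alt in alteration_matrix.columns:
        carrier = alteration_matrix[alt].to_numpy().astype(bool)
        n_alt, n_wt = int(carrier.sum()), int((~carrier).sum())
        if n_alt < min_group or n_wt < min_group:
            logger.info("effect_vectors: %s skipped (%d carriers, %d wild-type)",
                        alt, n_alt, n_wt)
            continue
        vec = X[carrier].mean(axis=0) - X[~carrier].mean(axis=0)
        p = _pillai_p(X, carrier)
        results.append(EffectVector(alteration=alt, vector=vec,
                                    n_altered=n_alt, n_wildtype=n_wt, anova_p=p))
    if results:
        qs = multipletests([e.anova_p for e in results], method="fdr_bh")[1]
        for e, q in zip(results, qs):
            e.q = float(q)
    return results


def _pillai_p(X: np.ndarray, carrier: np.ndarray) -> float:
    exog = np.column_stack([np.ones(len(carrier)), carrier.astype(float)])
    try:
        mv = MANOVA(endog=X, exog=exog)
        res = mv.mv_test(hypotheses=[("carrier", np.array([[0.0, 1.0]]))])
        tab = res.results["carrier"]["stat"]
        return float(tab.loc["Pillai's trace", "Pr > F"])
    except np.linalg.LinAlgError:
        # zero within-group variance: perfectly separated groups
        diff = X[carrier].mean(axis=0) - X[~carrier].mean(axis=0)
        return 0.0 if np.linalg.norm(diff) > 0 else 1.0


def global_specialization_test(
    coords: np.ndarray,
    alteration_matrix: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    min_group: int = 3,
) -> tuple[float, float, np.ndarray]:
    """Joint-permutation test of whether alterations collectively tune
    specialization.

    Observed statistic: mean effect-vector norm over testable
    alterations.  Null: one joint permutation of the sample order of the
    coordinates per replicate (preserving alteration co-occurrence).
    Returns ``(p, observed, null_statistics)``.
    """
    X = np.asarray(coords, dtype=float)
    carriers = []
    for alt in alteration_matrix.columns:
        c = alteration_matrix[alt].to_numpy().astype(bool)
        if c.sum() >= min_group and (~c).sum() >= min_group:
            carriers.append(c)
    if not carriers:
        raise ValueError("no alterations with enough carriers to test")

    def statistic(M: np.ndarray) -> float:
        norms = [
            np.linalg.norm(M[c].mean(axis=0) - M[~c].mean(axis=0)) for c in carriers
        ]
        return float(np.mean(norms))

    obs = statistic(X)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = statistic(X[rng.permutation(len(X))])
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return p, obs, null
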
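"""CpG-island methylator phenotype (CIMP) indexing and related screens.

The CIMP index of a sample is the fraction of CpG islands whose mean
beta value is at or above a threshold (default 0.3, i.e. >=30%
methylated).  The silencing screen looks for genes whose expression is
negatively correlated with both the CIMP index and the methylation of
their own island(s), the classic signature of methylation-driven
silencing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CIMPResult, OmicsView

logger = logging.getLogger(__name__)

# Default five-gene proxy: the five genes reported as silenced with
# increasing CIMP in pleural mesothelioma.  User-overridable; real
# cohorts should supply their own curated set.
DEFAULT_CIMP_PROXY_GENES = ["CBFA2T3", "FBLN2", "PRF1", "SLC34A2", "WT1"]


def island_beta(beta_view: OmicsView, island_map: dict[str, list[str]]) -> pd.DataFrame:
    """Per-sample unweighted mean beta over each island's CpGs.

    CpGs listed in the map but absent from the view are skipped (logged);
    islands with no present CpGs are dropped with a warning.
    """
    present = set(beta_view.feature_ids)
    cols, names = [], []
    n_missing = 0
    vals = beta_view.values
    for isl, cpgs in island_map.items():
        have = [c for c in cpgs if c in present]
        n_missing += len(cpgs) - len(have)
        if not have:
            logger.warning("island %s has no CpGs present; dropped", isl)
            continue
        cols.append(vals[have].mean(axis=1))
        names.append(isl)
    if n_missing:
        logger.info("island_beta: %d mapped CpGs absent from the view", n_missing)
    return pd.concat(cols, axis=1, keys=names) if cols else pd.DataFrame(index=vals.index)


def cimp_index(island_beta_mat: pd.DataFrame, threshold: float = 0.3) -> pd.Series:
    """Fraction of islands with mean beta >= ``threshold`` per sample
    (inclusive comparison)."""
    if island_beta_mat.shape[1] == 0:
        raise ValueError("empty island set")
    arr = island_beta_mat.to_numpy()
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("island betas must lie in [0,1]")
    return pd.Series(
        (arr >= threshold).mean(axis=1), index=island_beta_mat.index, name="cimp_index"
    )


def compute_cimp(beta_view: OmicsView, island_map: dict, threshold: float = 0.3) -> CIMPResult:
    ib = island_beta(beta_view, island_map)
    return CIMPResult(island_beta=ib, cimp_index=cimp_index(ib, threshold), threshold=threshold)


def silencing_screen(
    expression_view: OmicsView,
    island_beta_mat: pd.DataFrame,
    cimp: pd.Series,
    gene_island_link: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genes whose expression is negatively correlated with both the CIMP
    index and their own island's methylation (both BH-adjusted q below
    ``q_threshold``).

    ``gene_island_link`` needs columns ``gene_id`` and ``island_id``; a
    gene linked to several islands uses the mean beta across them.
    Returns the full per-gene table with a ``reported`` flag.
    """
    link = gene_island_link.groupby("gene_id")["island_id"].apply(list)
    samples = expression_view.sample_ids
    cimp_v = cimp.loc[samples].to_numpy(dtype=float)
    n_unlinked = 0
    rows = []
    for g in expression_view.feature_ids:
        if g not in link.index:
            n_unlinked += 1
            continue
        islands = [i for i in link[g] if i in island_beta_mat.columns]
        if not islands:
            n_unlinked += 1
            continue
        expr = expression_view.values[g].to_numpy(dtype=float)
        own = island_beta_mat.loc[samples, islands].mean(axis=1).to_numpy()
        if np.std(expr) == 0 or np.std(own) == 0:
            continue
        r_c, p_c = stats.pearsonr(expr, cimp_v)
        r_i, p_i = stats.pearsonr(expr, own)
        rows.append({"gene_id": g, "r_cimp": r_c, "p_cimp": p_c,
                     "r_island": r_i, "p_island": p_i})
    if n_unlinked:
        logger.info("silencing_screen: %d genes without a linked island excluded", n_unlinked)
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "r_cimp", "p_cimp", "q_cimp",
                     "r_island", "p_island", "q_island", "reported"]
        ).set_index("gene_id")
    tab = pd.DataFrame(rows).set_index("gene_id")
    tab["q_cimp"] = multipletests(tab["p_cimp"], method="fdr_bh")[1]
    tab["q_island"] = multipletests(tab["p_island"], method="fdr_bh")[1]
    tab["reported"] = (
        (tab["r_cimp"] < 0) & (tab["r_island"] < 0)
        & (tab["q_cimp"] < q_threshold) & (tab["q_island"] < q_threshold)
    )
    return tab


def proxy_scores(
    expression_view: OmicsView | None,
    island_beta_mat: pd.DataFrame | None,
    cn_view: OmicsView | None,
    clinical: pd.DataFrame | None,
    marker_config: dict,
) -> pd.DataFrame:
    """Simple per-sample surrogates for the four latent axes.

    - ``aneuploidy``: mean over genes of |CN - sample modal CN| where the
      modal CN is the per-sample median rounded to the nearest integer
      (a pragmatic aneuploidy burden, not a published formula).
    - ``sarcomatoid_pct``: passed through from the clinical table.
    - ``adaptive_minus_innate``: mean z-scored expression of the adaptive
      marker set minus that of the innate set.
    - ``cimp_proxy``: mean island beta over the configured island set.

    ``marker_config`` keys: ``adaptive``, ``innate`` (gene id lists) and
    ``proxy_islands`` (island id list).
    """
    out = {}
    index = None
    if cn_view is not None:
        cn = cn_view.values.to_numpy(dtype=float)
        modal = np.round(np.median(cn, axis=1))
        out["aneuploidy"] = pd.Series(
            np.abs(cn - modal[:, None]).mean(axis=1), index=cn_view.values.index
        )
        index = cn_view.values.index
    if clinical is not None and "sarcomatoid_pct" in clinical:
        out["sarcomatoid_pct"] = clinical["sarcomatoid_pct"]
        index = clinical.index if index is None else index
    if expression_view is not None:
        adaptive = marker_config.get("adaptive", [])
        innate = marker_config.get("innate", [])
        if not adaptive or not innate:
            raise ValueError("adaptive and innate marker sets must be non-empty")
        vals = expression_view.values
        z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1).replace(0, np.nan)
        a = [g for g in adaptive if g in z.columns]
        i = [g for g in innate if g in z.columns]
        if not a or not i:
            raise ValueError("marker sets have no overlap with the expression view")
        out["adaptive_minus_innate"] = z[a].mean(axis=1) - z[i].mean(axis=1)
        index = vals.index if index is None else index
    if island_beta_mat is not None:
        islands = marker_config.get("proxy_islands", [])
        if not islands:
            raise ValueError("proxy island set must be non-empty")
        have = [i for i in islands if i in island_beta_mat.columns]
        if not have:
            raise ValueError("no configured proxy islands present")
        out["cimp_proxy"] = island_beta_mat[have].mean(axis=1)
        index = island_beta_mat.index if index is None else index
    return pd.DataFrame(out, index=index)
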
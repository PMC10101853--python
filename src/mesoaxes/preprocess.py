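"""Per-layer feature engineering ahead of multi-view factorization.

Each filter follows the cohort-analysis conventions for this data type:
expression keeps autosomal genes whose FPKM spans at least 1 unit and
then the 5,000 most variable; methylation keeps autosomal CpGs with a
beta range of at least 0.1, split by genomic region, ranked by M-value
variance; copy number is purity-adjusted to a diploid-admixture scale,
grouped by identical profiles, restricted to recurrently altered
features and standardized; alterations are booleanized with a
recurrence and expression floor.

Variance ranking uses the sample variance (n-1 denominator) with ties
broken by feature id, so the kept set is independent of input order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import OmicsView, PurityTable, is_sex_chromosome

logger = logging.getLogger(__name__)


def _autosomal(view: OmicsView) -> pd.Index:
    keep = [f for f in view.feature_ids
            if not is_sex_chromosome(view.feature_meta.at[f, "chromosome"])]
    return pd.Index(keep)


def _top_k_by_variance(values: pd.DataFrame, top_k: int) -> list[str]:
    """Top-k feature ids by sample variance; ties broken lexicographically.

    Sorting on (-variance, feature_id) makes the selection deterministic
    and independent of the input column order.
    """
    var = values.var(axis=0, ddof=1)
    order = sorted(var.index, key=lambda f: (-var[f], f))
    return order[: min(top_k, len(order))]


def filter_expression(
    view_norm: OmicsView,
    view_fpkm: OmicsView,
    min_fpkm_range: float = 1.0,
    drop_sex: bool = True,
    top_k: int = 5000,
) -> OmicsView:
    """Expression filter: FPKM range >= ``min_fpkm_range``, autosomes only,
    then the ``top_k`` most variable genes of the normalized values."""
    if list(view_norm.feature_ids) != list(view_fpkm.feature_ids) or \
            list(view_norm.sample_ids) != list(view_fpkm.sample_ids):
        raise ValueError("normalized and FPKM views must share feature and sample ids")
    fpkm = view_fpkm.values
    rng_ok = (fpkm.max(axis=0) - fpkm.min(axis=0)) >= min_fpkm_range
    keep = rng_ok[rng_ok].index
    if drop_sex:
        keep = keep.intersection(_autosomal(view_norm))
    kept = _top_k_by_variance(view_norm.values[keep], top_k)
    if len(kept) < top_k:
        logger.info("filter_expression: only %d genes survive (top_k=%d)", len(kept), top_k)
    return view_norm.subset_features(kept)


VALID_REGIONS = {"promoter", "enhancer", "body"}
REGION_VIEW_NAMES = {"promoter": "MethPro", "enhancer": "MethEnh", "body": "MethBod"}


def filter_methylation(
    beta_view: OmicsView,
    M_view: OmicsView,
    region_map: pd.Series,
    min_beta_range: float = 0.1,
    top_k: int = 5000,
) -> dict[str, OmicsView]:
    """Split CpGs by region and keep, per region, autosomal CpGs with a
    beta range >= ``min_beta_range``, then the ``top_k`` most variable by
    M value.  Outputs carry M values."""
    if list(beta_view.feature_ids) != list(M_view.feature_ids) or \
            list(beta_view.sample_ids) != list(M_view.sample_ids):
        raise ValueError("beta and M views must be aligned")
    bad = set(region_map.unique()) - VALID_REGIONS
    if bad:
        raise ValueError(f"unknown region labels: {bad}")
    all_cpgs = pd.Index(beta_view.feature_ids)
    unlabeled = all_cpgs.difference(region_map.index)
    if len(unlabeled):
        logger.info("filter_methylation: %d unlabeled CpGs dropped", len(unlabeled))
    labeled = all_cpgs.intersection(region_map.index)
    beta = beta_view.values[labeled]
    rng_ok = (beta.max(axis=0) - beta.min(axis=0)) >= min_beta_range
    auto = _autosomal(beta_view)
    out: dict[str, OmicsView] = {}
    for region, out_name in REGION_VIEW_NAMES.items():
        cpgs = labeled[
            (region_map[labeled] == region).to_numpy()
            & rng_ok[labeled].to_numpy()
        ].intersection(auto)
        kept = _top_k_by_variance(M_view.values[cpgs], top_k)
        sub = M_view.subset_features(kept)
        sub.name = out_name
        out[out_name] = sub
    return out


def gene_level_copy_number(gene_cn: OmicsView, purity_table: PurityTable) -> OmicsView:
    """Mix tumor copy number with diploid normal contamination:
    value(g, s) = purity_s * CN_tumor(g, s) + (1 - purity_s) * 2."""
    missing = [s for s in gene_cn.sample_ids if s not in purity_table.purity.index]
    if missing:
        raise ValueError(f"missing purity for samples: {missing}")
    pur = purity_table.purity.loc[gene_cn.sample_ids].to_numpy()[:, None]
    mixed = pur * gene_cn.values.to_numpy() + (1.0 - pur) * 2.0
    return OmicsView(
        values=pd.DataFrame(mixed, index=gene_cn.values.index, columns=gene_cn.values.columns),
        feature_meta=gene_cn.feature_meta,
        name=gene_cn.name,
    )


def group_and_select_cn(
    cn_view: OmicsView,
    min_altered: int = 3,
    alteration_margin: float = 0.5,
    top_k: int = 5000,
) -> OmicsView:
    """Merge genes with bit-identical profiles, keep features deviating
    from diploid (|value - 2| > margin) in >= ``min_altered`` samples on
    autosomes, then center/scale and keep the ``top_k`` by pre-scaling
    variance."""
    vals = cn_view.values
    auto = _autosomal(cn_view)
    vals = vals[auto]
    meta = cn_view.feature_meta.loc[auto]

    # group identical columns: hash each profile, merge groups
    groups: dict[bytes, list[str]] = {}
    arr = vals.to_numpy()
    for j, f in enumerate(vals.columns):
        key = arr[:, j].tobytes()
        groups.setdefault(key, []).append(f)

    merged_cols, merged_ids, merged_chrom = [], [], []
    for members in groups.values():
        members = sorted(members)
        canon = members[0]
        merged_cols.append(vals[canon].to_numpy())
        merged_ids.append("|".join(members))
        merged_chrom.append(meta.at[canon, "chromosome"])
    merged = pd.DataFrame(
        np.column_stack(merged_cols), index=vals.index, columns=merged_ids
    )

    altered_counts = (np.abs(merged - 2.0) > alteration_margin).sum(axis=0)
    keep = altered_counts[altered_counts >= min_altered].index
    merged = merged[keep]
    chrom = pd.Series(merged_chrom, index=merged_ids)[keep]

    var = merged.var(axis=0, ddof=1)
    zerovar = var[var == 0].index
    if len(zerovar):
        logger.info("group_and_select_cn: dropping %d zero-variance features", len(zerovar))
        merged = merged.drop(columns=zerovar)
        var = var.drop(zerovar)

    kept = sorted(var.index, key=lambda f: (-var[f], f))[: min(top_k, len(var))]
    merged = merged[kept]
    scaled = (merged - merged.mean(axis=0)) / merged.std(axis=0, ddof=1)
    return OmicsView(
        values=scaled,
        feature_meta=pd.DataFrame(
            {"chromosome": chrom[kept].to_numpy(), "kind": "copy_number"}, index=kept
        ),
        name=cn_view.name,
    )


def booleanize_alterations(
    event_table: pd.DataFrame,
    expression_fpkm: OmicsView,
    min_samples: int = 3,
    expression_floor: float = 0.01,
    gene_meta: pd.DataFrame | None = None,
) -> OmicsView:
    """Boolean gene x sample alteration matrix from a (gene, sample) event
    table; genes kept when altered in >= ``min_samples`` samples, autosomal,
    and expressed (max FPKM >= ``expression_floor``).

    ``event_table`` needs columns ``gene_id`` and ``sample_id``; genes
    absent from the expression view are treated as unexpressed.
    """
    samples = expression_fpkm.sample_ids
    if len(event_table):
        unknown = set(event_table["sample_id"]) - set(samples)
        if unknown:
            raise ValueError(f"event table samples absent from expression: {sorted(unknown)[:5]}")
    mat = pd.DataFrame(0, index=samples, columns=[], dtype=int)
    if len(event_table):
        pivot = (
            event_table.assign(v=1)
            .pivot_table(index="sample_id", columns="gene_id", values="v", aggfunc="max", fill_value=0)
            .reindex(index=samples, fill_value=0)
        )
        mat = pivot.astype(int)
    fpkm_max = expression_fpkm.values.max(axis=0)
    meta_src = gene_meta if gene_meta is not None else expression_fpkm.feature_meta
    keep = []
    for g in mat.columns:
        if mat[g].sum() < min_samples:
            continue
        if g in meta_src.index and is_sex_chromosome(meta_src.at[g, "chromosome"]):
            continue
        if g not in fpkm_max.index or fpkm_max[g] < expression_floor:
            continue
        keep.append(g)
    mat = mat[keep]
    chrom = [
        meta_src.at[g, "chromosome"] if g in meta_src.index else "unknown" for g in keep
    ]
    return OmicsView(
        values=mat,
        feature_meta=pd.DataFrame({"chromosome": chrom, "kind": "alteration"}, index=keep),
        name="alterations",
    )


def center_view(view: OmicsView) -> OmicsView:
    """Per-feature centering (no scaling) ahead of factorization."""
    centered = view.values - view.values.mean(axis=0)
    return OmicsView(values=centered, feature_meta=view.feature_meta, name=view.name)
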
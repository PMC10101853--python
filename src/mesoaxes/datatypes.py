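"""Shared containers for the multiomic decomposition pipeline.

A *view* (molecular layer) is a samples x features matrix together with
per-feature metadata (chromosome, value kind).  All downstream stages
operate on :class:`OmicsView` objects so that sample alignment and
feature bookkeeping live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

VALUE_KINDS = {
    "expression_norm",
    "expression_fpkm",
    "meth_beta",
    "meth_M",
    "copy_number",
    "alteration",
}

SEX_CHROMOSOMES = {"X", "Y"}


def normalize_chromosome(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so 'chrX' and 'X' compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def is_sex_chromosome(chrom: str) -> bool:
    return normalize_chromosome(chrom).upper() in SEX_CHROMOSOMES


@dataclass
class OmicsView:
    """One molecular layer: samples x features values plus feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are feature ids.
    feature_meta
        DataFrame indexed by feature id with at least columns
        ``chromosome`` and ``kind`` (one of :data:`VALUE_KINDS`).
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    name: str = "view"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        missing = self.values.columns.difference(self.feature_meta.index)
        if len(missing):
            raise ValueError(f"features without metadata: {list(missing[:5])}")
        self.feature_meta = self.feature_meta.loc[self.values.columns]
        kinds = set(self.feature_meta["kind"].unique())
        unknown = kinds - VALUE_KINDS
        if unknown:
            raise ValueError(f"unknown value kinds: {unknown}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids) -> "OmicsView":
        return OmicsView(
            values=self.values[list(feature_ids)],
            feature_meta=self.feature_meta.loc[list(feature_ids)],
            name=self.name,
        )


@dataclass
class PurityTable:
    """Per-sample tumor purity (fraction of tumor cells) and ploidy."""

    purity: pd.Series
    ploidy: pd.Series

    def __post_init__(self) -> None:
        if ((self.purity <= 0) | (self.purity > 1)).any():
            raise ValueError("purity must lie in (0, 1]")
        if (self.ploidy <= 0).any():
            raise ValueError("ploidy must be positive")


@dataclass
class FactorModel:
    """Fitted shared-factor multi-view linear model.

    ``Z`` holds per-sample factor scores (samples x K); ``W`` maps view
    name to its features x K loading matrix; ``r2`` is the view x factor
    matrix of variance-explained fractions.
    """

    Z: pd.DataFrame
    W: dict[str, pd.DataFrame]
    sigma2: dict[str, float]
    r2: pd.DataFrame
    iterations: int
    converged: bool
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_factors(self) -> int:
        return self.Z.shape[1]


@dataclass
class CIMPResult:
    """Island-level mean betas and the per-sample CIMP index."""

    island_beta: pd.DataFrame
    cimp_index: pd.Series
    threshold: float


@dataclass
class ArchetypeFit:
    """Principal-convex-hull (archetypal analysis) fit on factor coordinates."""

    X: np.ndarray
    k: int
    archetypes: np.ndarray
    A: np.ndarray  # samples x k convex weights (rows on the simplex)
    B: np.ndarray  # k x samples convex weights defining archetypes from data
    sse: float
    var_expl: float
    t_ratio: Optional[float] = None
    fit_p: Optional[float] = None
    bootstrap_sd: Optional[np.ndarray] = None
    iterations: int = 0
    converged: bool = False
    sample_ids: Optional[list[str]] = None
    sse_trace: Optional[np.ndarray] = None


@dataclass
class EffectVector:
    """Centroid displacement of alteration carriers on the factor plane."""

    alteration: str
    vector: np.ndarray
    n_altered: int
    n_wildtype: int
    anova_p: float
    q: Optional[float] = None

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass
class SurvivalResult:
    """Cox proportional-hazards association summary."""

    summary: pd.DataFrame  # per-covariate: coef, hr, hr_lower, hr_upper, wald_p
    logrank_p: float
    concordance: float
    n_used: int
    n_dropped: int
    converged: bool = True
    auc: Optional[float] = None
    horizon: Optional[float] = None
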
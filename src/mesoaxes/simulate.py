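"""Synthetic multiomic cohort generator with planted four-factor structure.

Emulates the qualitative features of a pleural-mesothelioma multiomic
cohort: samples form continuous gradients (not clusters) between extreme
molecular profiles; two of the latent dimensions place samples inside a
triangle (mixtures of three archetypal profiles); one latent dimension
drives tumor ploidy from near-haploid to near-tetraploid; one drives a
bimodal CpG-island methylator phenotype (CIMP); Boolean gene alterations
displace carriers on the triangle; and survival follows proportional
hazards in the latent factors.

All randomness flows from a single seed through named, independent
streams, so each stage is reproducible when run standalone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OmicsView

# Stable stream indices: the global seed spawns one child per stage, so
# regenerating a single layer never perturbs the others.
_STREAMS = {
    "factors": 0,
    "expression": 1,
    "methylation": 2,
    "copy_number": 3,
    "alterations": 4,
    "survival": 5,
    "clinical": 6,
}

DEFAULT_TRIANGLE = ((0.0, 0.0), (4.0, 0.0), (2.0, 3.5))


@dataclass
class AlterationSpec:
    name: str
    prevalence: float
    displacement: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the conditions used throughout the test suite and the
    reproduction script: 120 samples, four latent factors, a triangle
    with vertices (0,0), (4,0), (2,3.5) filled by Dirichlet(0.5)
    mixtures, ploidy = 2 + 0.8 z1 + N(0, 0.2), 2,000 CpG islands of 5
    CpGs with logistic slope 4 on the CIMP factor, three alterations at
    prevalence 0.3 with displacement norm 0.8, and exponential
    proportional-hazards survival with ~30% uniform censoring.
    """

    n_samples: int = 120
    n_true_factors: int = 4
    features_per_view: dict = field(
        default_factory=lambda: {
            "expression": 6000,
            "meth_promoter": 4000,
            "meth_body": 3000,
            "meth_enhancer": 3000,
            "copy_number": 6000,
        }
    )
    loading_sparsity: float = 0.8
    noise_sd_per_view: dict = field(
        default_factory=lambda: {"expression": 0.5, "methylation": 0.02}
    )
    cpg_scatter_sd: float = 0.05
    dirichlet_alpha: float = 0.5
    triangle_vertices: tuple = DEFAULT_TRIANGLE
    ploidy_coupling: tuple[float, float] = (0.8, 0.2)  # (slope a, noise sd)
    cimp_coupling: tuple[float, int, int] = (4.0, 2000, 5)  # (slope b, islands, cpgs/island)
    alteration_specs: list = field(
        default_factory=lambda: [
            AlterationSpec("ALT1", 0.3, (0.8, 0.0)),
            AlterationSpec("ALT2", 0.3, (-0.4, 0.6928203230275509)),
            AlterationSpec("ALT3", 0.3, (-0.4, -0.6928203230275509)),
        ]
    )
    survival_coefs: tuple = (0.5, -0.4, -0.4, 0.3)
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.3
    purity_range: tuple[float, float] = (0.3, 0.95)
    cn_block_size: int = 50
    cn_block_alter_prob: float = 0.05
    marker_set_size: int = 15
    n_silenced_genes: int = 5
    marker_strength: float = 2.0
    sex_gene_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_true_factors <= 0:
            raise ValueError("counts must be positive")
        if self.dirichlet_alpha <= 0:
            raise ValueError(f"dirichlet_alpha must be > 0, got {self.dirichlet_alpha}")
        if not 0.0 <= self.loading_sparsity <= 1.0:
            raise ValueError("loading_sparsity must lie in [0,1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if len(self.triangle_vertices) != 3:
            raise ValueError("triangle_vertices must contain exactly 3 points")
        specs = []
        for s in self.alteration_specs:
            if isinstance(s, AlterationSpec):
                specs.append(s)
            else:
                specs.append(AlterationSpec(*s))
        self.alteration_specs = specs
        b, n_isl, n_cpg = self.cimp_coupling
        n_meth = sum(
            v for k, v in self.features_per_view.items() if k.startswith("meth_")
        )
        if n_isl * n_cpg != n_meth:
            raise ValueError(
                f"island count x cpgs per island ({n_isl}x{n_cpg}) must equal the "
                f"total methylation feature count ({n_meth})"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth for downstream parameter-recovery tests."""

    Z_true: pd.DataFrame
    archetype_weights_true: pd.DataFrame
    positions_true: pd.DataFrame  # raw 2-D triangle coordinates
    ploidy_true: pd.Series
    cimp_true: pd.Series | None = None
    alteration_matrix: pd.DataFrame | None = None
    survival_time: pd.Series | None = None
    survival_event: pd.Series | None = None


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def generate_factors(config: GeneratorConfig):
    """Draw the planted latent factors.

    Factor 1 is a standardized latent driving ploidy (2 + a z1 + noise,
    clipped to the haploid-to-tetraploid range [1, 4.5]).  Factors 2-3
    are the centered/scaled coordinates of Dirichlet mixtures of the
    triangle vertices, so samples fill the triangle rather than forming
    clusters.  Factor 4 is a standardized latent driving island
    methylation (the CIMP axis).

    Returns
    -------
    (Z_true, ploidy_true, archetype_weights_true, positions_true)
    """
    rng = config.rng("factors")
    n = config.n_samples
    ids = _sample_ids(n)

    z1 = rng.standard_normal(n)
    z1 = (z1 - z1.mean()) / z1.std()

    weights = rng.dirichlet([config.dirichlet_alpha] * 3, size=n)
    verts = np.asarray(config.triangle_vertices, dtype=float)
    pos = weights @ verts  # n x 2 inside the closed triangle
    z23 = (pos - pos.mean(axis=0)) / pos.std(axis=0)

    z4 = rng.standard_normal(n)
    z4 = (z4 - z4.mean()) / z4.std()

    a, sd = config.ploidy_coupling
    ploidy = 2.0 + a * z1 + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    ploidy = np.clip(ploidy, 1.0, 4.5)

    Z = pd.DataFrame(
        np.column_stack([z1, z23[:, 0], z23[:, 1], z4]),
        index=ids,
        columns=["z1", "z2", "z3", "z4"],
    )
    return (
        Z,
        pd.Series(ploidy, index=ids, name="ploidy"),
        pd.DataFrame(weights, index=ids, columns=["A1", "A2", "A3"]),
        pd.DataFrame(pos, index=ids, columns=["x", "y"]),
    )


def _gene_chromosomes(rng: np.random.Generator, n_genes: int, sex_fraction: float,
                      marker_idx: np.ndarray) -> np.ndarray:
    """Assign chromosomes; planted marker genes stay autosomal so the
    sex-chromosome filter cannot remove them."""
    chroms = rng.choice([f"chr{i}" for i in range(1, 23)], size=n_genes)
    n_sex = max(int(round(sex_fraction * n_genes)), 1)
    candidates = np.setdiff1d(np.arange(n_genes), marker_idx)
    sex_idx = rng.choice(candidates, size=n_sex, replace=False)
    chroms[sex_idx] = rng.choice(["chrX", "chrY"], size=n_sex)
    return chroms


def generate_expression(Z_true: pd.DataFrame, config: GeneratorConfig):
    """Linear-Gaussian expression layer with planted marker sets.

    expression = Z W^T + noise with sparse loadings.  Designated marker
    sets carry interpretable signal: an adaptive-immune set loads
    positively on factor 3, an innate set negatively, a proliferation
    set on factor 2, and >= 5 "silenced" genes decrease with factor 4
    (CIMP-associated silencing).

    Returns ``(norm_view, fpkm_view, marker_sets)`` where marker_sets maps
    set name -> list of gene ids.
    """
    if not 0.0 <= config.loading_sparsity <= 1.0:
        raise ValueError("loading sparsity outside [0,1]")
    rng = config.rng("expression")
    n, k = Z_true.shape
    p = config.features_per_view["expression"]
    genes = [f"G{j:05d}" for j in range(p)]

    W = rng.standard_normal((p, k))
    mask = rng.random((p, k)) < (1.0 - config.loading_sparsity)
    W = W * mask

    m = config.marker_set_size
    s = config.n_silenced_genes
    blocks = {
        "proliferation": np.arange(0, m),
        "adaptive": np.arange(m, 2 * m),
        "innate": np.arange(2 * m, 3 * m),
        "silenced": np.arange(3 * m, 3 * m + s),
    }
    str_ = config.marker_strength
    W[blocks["proliferation"], :] = 0.0
    W[blocks["proliferation"], 1] = str_ * (1.0 + 0.2 * rng.standard_normal(m))
    W[blocks["adaptive"], :] = 0.0
    W[blocks["adaptive"], 2] = str_ * (1.0 + 0.2 * rng.standard_normal(m))
    W[blocks["innate"], :] = 0.0
    W[blocks["innate"], 2] = -str_ * (1.0 + 0.2 * rng.standard_normal(m))
    W[blocks["silenced"], :] = 0.0
    W[blocks["silenced"], 3] = -str_ * (1.0 + 0.2 * rng.standard_normal(s))

    noise_sd = config.noise_sd_per_view.get("expression", 0.5)
    Y = Z_true.to_numpy() @ W.T
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, size=(n, p))

    marker_idx = np.concatenate(list(blocks.values()))
    chroms = _gene_chromosomes(rng, p, config.sex_gene_fraction, marker_idx)

    values = pd.DataFrame(Y, index=Z_true.index, columns=genes)
    meta = pd.DataFrame(
        {"chromosome": chroms, "kind": "expression_norm"}, index=genes
    )
    norm_view = OmicsView(values=values, feature_meta=meta, name="expression")

    # FPKM companion: positive-scale version of the same signal, used only
    # by the range filter and the alteration expression floor.
    fpkm = np.exp(0.5 * Y + rng.normal(1.0, 0.5, size=p))
    fpkm_view = OmicsView(
        values=pd.DataFrame(fpkm, index=Z_true.index, columns=genes),
        feature_meta=meta.assign(kind="expression_fpkm"),
        name="expression_fpkm",
    )
    marker_sets = {name: [genes[i] for i in idx] for name, idx in blocks.items()}
    return norm_view, fpkm_view, marker_sets


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_methylation(Z_true: pd.DataFrame, config: GeneratorConfig):
    """Island-structured methylation coupled to the CIMP factor.

    Island mean beta = logistic(c_i + b z4) + noise, truncated to [0,1];
    CpG betas scatter around their island mean.  M values are
    log2(beta/(1-beta)) with beta clipped away from {0,1}.

    Returns ``(beta_view, m_view, island_map, region_map, cimp_true)``.
    ``island_map`` maps island_id -> list of cpg ids; ``region_map`` is a
    Series cpg_id -> region in {promoter, body, enhancer}.
    """
    rng = config.rng("methylation")
    b, n_islands, cpgs_per_island = config.cimp_coupling
    n = Z_true.shape[0]
    z4 = Z_true.to_numpy()[:, 3]

    # Island baselines: wide spread relative to the coupling slope keeps the
    # cohort-level island *fraction* near-linear in z4 while each island's
    # beta profile across samples stays bimodal (CIMP-low vs CIMP-high).
    c = rng.normal(-2.0, 4.0, size=n_islands)
    noise_sd = config.noise_sd_per_view.get("methylation", 0.02)
    island_mean = _logistic(c[None, :] + b * z4[:, None])
    if noise_sd > 0:
        island_mean = island_mean + rng.normal(0.0, noise_sd, size=island_mean.shape)
    island_mean = np.clip(island_mean, 0.0, 1.0)  # truncate, do not resample

    cpg_ids, island_map, regions = [], {}, []
    region_cycle = []
    for reg, cnt in (
        ("promoter", config.features_per_view.get("meth_promoter", 0)),
        ("body", config.features_per_view.get("meth_body", 0)),
        ("enhancer", config.features_per_view.get("meth_enhancer", 0)),
    ):
        region_cycle.extend([reg] * (cnt // cpgs_per_island))
    for i in range(n_islands):
        ids = [f"cg{i:05d}_{j}" for j in range(cpgs_per_island)]
        island_map[f"isl{i:05d}"] = ids
        cpg_ids.extend(ids)
        regions.extend([region_cycle[i]] * cpgs_per_island)

    beta = np.repeat(island_mean, cpgs_per_island, axis=1)
    if config.cpg_scatter_sd > 0:
        beta = beta + rng.normal(0.0, config.cpg_scatter_sd, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)
    if (beta < 0).any() or (beta > 1).any():  # pragma: no cover
        raise RuntimeError("beta outside [0,1] after truncation")

    beta_clip = np.clip(beta, 1e-6, 1.0 - 1e-6)
    M = np.log2(beta_clip / (1.0 - beta_clip))

    # Sex-chromosome CpGs: a small tail of islands sits on chrX/chrY.
    n_sex_islands = max(int(round(config.sex_gene_fraction * n_islands)), 1)
    island_chrom = np.array([f"chr{(i % 22) + 1}" for i in range(n_islands)], dtype=object)
    island_chrom[-n_sex_islands:] = "chrX"
    cpg_chrom = np.repeat(island_chrom, cpgs_per_island)

    meta_beta = pd.DataFrame(
        {"chromosome": cpg_chrom, "kind": "meth_beta"}, index=cpg_ids
    )
    beta_view = OmicsView(
        values=pd.DataFrame(beta, index=Z_true.index, columns=cpg_ids),
        feature_meta=meta_beta,
        name="methylation_beta",
    )
    m_view = OmicsView(
        values=pd.DataFrame(M, index=Z_true.index, columns=cpg_ids),
        feature_meta=meta_beta.assign(kind="meth_M"),
        name="methylation_M",
    )
    region_map = pd.Series(regions, index=cpg_ids, name="region")
    cimp_true = pd.Series(
        (island_mean >= 0.3).mean(axis=1), index=Z_true.index, name="cimp_true"
    )
    return beta_view, m_view, island_map, region_map, cimp_true


def island_bed(island_map: dict, cpgs_per_island: int | None = None) -> pd.DataFrame:
    """Genomic intervals for the islands (synthetic coordinates, 0-based
    half-open), suitable for BED export."""
    rows = []
    for i, (isl, cpgs) in enumerate(island_map.items()):
        start = 1000 * i
        rows.append(("chr%d" % ((i % 22) + 1), start, start + 500, isl))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "island_id"])


def generate_copy_number(ploidy_true: pd.Series, config: GeneratorConfig):
    """Gene-level tumor copy number with segment-structured deviations.

    Each sample's baseline copy number is its ploidy; contiguous blocks
    of genes (segments) share sporadic integer deviations.  Genes within
    one segment have identical profiles, as in segment-level CN calls.
    Purity is Uniform over ``config.purity_range``.
    """
    rng = config.rng("copy_number")
    n = len(ploidy_true)
    p = config.features_per_view["copy_number"]
    bs = config.cn_block_size
    n_blocks = int(np.ceil(p / bs))
    genes = [f"CN{j:05d}" for j in range(p)]

    dev_block = np.zeros((n, n_blocks))
    hit = rng.random((n, n_blocks)) < config.cn_block_alter_prob
    signs = rng.choice([-1.0, 1.0], size=(n, n_blocks))
    sizes = rng.choice([1.0, 2.0], size=(n, n_blocks), p=[0.8, 0.2])
    dev_block[hit] = (signs * sizes)[hit]

    cn = ploidy_true.to_numpy()[:, None] + np.repeat(dev_block, bs, axis=1)[:, :p]
    cn = np.maximum(cn, 0.0)

    block_of_gene = np.arange(p) // bs
    chroms = np.array([f"chr{(bk % 22) + 1}" for bk in block_of_gene], dtype=object)
    n_sex_blocks = max(int(round(config.sex_gene_fraction * n_blocks)), 1)
    chroms[block_of_gene >= n_blocks - n_sex_blocks] = "chrY"

    view = OmicsView(
        values=pd.DataFrame(cn, index=ploidy_true.index, columns=genes),
        feature_meta=pd.DataFrame({"chromosome": chroms, "kind": "copy_number"}, index=genes),
        name="copy_number",
    )
    lo, hi = config.purity_range
    purity = pd.Series(rng.uniform(lo, hi, size=n), index=ploidy_true.index, name="purity")
    return view, purity


def generate_alterations(
    archetype_weights_true: pd.DataFrame,
    config: GeneratorConfig,
    positions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Boolean alteration matrix whose carriers are displaced on the triangle.

    For each alteration, carrier probability is a linear tilt of the
    marginal prevalence along the planted displacement direction,
    p_i = prev + prev(1-prev) (x_i - mean)^T Sigma^{-1} d (clipped to
    [0,1]), so the expected carrier-centroid minus wildtype-centroid
    difference equals the planted displacement exactly.
    """
    rng = config.rng("alterations")
    verts = np.asarray(config.triangle_vertices, dtype=float)
    if positions is None:
        positions = pd.DataFrame(
            archetype_weights_true.to_numpy() @ verts,
            index=archetype_weights_true.index,
            columns=["x", "y"],
        )
    X = positions.to_numpy()
    n = X.shape[0]
    mu = X.mean(axis=0)
    Sigma = np.cov(X.T)
    Sigma_inv = np.linalg.pinv(Sigma)

    cols = {}
    for spec in config.alteration_specs:
        d = np.asarray(spec.displacement, dtype=float)
        q = spec.prevalence
        tilt = q * (1.0 - q) * (X - mu) @ (Sigma_inv @ d)
        prob = np.clip(q + tilt, 0.0, 1.0)
        # re-center after clipping so marginal prevalence stays on target
        prob = np.clip(prob + (q - prob.mean()), 0.0, 1.0)
        carriers = rng.random(n) < prob
        if q * n < 3:
            warnings.warn(
                f"alteration {spec.name}: fewer than 3 expected carriers; "
                "downstream filters will drop it"
            )
        cols[spec.name] = carriers.astype(int)
    return pd.DataFrame(cols, index=positions.index)


def generate_survival(Z_true: pd.DataFrame, config: GeneratorConfig):
    """Exponential proportional-hazards survival times with uniform censoring.

    hazard_i = baseline * exp(sum_k beta_k z_ik).  Censoring times are
    Uniform(0, c_max) with c_max solved (bisection on the realized event
    times) so the expected censored fraction matches
    ``config.censoring_rate``.
    """
    coefs = np.asarray(config.survival_coefs, dtype=float)
    if coefs.shape[0] != Z_true.shape[1]:
        raise ValueError("one survival coefficient per factor required")
    rng = config.rng("survival")
    n = Z_true.shape[0]
    hazard = config.baseline_hazard * np.exp(Z_true.to_numpy() @ coefs)
    T = rng.exponential(1.0, size=n) / hazard

    rate = config.censoring_rate
    if rate <= 0:
        time, event = T, np.ones(n, dtype=int)
    else:
        # P(C < T) with C ~ U(0, c) is E[min(T, c)] / c; bisect on c.
        def censored_frac(c):
            return np.minimum(T, c).mean() / c

        lo, hi = T.min() * 1e-3, T.max() * 100
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_frac(mid) > rate:
                lo = mid
            else:
                hi = mid
        C = rng.uniform(0.0, 0.5 * (lo + hi), size=n)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    return (
        pd.Series(time, index=Z_true.index, name="time"),
        pd.Series(event, index=Z_true.index, name="event"),
    )


def generate_clinical(
    archetype_weights_true: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Clinical table: histotype driven by the dominant archetype,
    % sarcomatoid component tracking archetype 1 weight."""
    rng = config.rng("clinical")
    W = archetype_weights_true.to_numpy()
    histo_names = np.array(["sarcomatoid", "epithelioid", "biphasic"])
    # noisy argmax: mostly the dominant archetype's label
    noisy = W + rng.normal(0, 0.15, size=W.shape)
    histotype = histo_names[np.argmax(noisy, axis=1)]
    sarc = np.clip(100 * W[:, 0] + rng.normal(0, 5, size=W.shape[0]), 0, 100)
    return pd.DataFrame(
        {
            "histotype": histotype,
            "sarcomatoid_pct": sarc,
            "time_months": time,
            "event": event,
        },
        index=archetype_weights_true.index,
    )


@dataclass
class SyntheticDataset:
    """Bundle of all generated layers plus the planted truth."""

    expression: OmicsView
    expression_fpkm: OmicsView
    meth_beta: OmicsView
    meth_M: OmicsView
    island_map: dict
    region_map: pd.Series
    copy_number: OmicsView
    purity: pd.Series
    alterations: pd.DataFrame
    clinical: pd.DataFrame
    marker_sets: dict
    truth: SyntheticTruth


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Run every generator stage under one config and bundle the results."""
    config = config or GeneratorConfig()
    Z, ploidy, weights, pos = generate_factors(config)
    expr, fpkm, marker_sets = generate_expression(Z, config)
    beta, M, island_map, region_map, cimp_true = generate_methylation(Z, config)
    cn, purity = generate_copy_number(ploidy, config)
    alts = generate_alterations(weights, config, positions=pos)
    time, event = generate_survival(Z, config)
    clinical = generate_clinical(weights, time, event, config)
    truth = SyntheticTruth(
        Z_true=Z,
        archetype_weights_true=weights,
        positions_true=pos,
        ploidy_true=ploidy,
        cimp_true=cimp_true,
        alteration_matrix=alts,
        survival_time=time,
        survival_event=event,
    )
    return SyntheticDataset(
        expression=expr,
        expression_fpkm=fpkm,
        meth_beta=beta,
        meth_M=M,
        island_map=island_map,
        region_map=region_map,
        copy_number=cn,
        purity=purity,
        alterations=alts,
        clinical=clinical,
        marker_sets=marker_sets,
        truth=truth,
    )
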
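"""End-to-end orchestration: simulate -> preprocess -> factorize -> cimp
-> pareto -> interpret -> survival, with a machine-readable manifest.

Every stage reads and writes plain-text artifacts under the run
directory, so stages can be re-run standalone; all randomness flows from
the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cimp as cimp_mod
from . import factor as factor_mod
from . import interpret as interpret_mod
from . import io as io_mod
from . import pareto as pareto_mod
from . import preprocess as pre_mod
from . import survival as surv_mod
from .datatypes import PurityTable
from .simulate import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "factorize", "cimp", "pareto", "interpret", "survival"]

DEFAULT_PARAMS = {
    "K": 10,
    "top_k": 5000,
    "beta_threshold": 0.3,
    "n_boot": 200,
    "boot_frac": 0.75,
    "n_perm": 999,
    "q_threshold": 0.05,
    "factor_r2_threshold": 0.10,
    "k_archetypes": 3,
    "min_fpkm_range": 1.0,
    "min_beta_range": 0.1,
    "min_altered": 3,
}

_KNOWN_KEYS = {"stages", "out_dir", "seed", "params", "generator"}


def _param_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {
        "stages": config.get("stages", list(STAGES)),
        "out_dir": config.get("out_dir", "mesoaxes_run"),
        "seed": int(config.get("seed", 0)),
        "params": {**DEFAULT_PARAMS, **config.get("params", {})},
        "generator": config.get("generator", {}),
    }
    bad_stage = set(cfg["stages"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stages: {sorted(bad_stage)}")
    bad_param = set(cfg["params"]) - set(DEFAULT_PARAMS)
    if bad_param:
        raise ValueError(f"unknown params: {sorted(bad_param)}")
    return cfg


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input for stage: {what} ({path})")
    return path


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    Returns the manifest dict; raises on the first stage failure.
    """
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    params = cfg["params"]
    seed = cfg["seed"]
    manifest = {
        "seed": seed,
        "param_hash": _param_hash(params),
        "params": params,
        "stages": [],
    }
    stages = [s for s in STAGES if s in cfg["stages"]]
    state: dict = {}

    for stage in stages:
        t0 = _time.time()
        logger.info("stage %s start (seed=%d)", stage, seed)
        outputs = _STAGE_FUNCS[stage](out, cfg, state)
        rec = {
            "stage": stage,
            "outputs": sorted(outputs),
            "seconds": round(_time.time() - t0, 3),
            "status": "ok",
        }
        manifest["stages"].append(rec)
        logger.info("stage %s done in %.1fs", stage, rec["seconds"])

    io_mod.write_json(out / "manifest.json", manifest)
    return manifest


def _stage_simulate(out: Path, cfg: dict, state: dict) -> list[str]:
    gen_cfg = GeneratorConfig(seed=cfg["seed"], **cfg["generator"])
    ds = generate_dataset(gen_cfg)
    state["dataset"] = ds
    io_mod.write_view(out / "expression.tsv", ds.expression)
    io_mod.write_view(out / "expression_fpkm.tsv", ds.expression_fpkm)
    io_mod.write_view(out / "meth_beta.tsv", ds.meth_beta)
    io_mod.write_view(out / "meth_M.tsv", ds.meth_M)
    io_mod.write_view(out / "copy_number.tsv", ds.copy_number)
    io_mod.write_island_map(out / "island_map.tsv", ds.island_map)
    from .simulate import island_bed

    io_mod.write_island_bed(out / "islands.bed", island_bed(ds.island_map))
    ds.region_map.to_frame().to_csv(out / "region_map.tsv", sep="\t", index_label="cpg_id")
    ds.alterations.to_csv(out / "alterations.tsv", sep="\t", index_label="sample_id")
    clin = ds.clinical.copy()
    clin.to_csv(out / "clinical.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame({"purity": ds.purity, "ploidy": ds.truth.ploidy_true}).to_csv(
        out / "purity.tsv", sep="\t", index_label="sample_id"
    )
    truth = pd.concat(
        [ds.truth.Z_true, ds.truth.archetype_weights_true, ds.truth.positions_true,
         ds.truth.ploidy_true, ds.truth.cimp_true], axis=1
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index_label="sample_id")
    io_mod.write_gmt(out / "marker_sets.gmt", ds.marker_sets)
    return [p.name for p in out.iterdir() if p.is_file()]


def _stage_preprocess(out: Path, cfg: dict, state: dict) -> list[str]:
    ds = state.get("dataset")
    if ds is None:
        raise FileNotFoundError("missing input for stage: preprocess (simulate outputs)")
    p = cfg["params"]
    expr = pre_mod.filter_expression(
        ds.expression, ds.expression_fpkm,
        min_fpkm_range=p["min_fpkm_range"], top_k=p["top_k"],
    )
    meth = pre_mod.filter_methylation(
        ds.meth_beta, ds.meth_M, ds.region_map,
        min_beta_range=p["min_beta_range"], top_k=p["top_k"],
    )
    cn_adj = pre_mod.gene_level_copy_number(
        ds.copy_number, PurityTable(purity=ds.purity, ploidy=ds.truth.ploidy_true)
    )
    cn = pre_mod.group_and_select_cn(cn_adj, min_altered=p["min_altered"], top_k=p["top_k"])
    views = {"expression": expr, **meth, "copy_number": cn}
    state["views"] = views
    written = []
    for name, v in views.items():
        centered = pre_mod.center_view(v) if name != "copy_number" else v
        io_mod.write_view(out / f"view_{name}.tsv", centered)
        written.append(f"view_{name}.tsv")
        state.setdefault("centered_views", {})[name] = centered
    return written


def _stage_factorize(out: Path, cfg: dict, state: dict) -> list[str]:
    views = state.get("centered_views")
    if views is None:
        raise FileNotFoundError("missing input for stage: factorize (preprocess outputs)")
    p = cfg["params"]
    model = factor_mod.fit_multiview_factors(views, K=p["K"], seed=cfg["seed"])
    state["model"] = model
    io_mod.write_matrix(out / "factors_Z.tsv", model.Z)
    model.r2.to_csv(out / "factors_r2.tsv", sep="\t", index_label="view")
    selected = factor_mod.select_major_factors(model, threshold=p["factor_r2_threshold"])
    state["selected_factors"] = selected
    io_mod.write_json(out / "factor_model.json", {
        "iterations": model.iterations,
        "converged": bool(model.converged),
        "selected_factors": selected,
        "sigma2": model.sigma2,
    })
    return ["factors_Z.tsv", "factors_r2.tsv", "factor_model.json"]


def _stage_cimp(out: Path, cfg: dict, state: dict) -> list[str]:
    ds = state.get("dataset")
    if ds is None:
        raise FileNotFoundError("missing input for stage: cimp (simulate outputs)")
    res = cimp_mod.compute_cimp(ds.meth_beta, ds.island_map,
                                threshold=cfg["params"]["beta_threshold"])
    state["cimp"] = res
    res.cimp_index.to_frame().to_csv(out / "cimp_index.tsv", sep="\t", index_label="sample_id")
    return ["cimp_index.tsv"]


def _stage_pareto(out: Path, cfg: dict, state: dict) -> list[str]:
    model = state.get("model")
    if model is None:
        raise FileNotFoundError("missing input for stage: pareto (factorize outputs)")
    p = cfg["params"]
    selected = state.get("selected_factors") or list(model.Z.columns[:4])
    use = selected[: max(2, min(len(selected), 4))]
    names = pareto_mod.ordered_factor_names(model, "expression", use)
    X = model.Z[names[:2]].to_numpy(dtype=float)  # triangle lives on the top-2 axes
    fit = pareto_mod.fit_archetypes(X, k=p["k_archetypes"], seed=cfg["seed"])
    fit_p, obs, _ = pareto_mod.fit_significance(
        X, k=p["k_archetypes"], n_perm=p["n_perm"], seed=cfg["seed"]
    )
    fit.fit_p = fit_p
    _, sd, _ = pareto_mod.bootstrap_archetypes(
        X, k=p["k_archetypes"], n_boot=p["n_boot"], frac=p["boot_frac"],
        seed=cfg["seed"], reference=fit,
    )
    fit.bootstrap_sd = sd
    state["pareto_fit"] = fit
    state["pareto_coords"] = X
    np.savetxt(out / "archetypes.tsv", fit.archetypes, delimiter="\t")
    props = pd.DataFrame(
        fit.A, index=model.Z.index, columns=[f"archetype_{j+1}" for j in range(fit.k)]
    )
    props.to_csv(out / "archetype_proportions.tsv", sep="\t", index_label="sample_id")
    state["proportions"] = props
    io_mod.write_json(out / "pareto_fit.json", {
        "sse": fit.sse, "var_expl": fit.var_expl, "t_ratio": fit.t_ratio,
        "fit_p": fit.fit_p, "bootstrap_sd": fit.bootstrap_sd,
        "axes": names[:2],
    })
    return ["archetypes.tsv", "archetype_proportions.tsv", "pareto_fit.json"]


def _stage_interpret(out: Path, cfg: dict, state: dict) -> list[str]:
    ds = state.get("dataset")
    coords = state.get("pareto_coords")
    if ds is None or coords is None:
        raise FileNotFoundError("missing input for stage: interpret (pareto outputs)")
    p = cfg["params"]
    vectors = interpret_mod.effect_vectors(coords, ds.alterations)
    gp, obs, _ = interpret_mod.global_specialization_test(
        coords, ds.alterations, n_perm=p["n_perm"], seed=cfg["seed"]
    )
    tab = pd.DataFrame(
        [
            {
                "alteration": e.alteration,
                "dx": e.vector[0], "dy": e.vector[1], "norm": e.norm,
                "n_altered": e.n_altered, "n_wildtype": e.n_wildtype,
                "anova_p": e.anova_p, "q": e.q,
            }
            for e in vectors
        ]
    )
    tab.to_csv(out / "effect_vectors.tsv", sep="\t", index=False)
    io_mod.write_json(out / "specialization_test.json",
                      {"p": gp, "observed_mean_norm": obs})
    return ["effect_vectors.tsv", "specialization_test.json"]


def _stage_survival(out: Path, cfg: dict, state: dict) -> list[str]:
    ds = state.get("dataset")
    model = state.get("model")
    if ds is None or model is None:
        raise FileNotFoundError("missing input for stage: survival (factorize outputs)")
    selected = state.get("selected_factors") or list(model.Z.columns[:4])
    covs = model.Z[selected]
    res = surv_mod.cox_association(covs, ds.clinical["time_months"], ds.clinical["event"])
    res.summary.to_csv(out / "survival_cox.tsv", sep="\t", index_label="covariate")
    io_mod.write_json(out / "survival_model.json", {
        "logrank_p": res.logrank_p, "concordance": res.concordance,
        "n_used": res.n_used, "converged": bool(res.converged),
    })
    return ["survival_cox.tsv", "survival_model.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "factorize": _stage_factorize,
    "cimp": _stage_cimp,
    "pareto": _stage_pareto,
    "interpret": _stage_interpret,
    "survival": _stage_survival,
}
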
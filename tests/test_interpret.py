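"""Archetype interpretation: gene correlations, ordered-hypergeometric
enrichment (with a closed-form oracle), covariate associations, effect
vectors and the global specialization permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mesoaxes.datatypes import OmicsView
from mesoaxes.interpret import (
    archetype_covariate_association,
    correlate_features_with_archetypes,
    effect_vectors,
    enrich_gene_sets,
    global_specialization_test,
)


def expr_view(arr, samples=None, genes=None):
    genes = genes or [f"g{j}" for j in range(arr.shape[1])]
    vals = pd.DataFrame(arr, index=samples or [f"s{i}" for i in range(arr.shape[0])],
                        columns=genes)
    return OmicsView(values=vals, feature_meta=pd.DataFrame(
        {"chromosome": "chr1", "kind": "expression_norm"}, index=genes))


class TestGeneCorrelation:
    def test_gene_equal_to_proportion_r_one(self, rng):
        props = pd.DataFrame(rng.dirichlet([1, 1, 1], 50),
                             index=[f"s{i}" for i in range(50)],
                             columns=["A1", "A2", "A3"])
        arr = rng.standard_normal((50, 3))
        arr[:, 0] = props["A1"]
        ev = expr_view(arr)
        out = correlate_features_with_archetypes(ev, props)
        assert out["A1"].loc["g0", "r"] == pytest.approx(1.0)

    def test_matches_scipy_pearsonr(self, rng):
        props = pd.DataFrame(rng.dirichlet([1, 1, 1], 40),
                             index=[f"s{i}" for i in range(40)],
                             columns=["A1", "A2", "A3"])
        ev = expr_view(rng.standard_normal((40, 10)))
        out = correlate_features_with_archetypes(ev, props)
        for g in ["g0", "g5"]:
            r, p = stats.pearsonr(ev.values[g], props["A2"])
            assert out["A2"].loc[g, "r"] == pytest.approx(r, abs=1e-10)
            assert out["A2"].loc[g, "p"] == pytest.approx(p, rel=1e-6)

    def test_independent_gene_small_r(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            props = pd.DataFrame(rng.dirichlet([1, 1, 1], 200),
                                 index=[f"s{i}" for i in range(200)],
                                 columns=["A1", "A2", "A3"])
            ev = expr_view(rng.standard_normal((200, 1)))
            out = correlate_features_with_archetypes(ev, props)
            hits += abs(out["A1"].loc["g0", "r"]) < 0.2
        assert hits >= 18


class TestEnrichment:
    def _stats(self, rng, n=1000):
        return pd.DataFrame({
            "r": rng.uniform(0.01, 1.0, n),
            "p": rng.uniform(0, 1, n),
        }, index=[f"g{j:04d}" for j in range(n)])

    def test_top_block_set_extreme_min_p(self, rng):
        gs = self._stats(rng)
        ranked = gs.sort_index().sort_values("p", kind="mergesort")
        top30 = list(ranked.index[:30])
        out = enrich_gene_sets(gs, {"top": top30}, "positive", min_size=20, seed=0)
        # closed-form oracle: all 30 members in the top 30 ranks
        closed_form = stats.hypergeom.sf(29, 1000, 30, 30)
        assert out.loc["top", "min_p"] == pytest.approx(closed_form, rel=1e-6)
        assert out.loc["top", "min_p"] < 1e-20
        assert out.loc["top", "p"] == pytest.approx(1 / 1001)

    def test_disjoint_set_uninformative(self, rng):
        gs = self._stats(rng)
        out = enrich_gene_sets(gs, {"neg": [f"x{j}" for j in range(30)]}, "positive")
        assert len(out) == 0  # no overlap with the ranked list -> filtered by size

    def test_null_sets_calibrated_fpr(self, rng):
        gs = self._stats(rng)
        sets = {f"rand{j}": list(rng.choice(gs.index, 30, replace=False))
                for j in range(200)}
        out = enrich_gene_sets(gs, sets, "positive", seed=1)
        assert (out["q"] < 0.05).mean() <= 0.05
        # calibrated p approximately uniform: mean near 0.5
        assert 0.4 < out["p"].mean() < 0.6

    def test_gene_order_invariance(self, rng):
        gs = self._stats(rng, n=200)
        members = list(rng.choice(gs.index, 25, replace=False))
        out1 = enrich_gene_sets(gs, {"s": members}, "positive", min_size=20, seed=3)
        gs_shuffled = gs.sample(frac=1.0, random_state=5)
        out2 = enrich_gene_sets(gs_shuffled, {"s": members}, "positive", min_size=20, seed=3)
        assert out1.loc["s", "min_p"] == pytest.approx(out2.loc["s", "min_p"])

    def test_bh_adjustment_properties(self, rng):
        gs = self._stats(rng)
        sets = {f"r{j}": list(rng.choice(gs.index, 25, replace=False)) for j in range(20)}
        out = enrich_gene_sets(gs, sets, "positive", seed=2)
        assert (out["q"] >= out["p"] - 1e-12).all()
        srt = out.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_size_bounds_respected(self, rng):
        gs = self._stats(rng)
        sets = {"tiny": list(gs.index[:5]), "ok": list(gs.index[:25])}
        out = enrich_gene_sets(gs, sets, "positive")
        assert list(out.index) == ["ok"]


class TestCovariateAssociation:
    def test_proportion_column_self_correlation(self, rng):
        props = pd.DataFrame(rng.dirichlet([1, 1, 1], 60),
                             index=[f"s{i}" for i in range(60)],
                             columns=["A1", "A2", "A3"])
        cov = pd.DataFrame({"c": props["A1"]})
        out = archetype_covariate_association(props, cov)
        row = out[(out["archetype"] == "A1") & (out["covariate"] == "c")]
        assert row["statistic"].iloc[0] == pytest.approx(1.0)

    def test_histotype_concentrated_at_vertex_detected(self, default_dataset):
        ds = default_dataset
        props = ds.truth.archetype_weights_true
        out = archetype_covariate_association(props, ds.clinical[["histotype"]])
        assert (out["p"] < 0.01).any()

    def test_single_level_rejected(self, rng):
        props = pd.DataFrame(rng.dirichlet([1, 1], 10), columns=["A1", "A2"])
        cov = pd.DataFrame({"c": ["x"] * 10})
        with pytest.raises(ValueError, match="single-level"):
            archetype_covariate_association(props, cov)


class TestEffectVectors:
    def test_separated_groups_exact_vector(self):
        coords = np.array([[0.0, 0.0]] * 5 + [[1.0, 0.0]] * 5)
        alts = pd.DataFrame({"A": [0] * 5 + [1] * 5})
        out = effect_vectors(coords, alts)
        np.testing.assert_allclose(out[0].vector, [1.0, 0.0])
        assert out[0].n_altered == 5 and out[0].n_wildtype == 5

    def test_random_carriers_null(self):
        norms, ps = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            coords = rng.standard_normal((300, 2))
            alts = pd.DataFrame({"A": rng.integers(0, 2, 300)})
            out = effect_vectors(coords, alts)
            norms.append(out[0].norm)
            ps.append(out[0].anova_p)
        assert np.mean(norms) < 0.25
        assert (np.array(ps) < 0.05).mean() <= 0.2

    def test_small_group_skipped(self):
        coords = np.zeros((10, 2))
        alts = pd.DataFrame({"A": [1, 1] + [0] * 8})
        assert effect_vectors(coords, alts, min_group=3) == []

    def test_translation_equivariance(self, rng):
        coords = rng.standard_normal((50, 2))
        alts = pd.DataFrame({"A": rng.integers(0, 2, 50)})
        v1 = effect_vectors(coords, alts)[0].vector
        v2 = effect_vectors(coords + np.array([5.0, -3.0]), alts)[0].vector
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_planted_displacement_recovered(self):
        import mesoaxes as mx
        from mesoaxes.simulate import generate_alterations, generate_factors

        hits = 0
        for seed in range(10):
            cfg = mx.GeneratorConfig(
                n_samples=200, seed=seed,
                alteration_specs=[("A", 0.3, (0.8, 0.0))],
            )
            _, _, w, pos = generate_factors(cfg)
            alts = generate_alterations(w, cfg, positions=pos)
            out = effect_vectors(pos.to_numpy(), alts)
            hits += np.linalg.norm(out[0].vector - np.array([0.8, 0.0])) < 0.25
        assert hits >= 9


class TestGlobalTest:
    def test_planted_effects_minimal_p(self, rng):
        coords = np.vstack([rng.standard_normal((100, 2)) * 0.2,
                            rng.standard_normal((100, 2)) * 0.2 + [2.0, 0.0]])
        alts = pd.DataFrame({"A": [0] * 100 + [1] * 100})
        p, obs, null = global_specialization_test(coords, alts, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_null_p_roughly_uniform(self):
        ps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            coords = rng.standard_normal((100, 2))
            alts = pd.DataFrame({f"A{j}": rng.integers(0, 2, 100) for j in range(3)})
            p, *_ = global_specialization_test(coords, alts, n_perm=99, seed=seed)
            ps.append(p)
        assert 0.25 < np.mean(ps) < 0.75
        assert (np.array(ps) <= 0.05).mean() <= 0.2

    def test_single_permutation_grid(self, rng):
        coords = rng.standard_normal((30, 2))
        alts = pd.DataFrame({"A": rng.integers(0, 2, 30)})
        p, *_ = global_specialization_test(coords, alts, n_perm=1, seed=0)
        assert p in (0.5, 1.0)

    def test_rotation_invariant_statistic(self, rng):
        coords = rng.standard_normal((80, 2))
        alts = pd.DataFrame({"A": rng.integers(0, 2, 80)})
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        _, obs1, _ = global_specialization_test(coords, alts, n_perm=1, seed=0)
        _, obs2, _ = global_specialization_test(coords @ R.T + 7.0, alts, n_perm=1, seed=0)
        assert obs1 == pytest.approx(obs2)

    def test_no_testable_alterations_rejected(self):
        coords = np.zeros((10, 2))
        alts = pd.DataFrame({"A": [1] + [0] * 9})
        with pytest.raises(ValueError, match="no alterations"):
            global_specialization_test(coords, alts)
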
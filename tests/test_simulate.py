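"""Generator contracts: determinism, planted couplings, simplex geometry."""

import numpy as np
import pandas as pd
import pytest

import mesoaxes as mx
from mesoaxes.simulate import (
    GeneratorConfig,
    generate_alterations,
    generate_copy_number,
    generate_expression,
    generate_factors,
    generate_methylation,
    generate_survival,
)


def small_config(**kw):
    defaults = dict(
        n_samples=60,
        features_per_view={
            "expression": 300,
            "meth_promoter": 200,
            "meth_body": 150,
            "meth_enhancer": 150,
        "copy_number": 300},
        cimp_coupling=(4.0, 100, 5),
        seed=7,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestFactors:
    def test_noiseless_ploidy_is_exact_linear_map(self):
        cfg = small_config(ploidy_coupling=(0.5, 0.0))
        Z, ploidy, _, _ = generate_factors(cfg)
        # clipping at [1, 4.5] only affects |z1| > 2; restrict to the linear part
        keep = ploidy[(ploidy > 1) & (ploidy < 4.5)]
        r = np.corrcoef(Z.loc[keep.index, "z1"], keep)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_low_alpha_concentrates_samples_at_vertices(self):
        # oracle: direct Dirichlet sampling reproduces the planted weights
        hits = []
        for seed in range(100):
            cfg = small_config(n_samples=120, dirichlet_alpha=0.2, seed=seed)
            _, _, w, _ = generate_factors(cfg)
            hits.append((w.to_numpy().max(axis=1) > 0.6).mean())
        assert np.mean([h >= 0.6 for h in hits]) > 0.9

    def test_same_seed_bit_identical(self):
        cfg = small_config()
        out1 = generate_factors(cfg)
        out2 = generate_factors(small_config())
        for a, b in zip(out1, out2):
            pd.testing.assert_frame_equal(a, b) if isinstance(a, pd.DataFrame) \
                else pd.testing.assert_series_equal(a, b)

    def test_weights_on_simplex_and_positions_in_triangle(self):
        cfg = small_config()
        _, _, w, pos = generate_factors(cfg)
        arr = w.to_numpy()
        assert (arr >= 0).all()
        np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-9)
        # positions are convex combinations, so barycentric coords are the weights
        verts = np.asarray(cfg.triangle_vertices)
        np.testing.assert_allclose(pos.to_numpy(), arr @ verts, atol=1e-12)

    def test_ploidy_within_haploid_tetraploid_range(self):
        _, ploidy, _, _ = generate_factors(small_config(ploidy_coupling=(2.0, 1.0)))
        assert ploidy.min() >= 1.0 and ploidy.max() <= 4.5

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="dirichlet_alpha"):
            small_config(dirichlet_alpha=0.0)


class TestExpression:
    def test_noiseless_expression_is_exact_linear_combination(self):
        cfg = small_config(noise_sd_per_view={"expression": 0.0, "methylation": 0.02})
        Z, *_ = generate_factors(cfg)
        view, _, markers = generate_expression(Z, cfg)
        # a proliferation marker loads only on factor 2: column proportional to z2
        g = markers["proliferation"][0]
        col = view.values[g].to_numpy()
        z2 = Z["z2"].to_numpy()
        coef = col @ z2 / (z2 @ z2)
        np.testing.assert_allclose(col, coef * z2, atol=1e-10)

    def test_silenced_genes_anticorrelate_with_cimp_factor(self):
        neg = []
        for seed in range(20):
            cfg = small_config(n_samples=500, seed=seed,
                               noise_sd_per_view={"expression": 0.1, "methylation": 0.02})
            Z, *_ = generate_factors(cfg)
            view, _, markers = generate_expression(Z, cfg)
            z4 = Z["z4"].to_numpy()
            rs = [np.corrcoef(view.values[g], z4)[0, 1] for g in markers["silenced"]]
            neg.append(all(r < 0 for r in rs))
        assert all(neg)

    def test_zero_loadings_yield_pure_noise(self):
        cfg = small_config(n_samples=200, loading_sparsity=1.0, marker_strength=0.0)
        Z, *_ = generate_factors(cfg)
        view, _, _ = generate_expression(Z, cfg)
        Y = view.values.to_numpy()
        Yc = (Y - Y.mean(0)) / Y.std(0)
        Zc = (Z.to_numpy() - Z.to_numpy().mean(0)) / Z.to_numpy().std(0)
        corr = np.abs(Zc.T @ Yc / len(Z))
        assert corr.max() < 0.3

    def test_sex_chromosome_genes_present(self):
        cfg = small_config()
        Z, *_ = generate_factors(cfg)
        view, _, _ = generate_expression(Z, cfg)
        frac = view.feature_meta["chromosome"].isin(["chrX", "chrY"]).mean()
        assert frac >= 0.015


class TestMethylation:
    def test_zero_slope_zero_noise_gives_constant_cimp(self):
        cfg = small_config(cimp_coupling=(0.0, 100, 5),
                           noise_sd_per_view={"expression": 0.5, "methylation": 0.0})
        Z, *_ = generate_factors(cfg)
        *_, cimp_true = generate_methylation(Z, cfg)
        assert cimp_true.nunique() == 1

    def test_m_value_is_logit_of_beta(self):
        cfg = small_config()
        Z, *_ = generate_factors(cfg)
        beta, M, *_ = generate_methylation(Z, cfg)
        b = np.clip(beta.values.to_numpy(), 1e-6, 1 - 1e-6)
        np.testing.assert_allclose(M.values.to_numpy(), np.log2(b / (1 - b)), atol=1e-10)
        # beta exactly 0.5 maps to M = 0
        assert np.log2(0.5 / 0.5) == 0.0

    def test_strong_coupling_links_cimp_index_to_z4(self):
        from mesoaxes.cimp import compute_cimp

        for seed in range(5):
            cfg = GeneratorConfig(
                n_samples=120, seed=seed,
                features_per_view={"expression": 300, "meth_promoter": 4000,
                                   "meth_body": 3000, "meth_enhancer": 3000,
                                   "copy_number": 300},
                cimp_coupling=(4.0, 2000, 5),
            )
            Z, *_ = generate_factors(cfg)
            beta, _, island_map, _, _ = generate_methylation(Z, cfg)
            idx = compute_cimp(beta, island_map).cimp_index
            assert abs(np.corrcoef(idx, Z["z4"])[0, 1]) > 0.95

    def test_every_cpg_in_exactly_one_island(self):
        cfg = small_config()
        Z, *_ = generate_factors(cfg)
        beta, _, island_map, region_map, _ = generate_methylation(Z, cfg)
        all_cpgs = [c for cpgs in island_map.values() for c in cpgs]
        assert len(all_cpgs) == len(set(all_cpgs)) == beta.n_features
        assert set(region_map.unique()) <= {"promoter", "body", "enhancer"}


class TestCopyNumber:
    def test_zero_deviations_equal_ploidy(self):
        cfg = small_config(cn_block_alter_prob=0.0)
        Z, ploidy, *_ = generate_factors(cfg)
        view, _ = generate_copy_number(ploidy, cfg)
        arr = view.values.to_numpy()
        expected = np.broadcast_to(ploidy.to_numpy()[:, None], arr.shape)
        np.testing.assert_allclose(arr, expected, atol=1e-12)

    def test_mean_cn_tracks_ploidy(self):
        # default-scale CN layer (120 segments) so per-sample means average out
        cfg = mx.GeneratorConfig(seed=3)
        Z, ploidy, *_ = generate_factors(cfg)
        view, _ = generate_copy_number(ploidy, cfg)
        diff = view.values.mean(axis=1).to_numpy() - ploidy.to_numpy()
        assert np.abs(diff).max() < 0.2

    def test_purity_in_configured_range(self):
        cfg = small_config()
        _, ploidy, *_ = generate_factors(cfg)
        _, purity = generate_copy_number(ploidy, cfg)
        lo, hi = cfg.purity_range
        assert purity.between(lo, hi).all()


class TestAlterations:
    def test_null_displacement_gives_uniform_carriers(self):
        norms = []
        for seed, n in [(0, 200), (1, 800)]:
            cfg = small_config(
                n_samples=n, seed=seed,
                alteration_specs=[("NULL", 0.3, (0.0, 0.0))],
            )
            _, _, w, pos = generate_factors(cfg)
            alts = generate_alterations(w, cfg, positions=pos)
            c = alts["NULL"].to_numpy().astype(bool)
            X = pos.to_numpy()
            norms.append(np.linalg.norm(X[c].mean(0) - X[~c].mean(0)))
        assert norms[1] < 0.35  # shrinks toward 0 with n

    def test_prevalence_calibration_band(self):
        counts = []
        for seed in range(30):
            cfg = small_config(n_samples=200, seed=seed,
                               alteration_specs=[("A", 0.3, (0.8, 0.0))])
            _, _, w, pos = generate_factors(cfg)
            alts = generate_alterations(w, cfg, positions=pos)
            counts.append(int(alts["A"].sum()))
        assert all(36 <= c <= 84 for c in counts)

    def test_same_seed_identical_carrier_sets(self):
        cfg = small_config()
        _, _, w, pos = generate_factors(cfg)
        a1 = generate_alterations(w, cfg, positions=pos)
        a2 = generate_alterations(w, small_config(), positions=pos)
        pd.testing.assert_frame_equal(a1, a2)


class TestSurvival:
    def test_planted_binary_hazard_ratio_recovered(self):
        from mesoaxes.survival import cox_association

        inside = 0
        for seed in range(5):
            cfg = small_config(n_samples=1000, seed=seed,
                               survival_coefs=(np.log(2), 0, 0, 0),
                               censoring_rate=0.0)
            rng = np.random.default_rng(seed)
            z1 = rng.integers(0, 2, size=1000).astype(float)
            Z = pd.DataFrame(
                {"z1": z1, "z2": 0.0, "z3": 0.0, "z4": 0.0},
                index=[f"S{i}" for i in range(1000)],
            )
            t, e = generate_survival(Z, cfg)
            res = cox_association(Z[["z1"]], t, e, standardize=False)
            hr = res.summary.loc["z1", "hr"]
            inside += 1.7 <= hr <= 2.35
        assert inside >= 4

    def test_censoring_rate_calibrated(self):
        cfg = small_config(n_samples=500, censoring_rate=0.3)
        Z, *_ = generate_factors(cfg)
        _, event = generate_survival(Z, cfg)
        assert 0.6 <= event.mean() <= 0.8

    def test_requires_one_coef_per_factor(self):
        cfg = small_config(survival_coefs=(0.5, 0.5))
        Z, *_ = generate_factors(cfg)
        with pytest.raises(ValueError, match="one survival coefficient"):
            generate_survival(Z, cfg)


def test_full_dataset_deterministic_under_seed():
    d1 = mx.generate_dataset(small_config())
    d2 = mx.generate_dataset(small_config())
    pd.testing.assert_frame_equal(d1.expression.values, d2.expression.values)
    pd.testing.assert_frame_equal(d1.meth_beta.values, d2.meth_beta.values)
    pd.testing.assert_frame_equal(d1.alterations, d2.alterations)
    pd.testing.assert_series_equal(d1.truth.survival_time, d2.truth.survival_time)


def test_cimp_true_matches_computed_index_rank_order(default_dataset):
    from scipy.stats import spearmanr
    from mesoaxes.cimp import compute_cimp

    ds = default_dataset
    idx = compute_cimp(ds.meth_beta, ds.island_map).cimp_index
    rho = spearmanr(idx, ds.truth.cimp_true).statistic
    assert rho > 0.9
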
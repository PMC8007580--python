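"""Macrovoxel pooling, the four pdf families, SSE family selection and the
synthetic-pattern generators."""

import numpy as np
import pytest
from scipy import stats

from ordivox import (
    AugmentationPlan,
    VoxelDistributionFit,
    apply_configuration,
    evaluate_pdf,
    fit_family,
    generate_synthetic,
    macrovoxel_indices,
    noisy_replication,
    pool_class_samples,
    select_best_family,
)
from ordivox.volumes import OrdinalDataset


class TestMacrovoxel:
    def test_interior_width3_has_27_members(self):
        spec = macrovoxel_indices((2, 3, 2), 3, (5, 5, 5))
        assert len(spec.member_indices) == 27
        assert len(set(spec.member_indices.tolist())) == 27

    def test_corner_truncates_to_8(self):
        spec = macrovoxel_indices((0, 0, 0), 3, (5, 5, 5))
        assert len(spec.member_indices) == 8

    def test_width1_is_the_center_itself(self):
        from ordivox import linear_index

        spec = macrovoxel_indices((2, 3, 2), 1, (5, 5, 5))
        assert spec.member_indices.tolist() == [linear_index((2, 3, 2), (5, 5, 5))]

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            macrovoxel_indices((2, 2, 2), 2, (5, 5, 5))

    def test_informative_restriction(self):
        full = macrovoxel_indices((2, 3, 2), 3, (5, 5, 5)).member_indices
        keep = set(full[:5].tolist())
        spec = macrovoxel_indices((2, 3, 2), 3, (5, 5, 5), informative=keep)
        assert set(spec.member_indices.tolist()) == keep


class TestPooling:
    def _dataset(self, X, y):
        return OrdinalDataset(X=X, y=y, L=int(np.max(y)) + 1, dims=(5, 5, 5))

    def test_pool_size_is_members_times_images(self, rng):
        spec = macrovoxel_indices((2, 3, 2), 3, (5, 5, 5))
        ds = self._dataset(rng.random((12, 125)), np.repeat([0, 1], [10, 2]))
        z = pool_class_samples(ds, spec, 0)
        assert z.size == 27 * 10

    def test_single_member_collects_the_column(self):
        spec = macrovoxel_indices((0, 0, 0), 1, (5, 5, 5))
        X = np.zeros((3, 125))
        X[:, 0] = [1.0, 2.0, 3.0]
        ds = self._dataset(X, np.zeros(3, dtype=int))
        assert sorted(pool_class_samples(ds, spec, 0).tolist()) == [1.0, 2.0, 3.0]

    def test_pool_invariant_to_image_order(self, rng):
        spec = macrovoxel_indices((1, 1, 1), 3, (5, 5, 5))
        X = rng.random((6, 125))
        y = np.zeros(6, dtype=int)
        ds1 = self._dataset(X, y)
        perm = rng.permutation(6)
        ds2 = self._dataset(X[perm], y)
        z1, z2 = pool_class_samples(ds1, spec, 0), pool_class_samples(ds2, spec, 0)
        assert sorted(z1.tolist()) == sorted(z2.tolist())

    def test_empty_class_rejected(self, rng):
        spec = macrovoxel_indices((0, 0, 0), 1, (5, 5, 5))
        ds = self._dataset(rng.random((3, 125)), np.zeros(3, dtype=int))
        with pytest.raises(ValueError):
            pool_class_samples(ds, spec, 1)


class TestEvaluatePdf:
    def test_uniform_beta_special_case(self):
        assert evaluate_pdf("beta", (1.0, 1.0, 0.0, 1.0), 0.5) == pytest.approx(1.0)

    def test_gumbel_branch_at_zero(self):
        assert evaluate_pdf("genextreme", (0.0, 0.0, 1.0), 0.0) == pytest.approx(
            np.exp(-1)
        )

    def test_cauchy_special_case_of_t(self):
        assert evaluate_pdf("t_student", (1.0, 0.0, 1.0), 0.0) == pytest.approx(
            1 / np.pi
        )

    def test_outside_support_is_zero(self):
        assert evaluate_pdf("beta", (2.0, 2.0, 0.0, 1.0), 1.5) == 0.0
        assert evaluate_pdf("alpha", (3.0, 0.0, 1.0), -0.5) == 0.0

    @pytest.mark.parametrize(
        "family,dist,params",
        [
            ("alpha", stats.alpha, (3.5, 0.2, 1.3)),
            ("genextreme", stats.genextreme, (0.2, 0.1, 2.0)),
            ("genextreme", stats.genextreme, (-0.3, 0.0, 1.0)),
            ("t_student", stats.t, (4.0, -1.0, 0.7)),
            ("beta", stats.beta, (2.0, 5.0, -1.0, 4.0)),
        ],
    )
    def test_closed_forms_match_scipy(self, family, dist, params):
        z = np.linspace(-4, 4, 81)
        np.testing.assert_allclose(
            evaluate_pdf(family, params, z), dist.pdf(z, *params), atol=1e-12
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            evaluate_pdf("beta", (-1.0, 2.0, 0.0, 1.0), 0.5)
        with pytest.raises(ValueError):
            evaluate_pdf("t_student", (1.0, 0.0, 0.0), 0.5)  # sigma = 0


class TestFitFamily:
    def test_t_parameter_recovery(self):
        z = stats.t.rvs(3, size=5000, random_state=11)
        fit = fit_family(z, "t_student")
        assert 2.0 <= fit.params[0] <= 5.0
        assert fit.support == (z.min(), z.max())

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_family(np.full(100, 3.0), "beta")

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_family(np.arange(7.0), "t_student")

    def test_generating_family_beats_mismatch_on_uniform(self):
        z = stats.uniform.rvs(size=5000, random_state=3)
        assert fit_family(z, "beta").sse <= fit_family(z, "genextreme").sse


class TestSelectBestFamily:
    def test_uniform_sample_selects_beta(self):
        z = stats.uniform.rvs(size=5000, random_state=4)
        assert select_best_family(z).family == "beta"

    def test_gev_recovery_over_seeds(self):
        wins = sum(
            select_best_family(
                stats.genextreme.rvs(0.2, size=5000, random_state=s)
            ).family
            == "genextreme"
            for s in range(10)
        )
        assert wins >= 8


def _uniform_fit(lo=0.0, hi=1.0):
    return VoxelDistributionFit(
        family="beta", params=(1.0, 1.0, lo, hi - lo), sse=0.0, support=(lo, hi)
    )


def _reduced_dataset(counts=(4, 3, 2), n_feat=2, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(len(counts)), counts)
    X = rng.random((y.size, n_feat))
    return OrdinalDataset(
        X=X, y=y, L=len(counts), dims=(1, 1, 2), feature_indices=np.arange(n_feat)
    )


class TestGenerateSynthetic:
    def _fits(self, classes=(1,)):
        return {(fi, l): _uniform_fit() for fi in (0, 1) for l in classes}

    def test_zero_count_rejected(self):
        ds = _reduced_dataset()
        with pytest.raises(ValueError):
            generate_synthetic(ds, self._fits(), 1, 0, seed=0)

    def test_labels_shape_and_bounds(self):
        ds = _reduced_dataset()
        out = generate_synthetic(ds, self._fits(), 1, 50, seed=1)
        assert out.X.shape == (50, 2)
        assert np.all(out.y == 1)
        assert out.X.min() >= 0.0 and out.X.max() <= 1.0

    def test_draws_stay_inside_empirical_support(self):
        # a wide normal truncated to a narrow recorded support
        fit = VoxelDistributionFit(
            family="t_student", params=(50.0, 0.0, 5.0), sse=0.1, support=(-1.0, 1.0)
        )
        ds = _reduced_dataset(n_feat=1)
        fits = {(0, 1): fit}
        out = generate_synthetic(ds, fits, 1, 300, seed=2)
        assert out.X.min() >= -1.0 and out.X.max() <= 1.0

    def test_generated_mean_matches_fitted_mean(self):
        # law of large numbers at 3 standard errors of the fitted mean
        z = stats.beta.rvs(2, 5, size=5000, random_state=6)
        fit = fit_family(z, "beta")
        frozen = fit.frozen()
        ds = _reduced_dataset(n_feat=1)
        out = generate_synthetic(ds, {(0, 1): fit}, 1, 500, seed=7)
        se = frozen.std() / np.sqrt(500)
        assert abs(out.X[:, 0].mean() - frozen.mean()) < 3 * se

    def test_missing_fit_rejected(self):
        ds = _reduced_dataset()
        with pytest.raises(ValueError):
            generate_synthetic(ds, {(0, 1): _uniform_fit()}, 1, 5, seed=0)


class TestNoisyReplication:
    def test_zero_sd_duplicates_sources_exactly(self):
        ds = _reduced_dataset()
        out = noisy_replication(ds, 1, factor=2, noise_sd=0.0, seed=3)
        assert out.X.shape[0] == 3
        sources = {tuple(row) for row in ds.X[ds.y == 1]}
        assert all(tuple(row) in sources for row in out.X)

    def test_paper_scale_arithmetic(self):
        # triplicating a 51-pattern class adds 102 patterns (total 153)
        ds = _reduced_dataset(counts=(60, 51, 30), seed=1)
        out = noisy_replication(ds, 1, factor=3, seed=4)
        assert out.X.shape[0] == 102

    def test_factor_two_on_ten(self):
        ds = _reduced_dataset(counts=(5, 10), seed=2)
        out = noisy_replication(ds, 1, factor=2, seed=5)
        assert out.X.shape[0] == 10

    def test_factor_below_two_rejected(self):
        with pytest.raises(ValueError):
            noisy_replication(_reduced_dataset(), 1, factor=1, seed=0)


class TestApplyConfiguration:
    def _full_fits(self):
        return {(fi, l): _uniform_fit() for fi in (0, 1) for l in (0, 1, 2)}

    def test_conf0_is_identity(self):
        ds = _reduced_dataset()
        out = apply_configuration(ds, AugmentationPlan("CONF0", seed=0))
        assert np.array_equal(out.X, ds.X) and np.array_equal(out.y, ds.y)

    def test_conf5_triplicates_class1(self):
        ds = _reduced_dataset(counts=(189, 51, 63), seed=3)
        out = apply_configuration(
            ds, AugmentationPlan("CONF5", seed=1), fits=self._full_fits()
        )
        assert out.class_counts().tolist() == [189, 153, 63]

    def test_conf1_duplicates_every_class(self):
        ds = _reduced_dataset(counts=(189, 51, 63), seed=4)
        out = apply_configuration(
            ds, AugmentationPlan("CONF1", seed=2), fits=self._full_fits()
        )
        assert out.class_counts().tolist() == [378, 102, 126]

    @pytest.mark.parametrize(
        "config,expected",
        [("CONF2", [10, 8, 12]), ("CONF3", [10, 8, 6]), ("CONF4", [10, 4, 12])],
    )
    def test_partial_duplication_counts(self, config, expected):
        ds = _reduced_dataset(counts=(10, 4, 6), seed=5)
        out = apply_configuration(
            ds, AugmentationPlan(config, seed=3), fits=self._full_fits()
        )
        assert out.class_counts().tolist() == expected

    def test_rand_uses_noisy_replication_factor_three(self):
        ds = _reduced_dataset(counts=(10, 4, 6), seed=6)
        out = apply_configuration(ds, AugmentationPlan("RAND", seed=4))
        assert out.class_counts().tolist() == [10, 12, 6]

    def test_original_rows_preserved(self):
        ds = _reduced_dataset(counts=(6, 4, 3), seed=7)
        out = apply_configuration(
            ds, AugmentationPlan("CONF2", seed=5), fits=self._full_fits()
        )
        n = ds.X.shape[0]
        assert np.array_equal(out.X[:n], ds.X)
        assert np.array_equal(out.y[:n], ds.y)

    def test_synthetic_config_requires_fits(self):
        with pytest.raises(ValueError):
            apply_configuration(_reduced_dataset(), AugmentationPlan("CONF5", seed=0))

    def test_unknown_configuration_rejected(self):
        with pytest.raises(ValueError):
            AugmentationPlan("CONF9")
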
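import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from cogtomo import (
    FeatureSpace,
    GridDensity,
    SubjectiveDistribution,
    js_divergence,
    moment_match,
)
from _oracles import gl_grid, js_divergence_bruteforce, mixture_pdf_bruteforce, random_mixture

mixture_seeds = st.integers(min_value=0, max_value=10_000)


class TestFeatureSpace:
    def test_uniform_density_matches_box_volume(self, space):
        assert space.uniform_density == pytest.approx(1.0 / 64.0)

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            FeatureSpace(half_width=0.0)
        with pytest.raises(ValueError):
            FeatureSpace(n_dims=0)

    def test_grid_axes_cover_box(self, space):
        ax = space.grid_axes(100)
        assert len(ax) == 100
        step = ax[1] - ax[0]
        assert ax[0] == pytest.approx(-space.half_width + step / 2)
        assert ax[-1] == pytest.approx(space.half_width - step / 2)


class TestDensity:
    def test_standard_gaussian_peak(self, std_gaussian):
        assert std_gaussian.pdf(np.zeros(2)) == pytest.approx(1.0 / (2 * np.pi))

    def test_density_matches_componentwise_sum(self, space, bimodal):
        x = np.array([0.0, 0.0])
        assert bimodal.pdf(x) == pytest.approx(
            float(mixture_pdf_bruteforce(bimodal, x)[0]), rel=1e-12
        )

    def test_dimension_mismatch_rejected(self, std_gaussian):
        with pytest.raises(ValueError):
            std_gaussian.pdf(np.zeros(3))

    def test_invalid_mixture_rejected(self, space):
        with pytest.raises(ValueError):
            SubjectiveDistribution(
                space, np.array([0.6, 0.6]), np.zeros((2, 2)), np.stack([np.eye(2)] * 2)
            )
        with pytest.raises(ValueError):
            SubjectiveDistribution(
                space,
                np.array([1.0]),
                np.zeros((1, 2)),
                np.array([[[1.0, 2.0], [2.0, 1.0]]]),  # not PD
            )

    @settings(max_examples=10, deadline=None)
    @given(seed=mixture_seeds)
    def test_density_nonnegative_and_normalized(self, seed):
        p = random_mixture(seed, FeatureSpace())
        pts, wts = gl_grid(half_width=14.0, n_nodes=200)
        dens = p.pdf(pts)
        assert np.all(dens >= 0)
        assert np.sum(wts * dens) == pytest.approx(1.0, abs=1e-6)


class TestToGrid:
    def test_masses_sum_to_one(self, bimodal):
        g = bimodal.to_grid(64)
        assert g.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_resolution_floor(self, std_gaussian):
        with pytest.raises(ValueError):
            std_gaussian.to_grid(7)

    def test_flat_limit_is_uniform(self, space):
        broad = SubjectiveDistribution(
            space, np.array([1.0]), np.zeros((1, 2)), (1e6 * np.eye(2))[None]
        )
        g = broad.to_grid(50)
        assert g.masses.max() / g.masses.min() < 1.001

    def test_narrow_gaussian_grid_mean(self, space):
        narrow = SubjectiveDistribution(
            space, np.array([1.0]), np.zeros((1, 2)), (0.25 * np.eye(2))[None]
        )
        g = narrow.to_grid(200)
        assert np.abs(g.mean()).max() < 0.02

    def test_discretization_converges(self, bimodal):
        """Halving the cell size changes the discretization by < 1e-3 bits."""
        fine = bimodal.to_grid(200)
        coarse = bimodal.to_grid(100)
        pooled = fine.masses.reshape(100, 2, 100, 2).sum(axis=(1, 3))
        fine_as_coarse = GridDensity(fine.space, 100, pooled / pooled.sum())
        assert js_divergence(coarse, fine_as_coarse) < 1e-3


class TestSample:
    def test_seeded_determinism(self, bimodal):
        a = bimodal.sample(500, seed=7)
        b = bimodal.sample(500, seed=7)
        assert np.array_equal(a, b)

    def test_requires_positive_n(self, std_gaussian):
        with pytest.raises(ValueError):
            std_gaussian.sample(0, seed=0)

    def test_sample_mean(self, std_gaussian):
        x = std_gaussian.sample(100_000, seed=1)
        assert np.abs(x.mean(axis=0)).max() < 0.02

    def test_component_weight_fractions(self, space):
        p = SubjectiveDistribution(
            space,
            np.array([0.7, 0.3]),
            np.array([[-3.0, 0.0], [3.0, 0.0]]),
            np.stack([0.01 * np.eye(2)] * 2),
        )
        x = p.sample(100_000, seed=2)
        frac_right = float((x[:, 0] > 0).mean())
        assert frac_right == pytest.approx(0.3, abs=0.01)


class TestMomentMatch:
    def test_identity_on_single_component(self, std_gaussian):
        mm = moment_match(std_gaussian)
        assert np.array_equal(mm.means, std_gaussian.means)
        assert np.array_equal(mm.covariances, std_gaussian.covariances)

    def test_symmetric_bimodal_closed_form(self, bimodal):
        mm = moment_match(bimodal)
        assert np.allclose(mm.means[0], [0.0, 0.0])
        assert np.allclose(mm.covariances[0], np.diag([0.5 + 4.0, 0.5]))

    def test_matches_monte_carlo_moments(self, space):
        p = random_mixture(42, space)
        x = p.sample(1_000_000, seed=3)
        mm = moment_match(p)
        assert np.allclose(mm.means[0], x.mean(axis=0), atol=0.01)
        assert np.allclose(mm.covariances[0], np.cov(x.T), rtol=0.01, atol=0.01)

    @settings(max_examples=10, deadline=None)
    @given(seed=mixture_seeds)
    def test_idempotent(self, seed):
        p = random_mixture(seed, FeatureSpace())
        once = moment_match(p)
        twice = moment_match(once)
        assert np.array_equal(once.means, twice.means)
        assert np.array_equal(once.covariances, twice.covariances)


class TestJSDivergence:
    def test_self_divergence_zero(self, bimodal):
        g = bimodal.to_grid(64)
        assert js_divergence(g, g) == 0.0

    def test_disjoint_support_is_one_bit(self, space):
        res = 16
        left = np.zeros((res, res))
        right = np.zeros((res, res))
        left[: res // 2] = 1.0
        right[res // 2 :] = 1.0
        gl = GridDensity(space, res, left / left.sum())
        gr = GridDensity(space, res, right / right.sum())
        assert js_divergence(gl, gr) == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_grids_rejected(self, bimodal):
        with pytest.raises(ValueError):
            js_divergence(bimodal.to_grid(64), bimodal.to_grid(32))

    def test_matches_bruteforce_and_scipy(self, space, bimodal, std_gaussian):
        a = bimodal.to_grid(100)
        b = std_gaussian.to_grid(100)
        ours = js_divergence(a, b)
        brute = js_divergence_bruteforce(a.masses, b.masses)
        assert ours == pytest.approx(brute, abs=1e-9)
        scipy_js = jensenshannon(a.masses.ravel(), b.masses.ravel(), base=2) ** 2
        assert ours == pytest.approx(float(scipy_js), abs=1e-9)

    @settings(max_examples=10, deadline=None)
    @given(seed=mixture_seeds)
    def test_symmetric_bounded_and_metric_root(self, seed):
        space = FeatureSpace()
        rng_seeds = [seed, seed + 77_777, seed + 155_554]
        grids = [random_mixture(s, space).to_grid(40) for s in rng_seeds]
        d01 = js_divergence(grids[0], grids[1])
        d10 = js_divergence(grids[1], grids[0])
        assert d01 == pytest.approx(d10, abs=1e-15)
        for g in grids:
            for h in grids:
                d = js_divergence(g, h)
                assert 0.0 <= d <= 1.0
        r01 = np.sqrt(js_divergence(grids[0], grids[1]))
        r12 = np.sqrt(js_divergence(grids[1], grids[2]))
        r02 = np.sqrt(js_divergence(grids[0], grids[2]))
        assert r02 <= r01 + r12 + 1e-9

    def test_zero_only_for_identical_grids(self, space, bimodal):
        shifted = SubjectiveDistribution(
            space, bimodal.weights, bimodal.means + 0.05, bimodal.covariances
        )
        assert js_divergence(bimodal.to_grid(64), shifted.to_grid(64)) > 0.0


class TestSerialization:
    def test_json_roundtrip_exact(self, bimodal):
        back = SubjectiveDistribution.from_json(bimodal.to_json())
        assert np.array_equal(back.weights, bimodal.weights)
        assert np.array_equal(back.means, bimodal.means)
        assert np.array_equal(back.covariances, bimodal.covariances)
        assert back.space == bimodal.space
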
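import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogtomo import (
    FAMILIARITY,
    ODD_ONE_OUT,
    ObserverParams,
    Response,
    SubjectiveDistribution,
    Trial,
    choice_probabilities,
    familiarity_likelihoods,
    ooo_by_familiarity,
    ooo_likelihoods,
    response_probability,
)
from cogtomo.ideal_observer import HypothesisLikelihoods
from _oracles import quad_familiarity_likelihoods, quad_ooo_likelihoods, random_mixture


def equilateral(center, side, phase=0.0):
    r = side / np.sqrt(3.0)
    ang = phase + 2 * np.pi * np.arange(3) / 3
    return center + r * np.stack([np.cos(ang), np.sin(ang)], axis=1)


class TestTrialValidation:
    def test_stimulus_count_must_match_task(self, space):
        with pytest.raises(ValueError):
            Trial(FAMILIARITY, np.zeros((3, 2)), space)
        with pytest.raises(ValueError):
            Trial(ODD_ONE_OUT, np.zeros((2, 2)), space)

    def test_stimuli_must_be_inside_box(self, space):
        with pytest.raises(ValueError):
            Trial(FAMILIARITY, np.array([[0.0, 0.0], [5.0, 0.0]]), space)

    def test_choice_range(self, space):
        t = Trial(FAMILIARITY, np.zeros((2, 2)), space)
        with pytest.raises(ValueError):
            Response(t, 2)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ObserverParams(perceptual_sigma=0.0, temperature=1.0)
        with pytest.raises(ValueError):
            ObserverParams(perceptual_sigma=1.0, temperature=1.0, lapse=1.5)


class TestFamiliarityLikelihoods:
    def test_identical_stimuli_are_symmetric(self, std_gaussian, gen_params, space):
        t = Trial(FAMILIARITY, np.array([[1.0, 1.0], [1.0, 1.0]]), space)
        lik = familiarity_likelihoods(t, std_gaussian, gen_params)
        assert lik.values[0] == lik.values[1]

    def test_stimulus_at_mode_is_more_likely(self, std_gaussian, gen_params, space):
        t = Trial(FAMILIARITY, np.array([[0.0, 0.0], [3.0, 0.0]]), space)
        lik = familiarity_likelihoods(t, std_gaussian, gen_params)
        assert lik.values[0] > lik.values[1]

    def test_wrong_task_rejected(self, std_gaussian, gen_params, space):
        t = Trial(ODD_ONE_OUT, np.zeros((3, 2)), space)
        with pytest.raises(ValueError):
            familiarity_likelihoods(t, std_gaussian, gen_params)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_quadrature(self, space, seed):
        rng = np.random.default_rng(seed)
        p = random_mixture(seed, space)
        params = ObserverParams(
            perceptual_sigma=rng.uniform(0.3, 1.0),
            temperature=rng.uniform(1.0, 5.0),
            lapse=rng.uniform(0.0, 0.2),
        )
        t = Trial(FAMILIARITY, rng.uniform(-4, 4, (2, 2)), space)
        analytic = familiarity_likelihoods(t, p, params).values
        quad = quad_familiarity_likelihoods(t, p, params)
        assert np.allclose(analytic, quad, rtol=1e-6)


class TestOOOLikelihoods:
    def test_symmetric_triad_symmetric_prior(self, std_gaussian, gen_params, space):
        t = Trial(ODD_ONE_OUT, equilateral(np.zeros(2), 2.0), space)
        lik = ooo_likelihoods(t, std_gaussian, gen_params)
        assert np.max(np.abs(lik.log_values - lik.log_values[0])) < 1e-12

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_quadrature(self, space, seed):
        rng = np.random.default_rng(seed + 1)
        p = random_mixture(seed + 1, space)
        params = ObserverParams(
            perceptual_sigma=rng.uniform(0.3, 1.0), temperature=1.0, lapse=0.0
        )
        t = Trial(ODD_ONE_OUT, rng.uniform(-3.5, 3.5, (3, 2)), space)
        analytic = ooo_likelihoods(t, p, params).values
        quad = quad_ooo_likelihoods(t, p, params)
        assert np.allclose(analytic, quad, rtol=1e-5)

    def test_pairs_near_modes_are_easier_to_discriminate(self, space):
        """With a pair of stimuli in a high-density region and the third far
        out in the tails, hypotheses placing the odd one INSIDE the pair beat
        the geometric answer: density scales the two-sample account."""
        p = SubjectiveDistribution(
            space, np.array([1.0]), np.array([[-2.0, 0.0]]), (0.25 * np.eye(2))[None]
        )
        params = ObserverParams(perceptual_sigma=0.2, temperature=1.0, lapse=0.0)
        # stimuli 0,1 near the mode; stimulus 2 in the far low-density corner
        tri = equilateral(np.zeros(2), 3.0, phase=np.pi / 6)
        shift = np.array([-2.0, 0.0]) - (tri[0] + tri[1]) / 2
        stim = np.clip(tri + shift, -3.9, 3.9)
        t = Trial(ODD_ONE_OUT, stim, space)
        lik = ooo_likelihoods(t, p, params)
        assert max(lik.values[0], lik.values[1]) > lik.values[2]


class TestChoiceProbabilities:
    def test_equal_likelihoods_uniform(self):
        lik = HypothesisLikelihoods(np.log([0.2, 0.2, 0.2]))
        probs = choice_probabilities(lik, ObserverParams(0.5, 7.0, 0.1))
        assert np.allclose(probs, 1 / 3, atol=1e-15)

    def test_pure_lapse_uniform(self):
        lik = HypothesisLikelihoods(np.log([0.9, 0.01]))
        probs = choice_probabilities(lik, ObserverParams(0.5, 2.0, 1.0))
        assert np.allclose(probs, 0.5, atol=1e-15)

    def test_high_temperature_approaches_argmax(self):
        lik = HypothesisLikelihoods(np.log([0.3, 0.2, 0.1]))
        probs = choice_probabilities(lik, ObserverParams(0.5, 1e3, 0.0))
        assert probs[0] > 0.999

    @settings(max_examples=20, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        temperature=st.floats(0.1, 50.0),
        lapse=st.floats(0.0, 1.0),
    )
    def test_probability_simplex(self, seed, temperature, lapse):
        rng = np.random.default_rng(seed)
        lik = HypothesisLikelihoods(rng.uniform(-30, 0, size=3))
        probs = choice_probabilities(lik, ObserverParams(0.5, temperature, lapse))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(probs >= 0) and np.all(probs <= 1)


class TestResponseProbability:
    def test_identical_familiarity_stimuli_fifty_fifty(self, std_gaussian, gen_params, space):
        t = Trial(FAMILIARITY, np.array([[0.5, -1.0], [0.5, -1.0]]), space)
        assert np.allclose(
            response_probability(t, std_gaussian, gen_params), [0.5, 0.5], atol=1e-15
        )

    def test_symmetric_triad_uniform(self, std_gaussian, gen_params, space):
        t = Trial(ODD_ONE_OUT, equilateral(np.zeros(2), 2.5, phase=0.3), space)
        assert np.allclose(
            response_probability(t, std_gaussian, gen_params), 1 / 3, atol=1e-12
        )

    def test_composition_identity(self, bimodal, gen_params, space):
        rng = np.random.default_rng(5)
        t = Trial(ODD_ONE_OUT, rng.uniform(-3, 3, (3, 2)), space)
        via_ops = choice_probabilities(ooo_likelihoods(t, bimodal, gen_params), gen_params)
        assert np.array_equal(response_probability(t, bimodal, gen_params), via_ops)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_equivariance(self, space, seed):
        rng = np.random.default_rng(seed)
        p = random_mixture(seed + 2, space)
        params = ObserverParams(0.4, 2.5, 0.1)
        stim = rng.uniform(-3.5, 3.5, (3, 2))
        perm = rng.permutation(3)
        base = response_probability(Trial(ODD_ONE_OUT, stim, space), p, params)
        permuted = response_probability(Trial(ODD_ONE_OUT, stim[perm], space), p, params)
        assert np.allclose(permuted, base[perm], rtol=1e-12)

    def test_huge_perceptual_noise_gives_uniform_ooo(self, bimodal, space):
        params = ObserverParams(perceptual_sigma=100.0, temperature=2.0, lapse=0.0)
        t = Trial(ODD_ONE_OUT, equilateral(np.array([1.0, -0.5]), 3.0), space)
        assert np.allclose(response_probability(t, bimodal, params), 1 / 3, atol=1e-3)


class TestOOOByFamiliarity:
    def test_symmetric_configuration_uniform(self, std_gaussian, gen_params, space):
        t = Trial(ODD_ONE_OUT, equilateral(np.zeros(2), 2.0), space)
        for mode in ("most", "least"):
            probs = ooo_by_familiarity(t, std_gaussian, gen_params, mode=mode)
            assert np.allclose(probs, 1 / 3, atol=1e-12)

    def test_modes_concentrate_on_opposite_extremes(self, std_gaussian, space):
        params = ObserverParams(0.3, 100.0, 0.0)
        stim = np.array([[0.0, 0.0], [1.5, 0.0], [3.5, 0.0]])
        t = Trial(ODD_ONE_OUT, stim, space)
        most = ooo_by_familiarity(t, std_gaussian, params, mode="most")
        least = ooo_by_familiarity(t, std_gaussian, params, mode="least")
        assert np.argmax(most) == 0  # densest stimulus
        assert np.argmax(least) == 2  # least familiar stimulus

    def test_rank_reversal_between_modes(self, bimodal, gen_params, space):
        rng = np.random.default_rng(11)
        t = Trial(ODD_ONE_OUT, rng.uniform(-3, 3, (3, 2)), space)
        most = ooo_by_familiarity(t, bimodal, gen_params, mode="most")
        least = ooo_by_familiarity(t, bimodal, gen_params, mode="least")
        assert np.array_equal(np.argsort(most), np.argsort(least)[::-1])

    def test_wrong_task_rejected(self, std_gaussian, gen_params, space):
        t = Trial(FAMILIARITY, np.zeros((2, 2)), space)
        with pytest.raises(ValueError):
            ooo_by_familiarity(t, std_gaussian, gen_params)
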
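"""Ideal-observer inference steps, knowledge variants, and the full loop."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynbias.observer import (
    ObserverConfig,
    cue_likelihood,
    decide,
    make_model_variant,
    orientation_posterior,
    predict_next_belief,
    run_observer,
    stimulus_prior,
    transition_matrix,
    update_context_posterior,
)
from dynbias.task import (
    TaskConfig,
    default_context_pmfs,
    sample_measurements,
    simulate_trials,
)

GRID = np.array([-7.5, -5.0, -2.5, 0.0, 2.5, 5.0, 7.5])


class TestTransitionMatrix:
    def test_zero_hazard_identity(self):
        assert np.allclose(transition_matrix(0.0, 3), np.eye(3))

    def test_maximally_volatile_is_memoryless(self):
        assert np.allclose(transition_matrix(2 / 3, 3), np.full((3, 3), 1 / 3))

    def test_h20(self):
        T = transition_matrix(0.2, 3)
        assert np.allclose(np.diag(T), 0.8)
        assert np.allclose(T[~np.eye(3, dtype=bool)], 0.1)
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_too_few_contexts_raises(self):
        with pytest.raises(ValueError):
            transition_matrix(0.2, 1)


class TestCueLikelihood:
    def test_zero_kappa_uniform(self):
        cfg = ObserverConfig(assumed_kappa=0.0)
        lik = cue_likelihood(1.234, cfg)
        assert np.allclose(lik, 1 / (2 * np.pi))

    def test_cue_at_label_is_maximal(self):
        cfg = ObserverConfig(assumed_kappa=2.0)
        lik = cue_likelihood(cfg.context_labels[1], cfg)
        assert lik.argmax() == 1

    def test_midpoint_cue_is_ambiguous(self):
        cfg = ObserverConfig(assumed_kappa=2.0)
        mid = (cfg.context_labels[0] + cfg.context_labels[1]) / 2
        lik = cue_likelihood(mid, cfg)
        assert np.isclose(lik[0], lik[1])


class TestBeliefUpdates:
    def test_uniform_times_uniform(self):
        post = update_context_posterior(np.full(3, 1 / 3), np.ones(3))
        assert np.allclose(post, 1 / 3)

    def test_absorbing_prior(self):
        post = update_context_posterior(np.array([1.0, 0, 0]), np.array([0.2, 5.0, 3.0]))
        assert np.allclose(post, [1, 0, 0])

    def test_degenerate_product_raises(self):
        with pytest.raises(FloatingPointError):
            update_context_posterior(np.array([1.0, 0, 0]), np.array([0.0, 1.0, 1.0]))

    def test_stimulus_prior_selects_and_mixes(self):
        pmfs = default_context_pmfs()
        assert np.allclose(stimulus_prior(np.array([0, 1.0, 0]), pmfs), pmfs[1])
        mix = stimulus_prior(np.array([0.5, 0, 0.5]), pmfs)
        assert np.allclose(mix, (pmfs[0] + pmfs[2]) / 2)

    def test_predict_next_belief(self):
        b = np.array([1.0, 0, 0])
        assert np.allclose(predict_next_belief(b, transition_matrix(0.0, 3)), b)
        assert np.allclose(
            predict_next_belief(b, transition_matrix(2 / 3, 3)), np.full(3, 1 / 3)
        )
        assert np.allclose(
            predict_next_belief(b, transition_matrix(0.2, 3)), [0.8, 0.1, 0.1]
        )

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0.0, 2 * np.pi), min_size=1, max_size=20))
    def test_belief_stays_normalized(self, cues):
        cfg = ObserverConfig(assumed_kappa=1.5, assumed_hazard=0.3)
        T = transition_matrix(0.3, 3)
        b = np.full(3, 1 / 3)
        for c in cues:
            b = update_context_posterior(b, cue_likelihood(c, cfg))
            assert abs(b.sum() - 1.0) < 1e-10
            assert (b >= 0).all()
            b = predict_next_belief(b, T)


class TestOrientationPosterior:
    def test_symmetric_measurement(self):
        post = orientation_posterior(0.0, np.full(7, 1 / 7), 5.0, GRID)
        assert np.isclose(post[GRID > 0].sum(), post[GRID < 0].sum())

    def test_flat_likelihood_limit_returns_prior(self):
        prior = default_context_pmfs()[2]
        post = orientation_posterior(3.0, prior, 1e8, GRID)
        assert np.abs(post - prior).max() < 1e-6

    def test_hand_computed_product(self):
        y, scale = 5.0, 10.0
        prior = np.full(7, 1 / 7)
        expect = prior * np.exp(-((y - GRID) ** 2) / (2 * scale**2))
        expect /= expect.sum()
        assert np.allclose(orientation_posterior(y, prior, scale, GRID), expect, atol=1e-12)

    def test_extreme_measurement_no_nan(self):
        post = orientation_posterior(1e6, np.full(7, 1 / 7), 2.0, GRID)
        assert np.isfinite(post).all()
        assert np.isclose(post.sum(), 1.0)


class TestDecide:
    def test_all_mass_clockwise(self):
        post = np.zeros(7)
        post[GRID > 0] = 1 / 3
        choice, p = decide(post, GRID)
        assert choice == 1 and p == 1.0

    def test_symmetric_posterior_literal_rule_tilts_ccw(self):
        # the literal printed rule excludes vertical mass from p_cw, so a
        # symmetric posterior has p_cw < 0.5 and is judged counter-clockwise
        post = np.full(7, 1 / 7)
        choice, p = decide(post, GRID)
        assert p < 0.5 and choice == -1

    def test_symmetric_posterior_split_rule_is_coin(self):
        post = np.full(7, 1 / 7)
        _, p = decide(post, GRID, split_zero=True)
        assert p == 0.5

    def test_point_mass_ccw(self):
        post = np.zeros(7)
        post[GRID == -2.5] = 1.0
        choice, _ = decide(post, GRID)
        assert choice == -1


def _path_sum_posterior(cues, kappa, hazard):
    """Exhaustive HMM oracle: sum over all 3^T context paths."""
    from dynbias.observer import _von_mises_likelihoods

    labels = ObserverConfig().context_labels
    lik = _von_mises_likelihoods(np.asarray(cues), labels, kappa)
    T = transition_matrix(hazard, 3)
    post = np.zeros(3)
    for path in itertools.product(range(3), repeat=len(cues)):
        w = 1.0 / 3.0
        for t, c in enumerate(path):
            if t > 0:
                w *= T[path[t - 1], c]
            w *= lik[t, c]
        post[path[-1]] += w
    return post / post.sum()


class TestFullLoop:
    def test_filtering_matches_path_sum_oracle(self):
        rng = np.random.default_rng(3)
        cues = rng.uniform(0, 2 * np.pi, 8)
        cfg = TaskConfig(n_trials=8, hazard=0.3, cue_kappa=1.5, seed=0)
        trials = simulate_trials(cfg)
        trials.cue[:] = cues
        obs = make_model_variant(4, cfg, assumed_hazard=0.3)
        y = np.zeros(8)
        trace = run_observer(trials, y, obs)
        oracle = _path_sum_posterior(cues, 1.5, 0.3)
        assert np.abs(trace.posterior_belief[-1] - oracle).max() < 1e-10

    def test_variant1_decision_is_sign_of_measurement(self):
        cfg = TaskConfig.ladder(5000, seed=6)
        trials = simulate_trials(cfg)
        rng = np.random.default_rng(8)
        y = sample_measurements(trials.orientation, trials.contrast, cfg, rng)
        trace = run_observer(trials, y, make_model_variant(1, cfg))
        nz = y != 0
        assert (trace.choice[nz] == np.sign(y[nz])).all()

    def test_variant4_flat_dynamics_equals_variant3(self):
        cfg = TaskConfig.ladder(5000, seed=6)
        trials = simulate_trials(cfg)
        y = sample_measurements(
            trials.orientation, trials.contrast, cfg, np.random.default_rng(8)
        )
        t3 = run_observer(trials, y, make_model_variant(3, cfg), np.random.default_rng(1))
        t4 = run_observer(
            trials, y, make_model_variant(4, cfg, assumed_hazard=2 / 3), np.random.default_rng(1)
        )
        assert (t3.choice == t4.choice).all()
        assert np.allclose(t3.p_cw, t4.p_cw)

    def test_tiny_noise_perfect_on_tilted_trials(self):
        cfg = TaskConfig(n_trials=2000, gen_noise={"high": 1e-6, "low": 1e-6}, seed=2)
        trials = simulate_trials(cfg)
        y = sample_measurements(
            trials.orientation, trials.contrast, cfg, np.random.default_rng(4)
        )
        trace = run_observer(trials, y, make_model_variant(1, cfg))
        tilted = trials.orientation != 0
        assert (trace.choice[tilted] == np.sign(trials.orientation[tilted])).all()

    def test_length_mismatch_raises(self):
        cfg = TaskConfig(n_trials=10, seed=2)
        trials = simulate_trials(cfg)
        with pytest.raises(ValueError):
            run_observer(trials, np.zeros(5), make_model_variant(1, cfg))

    def test_trace_pmfs_normalized(self):
        cfg = TaskConfig(n_trials=500, seed=2)
        trials = simulate_trials(cfg)
        y = sample_measurements(
            trials.orientation, trials.contrast, cfg, np.random.default_rng(4)
        )
        trace = run_observer(trials, y, make_model_variant(4, cfg))
        assert np.abs(trace.posterior_belief.sum(axis=1) - 1).max() < 1e-10
        assert np.isfinite(trace.p_cw).all()


class TestVariants:
    def test_invalid_variant_raises(self):
        cfg = TaskConfig(n_trials=10)
        with pytest.raises(ValueError):
            make_model_variant(5, cfg)

    def test_pooled_noise_is_rms(self):
        cfg = TaskConfig(n_trials=10, gen_noise={"high": 10.0, "low": 20.0})
        v1 = make_model_variant(1, cfg)
        pooled = v1.noise_for(np.array([True, False]))
        assert np.allclose(pooled, np.sqrt((100 + 400) / 2))

    def test_variant_knowledge_flags(self):
        cfg = TaskConfig(n_trials=10)
        flags = [
            (
                make_model_variant(k, cfg).knows_context_priors,
                make_model_variant(k, cfg).knows_contrast_noise,
                make_model_variant(k, cfg).knows_dynamics,
            )
            for k in (1, 2, 3, 4)
        ]
        assert flags == [
            (False, False, False),
            (True, False, False),
            (True, True, False),
            (True, True, True),
        ]
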
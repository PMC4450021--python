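"""AIMMPF: mixing, prediction, weighting, mode probabilities, resampling."""

import numpy as np
import pytest

from aimmtrack import aimmpf
from aimmtrack.aimmpf import (
    FilterConfig,
    acv_only_config,
    estimate,
    make_bank,
    mix,
    predict,
    resample,
    step,
    systematic_resample,
    update,
    update_mode_probs,
)


def small_config(**kw):
    defaults = dict(n_particles=100)
    defaults.update(kw)
    return FilterConfig(**defaults)


@pytest.fixture
def bank(rng):
    return make_bank(50.0, 60.0, 100.0, small_config(), rng)


class TestMix:
    def test_identity_transitions_keep_clouds(self, rng):
        cfg = small_config(trans=np.eye(3), init_mode_probs=np.array([0.4, 0.3, 0.3]))
        b = make_bank(0, 0, 10, cfg, rng)
        for j in range(3):
            b.particles[j][:, 0] = j * 100.0  # make clouds distinct
        mixed, c_bar = mix(b, rng)
        np.testing.assert_allclose(c_bar, [0.4, 0.3, 0.3])
        for j in range(3):
            # uniform weights + systematic scheme: exact multiset preserved
            assert set(mixed.particles[j][:, 0]) == {j * 100.0}

    def test_predicted_mode_probs_are_markov_product(self, bank, rng):
        bank.mode_probs = np.array([1.0, 0.0, 0.0])
        _, c_bar = mix(bank, rng)
        np.testing.assert_allclose(c_bar, [0.8, 0.1, 0.1])

    def test_uniform_everything_stays_uniform(self, rng):
        cfg = small_config(
            trans=np.full((3, 3), 1 / 3), init_mode_probs=np.full(3, 1 / 3)
        )
        b = make_bank(0, 0, 10, cfg, rng)
        _, c_bar = mix(b, rng)
        np.testing.assert_allclose(c_bar, np.full(3, 1 / 3))

    def test_degenerate_transition_raises(self, bank, rng):
        bank.trans = np.zeros((3, 3))
        bank.mode_probs = np.zeros(3)
        with pytest.raises(FloatingPointError):
            mix(bank, rng)


class TestPredict:
    def test_noiseless_deterministic_and_acv_act_agree_at_zero_omega(self, rng):
        cfg = small_config(Q={m: np.zeros(6) for m in ("acv", "act1", "act2")})
        b = make_bank(10, 10, 50, cfg, rng)
        for j in range(3):
            b.particles[j] = np.tile([10.0, 10.0, 2.0, 1.0, 0.0, 50.0], (100, 1))
        out = predict(b, 1.0, 1.0, cfg, rng)
        np.testing.assert_allclose(out.particles[0], out.particles[1])
        np.testing.assert_allclose(out.particles[0][0, :2], [12.0, 11.0])

    def test_lambda_doubles_act1_areas(self, rng):
        cfg = small_config(Q={m: np.zeros(6) for m in ("acv", "act1", "act2")})
        b = make_bank(0, 0, 50, cfg, rng)
        b.particles[1][:, 5] = 50.0
        b.particles[1][:, 4] = 0.0
        out = predict(b, 2.0, 1.0, cfg, rng)
        np.testing.assert_allclose(out.particles[1][:, 5], 100.0)

    def test_cloud_spread_grows_per_gqgt(self, rng):
        q = np.array([30.0, 30.0, 0.1, 0.1, 0.01, 0.01])
        cfg = FilterConfig(n_particles=50000, Q={m: q for m in ("acv", "act1", "act2")})
        b = make_bank(0, 0, 50, cfg, rng)
        b.particles[0] = np.tile([0.0, 0.0, 1.0, 0.0, 0.0, 50.0], (50000, 1))
        out = predict(b, 1.0, 0.5, cfg, rng)
        expected = np.array([30.0 / 4, 30.0 / 4, 0.1, 0.1, 0.01, 0.01])
        np.testing.assert_allclose(out.particles[0].var(axis=0), expected, rtol=0.05)

    @pytest.mark.parametrize("lam,kap", [(0.5, 0.0), (2.5, 0.0), (1.0, -0.1), (1.0, 1.5)])
    def test_control_bounds_enforced(self, bank, rng, lam, kap):
        with pytest.raises(ValueError):
            predict(bank, lam, kap, small_config(), rng)


class TestUpdate:
    def test_identical_particles_get_uniform_weights(self, rng):
        cfg = small_config()
        b = make_bank(0, 0, 50, cfg, rng)
        for j in range(3):
            b.particles[j] = np.tile([5.0, 5.0, 0.0, 0.0, 0.0, 50.0], (100, 1))
        out, loglik = update(b, np.array([5.0, 5.0, 50.0]), np.ones(3))
        np.testing.assert_allclose(out.weights, 1.0 / 100)
        assert np.all(np.isfinite(loglik))

    def test_two_particle_gaussian_ratio(self, rng):
        cfg = FilterConfig(n_particles=2)
        b = make_bank(0, 0, 50, cfg, rng)
        b.particles[0] = np.array(
            [[0.0, 0.0, 0, 0, 0, 50.0], [3.0, 4.0, 0, 0, 0, 50.0]]
        )
        out, _ = update(b, np.array([0.0, 0.0, 50.0]), np.ones(3))
        ratio = out.weights[0][1] / out.weights[0][0]
        assert ratio == pytest.approx(np.exp(-25.0 / 2.0), rel=1e-9)

    def test_likelihood_invariant_to_particle_order(self, rng):
        cfg = small_config()
        b = make_bank(0, 0, 50, cfg, rng)
        _, ll1 = update(b, np.array([1.0, 2.0, 50.0]), np.ones(3))
        perm = rng.permutation(100)
        b2 = b.copy()
        for j in range(3):
            b2.particles[j] = b.particles[j][perm]
        _, ll2 = update(b2, np.array([1.0, 2.0, 50.0]), np.ones(3))
        np.testing.assert_allclose(ll1, ll2)

    def test_survives_extreme_mismatch(self, rng):
        # a measurement absurdly far away must not produce NaNs or crash
        b = make_bank(0, 0, 50, small_config(), rng)
        out, loglik = update(b, np.array([1e6, 1e6, 1e6]), np.ones(3))
        assert np.all(np.isfinite(out.weights))


class TestModeProbs:
    def test_equal_likelihoods_return_prior(self):
        c = np.array([0.5, 0.3, 0.2])
        probs, flag = update_mode_probs(c, np.log([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(probs, c)
        assert not flag

    def test_single_surviving_mode(self):
        probs, _ = update_mode_probs(
            np.array([0.8, 0.1, 0.1]), np.array([0.0, -np.inf, -np.inf])
        )
        np.testing.assert_allclose(probs, [1.0, 0.0, 0.0])

    def test_arithmetic_example(self):
        probs, _ = update_mode_probs(
            np.array([0.8, 0.1, 0.1]), np.log([1.0, 2.0, 1.0])
        )
        np.testing.assert_allclose(probs, np.array([0.8, 0.2, 0.1]) / 1.1)

    def test_all_zero_likelihood_keeps_prior(self):
        c = np.array([0.8, 0.1, 0.1])
        probs, flag = update_mode_probs(c, np.full(3, -np.inf))
        np.testing.assert_allclose(probs, c)
        assert flag

    def test_huge_dynamic_range_between_modes(self):
        # log-space update must resolve likelihood ratios far below float
        # underflow (e.g. a doubled area at a merge)
        probs, _ = update_mode_probs(
            np.array([0.8, 0.1, 0.1]), np.array([-1250.0, -130.0, -4500.0])
        )
        assert probs[1] > 0.999


class TestResample:
    def test_degenerate_weight_gives_n_copies(self, rng):
        parts = np.arange(30, dtype=float).reshape(5, 6)
        w = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        out, w2 = resample(parts, w, rng)
        assert np.all(out == parts[2])
        np.testing.assert_allclose(w2, 0.2)

    def test_systematic_copy_count_deviation_below_one(self, rng):
        w = rng.dirichlet(np.ones(50))
        idx = systematic_resample(w, rng, 1000)
        counts = np.bincount(idx, minlength=50)
        assert np.all(np.abs(counts - 1000 * w) <= 1.0)

    def test_uniform_weights_preserve_multiset(self, rng):
        parts = rng.normal(size=(8, 6))
        out, _ = resample(parts, np.full(8, 1 / 8), rng)
        np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(parts[:, 0]))


class TestEstimate:
    def test_single_mode_mean(self, bank):
        bank.mode_probs = np.array([1.0, 0.0, 0.0])
        _, est = estimate(bank)
        np.testing.assert_allclose(
            est.state.to_array(),
            bank.particles[0].mean(axis=0),
        )

    def test_combined_equals_brute_force_sum(self, bank, rng):
        bank.mode_probs = np.array([0.5, 0.3, 0.2])
        for j in range(3):
            w = rng.dirichlet(np.ones(100))
            bank.weights[j] = w
        _, est = estimate(bank)
        brute = np.zeros(6)
        for j in range(3):
            for i in range(100):
                brute += bank.mode_probs[j] * bank.weights[j][i] * bank.particles[j][i]
        np.testing.assert_allclose(est.state.to_array(), brute)

    def test_turn_rate_feedback_written_back(self, bank):
        bank.particles[1][:, 4] = 0.42
        bank.particles[2][:, 4] = -0.13
        out, _ = estimate(bank)
        np.testing.assert_allclose(out.omega_hat, [0.42, -0.13])


class TestStep:
    def test_mode_probs_remain_distribution(self, rng):
        cfg = small_config()
        b = make_bank(0, 0, 50, cfg, rng)
        for k in range(10):
            z = np.array([2.0 * k, 0.0, 50.0])
            b, est = step(b, z, cfg, rng, frame=k)
            assert est.mode_probs.sum() == pytest.approx(1.0)
            assert np.all(est.mode_probs >= 0)
            np.testing.assert_allclose(b.weights.sum(axis=1), 1.0)

    def test_missed_detection_grows_spread_without_crash(self, rng):
        cfg = small_config()
        b = make_bank(0, 0, 50, cfg, rng)
        b, _ = step(b, np.array([0.0, 0.0, 50.0]), cfg, rng)
        spread_before = b.particles[0][:, :2].std()
        b, est = step(b, None, cfg, rng)
        spread_after = b.particles[0][:, :2].std()
        assert spread_after > spread_before
        assert est.mode_probs.sum() == pytest.approx(1.0)

    def test_bit_reproducible_under_fixed_seed(self):
        cfg = small_config()
        outs = []
        for _ in range(2):
            r = np.random.default_rng(99)
            b = make_bank(0, 0, 50, cfg, r)
            states = []
            for k in range(5):
                b, est = step(b, np.array([k * 1.0, 0.0, 50.0]), cfg, r)
                states.append(est.state.to_array())
            outs.append(np.array(states))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_acv_only_reduces_to_bootstrap_filter(self, rng):
        # with identity transitions and all mass on ACV the other clouds
        # never influence the estimate
        cfg = acv_only_config(small_config())
        b = make_bank(0, 0, 50, cfg, rng)
        for k in range(5):
            b, est = step(b, np.array([2.0 * k, k * 1.0, 50.0]), cfg, rng)
        np.testing.assert_allclose(est.mode_probs, [1.0, 0.0, 0.0])
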
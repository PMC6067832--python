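"""Hebbian learning, homeostasis and training-loop contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gcalsim as g
from gcalsim.model import build_model
from gcalsim.plasticity import hebbian_update, homeostatic_update, train

from conftest import tiny_config


class TestHebbianUpdate:
    def test_toy_two_weight_oracle(self):
        """w=(0.5,0.5), pre=(1,0), post=1, alpha=0.1 -> (0.6,0.5)/1.1."""
        w = np.array([[0.5, 0.5]])
        mask = np.ones_like(w)
        pre = np.array([[1.0, 0.0]])
        post = np.array([1.0])
        hebbian_update(w, mask, pre, post, alpha=0.1)
        np.testing.assert_allclose(w, [[0.6 / 1.1, 0.5 / 1.1]], atol=1e-12)

    def test_zero_alpha_is_bitwise_noop(self):
        rng = np.random.default_rng(0)
        w = rng.random((5, 7))
        w /= w.sum(1, keepdims=True)
        before = w.copy()
        hebbian_update(w, np.ones_like(w), rng.random((5, 7)), rng.random(5), 0.0)
        np.testing.assert_array_equal(w, before)

    def test_silent_postsynaptic_units_unchanged(self):
        rng = np.random.default_rng(1)
        w = rng.random((4, 6))
        w /= w.sum(1, keepdims=True)
        before = w.copy()
        post = np.array([0.0, 1.0, 0.0, 0.0])
        hebbian_update(w, np.ones_like(w), rng.random((4, 6)), post, 0.05)
        np.testing.assert_array_equal(w[[0, 2, 3]], before[[0, 2, 3]])
        assert not np.array_equal(w[1], before[1])

    def test_normalization_conserved(self):
        rng = np.random.default_rng(2)
        mask = (rng.random((8, 10)) > 0.2).astype(float)
        w = rng.random((8, 10)) * mask
        w /= w.sum(1, keepdims=True)
        hebbian_update(w, mask, rng.random((8, 10)), rng.random(8), 0.3)
        np.testing.assert_allclose(w.sum(1), 1.0, atol=1e-9)
        assert np.all(w[mask == 0] == 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**16),
        alpha=st.floats(0.0, 5.0),
        n=st.integers(1, 6),
        p=st.integers(1, 12),
    )
    def test_conservation_holds_for_arbitrary_updates(self, seed, alpha, n, p):
        """Per-unit weight sums stay 1 and masked weights stay 0 for any
        nonnegative activities and rate."""
        rng = np.random.default_rng(seed)
        mask = (rng.random((n, p)) > 0.3).astype(float)
        mask[:, 0] = 1.0  # every unit keeps at least one connection
        w = (rng.random((n, p)) + 1e-3) * mask
        w /= w.sum(1, keepdims=True)
        hebbian_update(w, mask, rng.random((n, p)), rng.random(n), alpha)
        np.testing.assert_allclose(w.sum(1), 1.0, atol=1e-9)
        assert np.all(w[mask == 0] == 0)
        assert np.all(w >= 0)


class TestHomeostasis:
    def test_frozen_when_rate_zero(self):
        st = build_model(tiny_config(), seed=0)
        st.config.homeostasis.adaptation_rate = 0.0
        before = st.theta.copy()
        homeostatic_update(st, np.random.default_rng(0).random(st.theta.shape))
        np.testing.assert_array_equal(st.theta, before)

    def test_fixed_point_at_target_activity(self):
        st = build_model(tiny_config(), seed=0)
        mu = st.config.homeostasis.target_activity
        eta = np.full(st.theta.shape, mu)
        for _ in range(500):
            homeostatic_update(st, eta)
        prev = st.theta.copy()
        homeostatic_update(st, eta)
        assert np.abs(st.theta - prev).max() < 1e-6

    def test_threshold_increases_monotonically_for_pinned_unit(self):
        """A unit pinned at activity 1 with mu < 1 raises its threshold forever."""
        st = build_model(tiny_config(), seed=0)
        eta = np.ones(st.theta.shape)
        last = st.theta.copy()
        for _ in range(20):
            homeostatic_update(st, eta)
            assert np.all(st.theta > last)
            last = st.theta.copy()


class TestTrain:
    def test_zero_iterations_is_noop(self):
        st = build_model(tiny_config(), seed=0)
        h = st.content_hash()
        train(st, 0)
        assert st.content_hash() == h
        assert st.iteration == 0

    def test_training_is_deterministic(self):
        a = build_model(tiny_config(), seed=9)
        b = build_model(tiny_config(), seed=9)
        train(a, 30, log_every=0)
        train(b, 30, log_every=0)
        np.testing.assert_array_equal(a.afferent.w, b.afferent.w)
        np.testing.assert_array_equal(a.theta, b.theta)
        assert a.content_hash() == b.content_hash()

    def test_weight_sums_conserved_through_training(self):
        st = build_model(tiny_config(), seed=4)
        train(st, 50, log_every=0)
        for proj in st.projections().values():
            np.testing.assert_allclose(proj.w.sum(axis=1), 1.0, atol=1e-9)

    def test_activity_trace_approaches_target(self, baselines):
        """Homeostasis drives the long-run mean V1 activity toward mu."""
        st = baselines[0]
        mu = st.config.homeostasis.target_activity
        assert st.ybar.mean() == pytest.approx(mu, rel=0.25)

    def test_homeostasis_recovers_after_drive_reduction(self, baselines):
        """Halving afferent strengths: training returns activity to ~mu."""
        st = baselines[0].copy()
        st.config.retina_to_lgn.strength *= 0.5
        st.config.lgn_to_v1.strength *= 0.5
        train(st, 2000, log_every=0)
        mu = st.config.homeostasis.target_activity
        assert st.ybar.mean() == pytest.approx(mu, rel=0.25)
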
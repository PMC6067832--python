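"""Core machinery: DoG filtering, LGN gain control, recurrent settling.

Brute-force oracles here are deliberately naive (explicit python loops over
kernels and units) and independent of the package's vectorized/compiled paths.
"""

import numpy as np
import pytest

import gcalsim as g
from gcalsim import _kernels
from gcalsim.config import ConfigurationError, default_config
from gcalsim.geometry import SheetGeometry
from gcalsim.model import (
    DoGParams,
    SettlingError,
    afferent_drive,
    build_model,
    dog_kernel,
    dog_response,
    lgn_step,
    v1_settle,
)
from gcalsim.stimuli import GratingSpec, grating

from conftest import tiny_config


PARAMS = DoGParams(sigma_center=0.036925, sigma_surround=0.1477)


def naive_dog(image, kernel):
    """Explicitly summed valid-mode correlation."""
    kh = kernel.shape[0]
    out = np.zeros((image.shape[0] - kh + 1, image.shape[1] - kh + 1))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            acc = 0.0
            for i in range(kh):
                for j in range(kh):
                    acc += image[r + i, c + j] * kernel[i, j]
            out[r, c] = acc
    return out


class TestBuildModel:
    def test_determinism(self):
        a = build_model(seed=42)
        b = build_model(seed=42)
        assert a.content_hash() == b.content_hash()
        np.testing.assert_array_equal(a.afferent.w, b.afferent.w)

    def test_default_sheet_sizes(self):
        st = build_model(seed=0)
        assert st.sheets["v1"].shape == (48, 48)
        assert st.sheets["lgn_on"].shape == st.sheets["lgn_off"].shape
        assert st.sheets["lgn_on"].density == 24
        # 4x the units per visual area: double density in each dimension
        assert st.sheets["v1"].density == 2 * st.sheets["lgn_on"].density

    def test_plastic_weight_sums_are_one(self):
        st = build_model(seed=3)
        for proj in st.projections().values():
            np.testing.assert_allclose(proj.w.sum(axis=1), 1.0, atol=1e-9)

    def test_oversized_radius_names_projection(self):
        cfg = default_config()
        cfg.lgn_to_v1.radius = 5.0
        with pytest.raises(ConfigurationError, match="lgn_to_v1"):
            build_model(cfg, seed=0)


class TestDoGResponse:
    def test_uniform_image_zero_drive(self):
        image = np.full((40, 40), 0.5)
        drive = dog_response(image, PARAMS, radius=0.375, density=24)
        assert np.abs(drive).max() < 1e-12

    def test_point_source_center_surround_shape(self):
        image = np.zeros((41, 41))
        image[20, 20] = 1.0
        drive = dog_response(image, PARAMS, radius=0.375, density=24)
        c = drive.shape[0] // 2
        assert drive[c, c] > 0  # positive On drive at the source
        assert drive[c, c + 3] < 0  # negative annulus around it

    def test_on_off_antisymmetry_vs_naive_oracle(self):
        """On drive of I equals Off drive of (1-I); both match the loop oracle."""
        rng = np.random.default_rng(5)
        image = rng.random((24, 24))
        kern = dog_kernel(PARAMS, radius=0.25, density=24)
        on = dog_response(image, PARAMS, radius=0.25, density=24)
        off_params = DoGParams(PARAMS.sigma_center, PARAMS.sigma_surround, "off_center")
        off_of_inverse = dog_response(1.0 - image, off_params, radius=0.25, density=24)
        np.testing.assert_allclose(on, off_of_inverse, atol=1e-9)
        np.testing.assert_allclose(on, naive_dog(image, kern), atol=1e-9)


class TestLgnStep:
    def test_zero_contrast_silent(self):
        st = build_model(seed=0)
        img = grating(GratingSpec(1.5, 0.0), st.sheets["retina"])
        on, off = lgn_step(st, img)
        assert np.abs(on).max() < 1e-9 and np.abs(off).max() < 1e-9

    def test_contrast_ratio_linear_without_gain_control(self):
        """Without gain control the response is linear in contrast (ratio 4)."""
        cfg = default_config()
        cfg.lgn_gain_control.strength = 0.0
        st = build_model(cfg, seed=0)
        # contrasts low enough that the undivided response stays below 1
        hi = lgn_step(st, grating(GratingSpec(6.0, 0.08), st.sheets["retina"]))[0]
        lo = lgn_step(st, grating(GratingSpec(6.0, 0.02), st.sheets["retina"]))[0]
        active = lo > 1e-6
        assert active.any()
        assert hi.max() < 1.0  # no clipping in this regime
        np.testing.assert_allclose(hi[active] / lo[active], 4.0, atol=1e-6)

    def test_gain_control_is_compressive(self):
        st = build_model(seed=0)
        hi = lgn_step(st, grating(GratingSpec(6.0, 0.80), st.sheets["retina"]))[0]
        lo = lgn_step(st, grating(GratingSpec(6.0, 0.20), st.sheets["retina"]))[0]
        active = lo > 1e-3
        ratios = hi[active] / lo[active]
        assert np.all(ratios < 4.0)

    def test_reducing_gain_control_does_not_decrease_output(self):
        cfg = default_config()
        st = build_model(cfg, seed=0)
        img = grating(GratingSpec(1.5, 0.80), st.sheets["retina"])
        full = lgn_step(st, img)[0]
        st.config.lgn_gain_control.strength *= 0.5
        halved = lgn_step(st, img)[0]
        assert halved.mean() >= full.mean() - 1e-12

    def test_compression_ratio_smaller_with_gain_control(self):
        """80%/5% LGN mean-response ratio shrinks when gain control is on."""
        def ratio(gs):
            cfg = default_config()
            cfg.lgn_gain_control.strength = gs
            st = build_model(cfg, seed=0)
            hi = lgn_step(st, grating(GratingSpec(6.0, 0.80), st.sheets["retina"]))[0]
            lo = lgn_step(st, grating(GratingSpec(6.0, 0.05), st.sheets["retina"]))[0]
            return hi.mean() / lo.mean()

        assert ratio(default_config().lgn_gain_control.strength) < ratio(0.0)


class TestV1Settle:
    def test_zero_input_zero_activity(self):
        st = build_model(seed=0)
        zero = np.zeros(st.sheets["lgn_on"].shape)
        v1 = v1_settle(st, zero, zero)
        assert np.abs(v1).max() == 0.0

    def test_single_unit_closed_form(self):
        """With no lateral interaction the output is f(gamma_A * x - theta)."""
        cfg = tiny_config()
        cfg.v1_lateral_excitatory.strength = 0.0
        cfg.v1_lateral_inhibitory.strength = 0.0
        st = build_model(cfg, seed=1)
        on = np.full(st.sheets["lgn_on"].shape, 0.4)
        off = np.full(st.sheets["lgn_off"].shape, 0.1)
        v1 = v1_settle(st, on, off)
        aff = afferent_drive(st, on, off)
        expected = np.clip(aff - st.theta, 0.0, 1.0).reshape(st.v1_shape)
        np.testing.assert_allclose(v1, expected, atol=1e-12)

    def test_matches_naive_double_loop_settler(self):
        """Settling equals an explicitly looped reference on a small sheet."""
        cfg = tiny_config()
        st = build_model(cfg, seed=2)
        rng = np.random.default_rng(0)
        on = rng.random(st.sheets["lgn_on"].shape) * 0.5
        off = rng.random(st.sheets["lgn_off"].shape) * 0.5
        v1 = v1_settle(st, on, off)

        # naive reference: per-unit loops over explicit patch index arrays
        aff = afferent_drive(st, on, off)
        theta = st.theta
        cfgv = st.config
        act = np.clip(aff - theta, 0, 1)
        nv1 = st.sheets["v1"].n_units
        for _ in range(cfgv.timecourse.settle_steps):
            new = np.empty(nv1)
            for i in range(nv1):
                e = sum(
                    st.lateral_exc.w[i, k] * act[st.lateral_exc.patches.idx[i, k]]
                    for k in range(st.lateral_exc.patches.idx.shape[1])
                )
                h = sum(
                    st.lateral_inh.w[i, k] * act[st.lateral_inh.patches.idx[i, k]]
                    for k in range(st.lateral_inh.patches.idx.shape[1])
                )
                x = (
                    aff[i]
                    + cfgv.v1_lateral_excitatory.strength * e
                    - cfgv.v1_lateral_inhibitory.strength * h
                    - theta[i]
                )
                new[i] = min(max(x, 0.0), 1.0)
            act = new
        np.testing.assert_allclose(v1.ravel(), act, atol=1e-9)

    def test_nonfinite_raises_with_step_index(self):
        st = build_model(tiny_config(), seed=0)
        st.theta[:] = np.nan
        on = np.full(st.sheets["lgn_on"].shape, 0.5)
        with pytest.raises(SettlingError):
            v1_settle(st, on, on)

    def test_activity_bounded_in_unit_interval(self):
        st = build_model(seed=0)
        img = grating(GratingSpec(6.0, 0.8), st.sheets["retina"])
        on, off = lgn_step(st, img)
        assert on.min() >= 0 and on.max() <= 1
        v1, trace = v1_settle(st, on, off, record=True)
        for step_act in trace:
            assert step_act.min() >= 0.0 and step_act.max() <= 1.0

    def test_rotational_equivariance_before_training(self):
        """Isotropic initial weights: 90 deg-rotated gratings give ~equal drive."""
        st = build_model(seed=11)
        a = v1_settle(st, *lgn_step(st, grating(GratingSpec(3.75, 0.8, np.pi / 2), st.sheets["retina"])))
        b = v1_settle(st, *lgn_step(st, grating(GratingSpec(3.75, 0.8, 0.0), st.sheets["retina"])))
        assert a.mean() == pytest.approx(b.mean(), rel=0.05)
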
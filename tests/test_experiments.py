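"""Perturbation mechanics and protocol plumbing."""

import dataclasses

import numpy as np
import pytest

import gcalsim as g
from gcalsim.config import ConfigurationError, get_path
from gcalsim.experiments import (
    CHRONIC_PERTURBATIONS,
    FES_PERTURBATIONS,
    PROTOCOLS,
    SWEEP_CLASSES,
    PerturbationSpec,
    apply_perturbation,
    invert_perturbation,
    run_protocol,
    sweep_protocols,
)
from gcalsim.model import build_model

from conftest import tiny_config


class TestApplyPerturbation:
    def test_scale_changes_only_named_scalar(self):
        st = build_model(tiny_config(), seed=0)
        w_before = st.afferent.w.copy()
        inh_before = st.config.v1_lateral_inhibitory.strength
        apply_perturbation(st, PerturbationSpec("v1_lateral_inhibitory.strength", "scale", 0.9))
        assert st.config.v1_lateral_inhibitory.strength == pytest.approx(0.9 * inh_before)
        np.testing.assert_array_equal(st.afferent.w, w_before)
        assert st.perturbation_log[-1]["parameter"] == "v1_lateral_inhibitory.strength"

    def test_triple_learning_rate_from_default(self):
        st = build_model(seed=0)
        assert st.config.lgn_to_v1.learning_rate == pytest.approx(0.01)
        apply_perturbation(st, PerturbationSpec("lgn_to_v1.learning_rate", "scale", 3.0))
        assert st.config.lgn_to_v1.learning_rate == pytest.approx(0.03)

    def test_identity_scale_only_logs(self):
        st = build_model(tiny_config(), seed=0)
        h_cfg = repr(st.config)
        apply_perturbation(st, PerturbationSpec("lgn_to_v1.strength", "scale", 1.0))
        assert repr(st.config) == h_cfg
        assert len(st.perturbation_log) == 1

    def test_unknown_path_is_rejected_with_guidance(self):
        st = build_model(tiny_config(), seed=0)
        with pytest.raises(ConfigurationError, match="valid"):
            apply_perturbation(st, PerturbationSpec("v1_lateral.bogus", "scale", 0.5))

    def test_apply_then_invert_restores_exact_state(self):
        st = build_model(tiny_config(), seed=0)
        before = st.config.v1_lateral_inhibitory.strength
        rec = apply_perturbation(st, PerturbationSpec("v1_lateral_inhibitory.strength", "scale", 0.9))
        invert_perturbation(st, rec)
        assert st.config.v1_lateral_inhibitory.strength == before  # bitwise


class TestRegistry:
    def test_best_fit_perturbation_magnitudes(self):
        chronic = {p.parameter: p for p in CHRONIC_PERTURBATIONS}
        assert chronic["v1_lateral_inhibitory.strength"].value == pytest.approx(0.90)
        assert chronic["lgn_to_v1.learning_rate"].value == pytest.approx(3.0)
        fes = {p.parameter: p for p in FES_PERTURBATIONS}
        assert fes["retina_to_lgn.strength"].value == pytest.approx(0.85)
        assert fes["lgn_to_v1.strength"].value == pytest.approx(0.85)

    def test_registry_contains_all_model_classes(self):
        for name in ("unmodified", "chronic_best", "fes_best", "fes_best_1k",
                     "model_b", "model_c", "model_d", "model_e", "model_f",
                     "model_g", "sequential"):
            assert name in PROTOCOLS

    def test_sweep_classes_cover_manipulated_parameters(self):
        params = {p for paths, _, _ in SWEEP_CLASSES.values() for p in paths}
        assert "lgn_gain_control.strength" in params
        assert "homeostasis.adaptation_rate" in params
        protos = sweep_protocols("lateral_inhibition_decrease")
        values = [p.phases[1].perturbations[0].value for p in protos]
        assert 0.90 in values and 0.50 in values


class TestRunProtocol:
    def test_run_is_deterministic(self):
        a = run_protocol("unmodified", 7, config=tiny_config(), pretrain=20, post=20, log_every=0)
        b = run_protocol("unmodified", 7, config=tiny_config(), pretrain=20, post=20, log_every=0)
        pd_a = a.checkpoints["continued"].contrast_table
        pd_b = b.checkpoints["continued"].contrast_table
        assert pd_a.equals(pd_b)
        assert a.final_state.content_hash() == b.final_state.content_hash()

    def test_cached_baseline_matches_uncached_run(self):
        """Continuing from a cached pretrain state equals the uninterrupted run."""
        cfg = tiny_config()
        base = g.build_model(cfg, seed=3)
        g.train(base, 25, log_every=0)
        cached = run_protocol("chronic_best", 3, initial_state=base, pretrain=25, post=15, log_every=0)
        direct = run_protocol("chronic_best", 3, config=cfg, pretrain=25, post=15, log_every=0)
        assert cached.final_state.content_hash() == direct.final_state.content_hash()

    def test_misaligned_cache_is_rejected(self):
        base = g.build_model(tiny_config(), seed=3)
        g.train(base, 13, log_every=0)
        with pytest.raises(ValueError, match="align"):
            run_protocol("chronic_best", 3, initial_state=base, pretrain=25, post=5, log_every=0)

    def test_sequential_restoration_preserves_weights(self):
        """Afferent strengths return to baseline; learned weights are untouched."""
        bundle = run_protocol(
            "sequential", 1, config=tiny_config(),
            pretrain=10, fes_iterations=5, chronic_iterations=0, log_every=0,
        )
        st = bundle.final_state
        pristine = g.default_config()
        assert st.config.retina_to_lgn.strength == pristine.retina_to_lgn.strength
        assert st.config.lgn_to_v1.strength == pristine.lgn_to_v1.strength
        restores = [e for e in st.perturbation_log if e["mode"] == "restore"]
        assert len(restores) == 2
        # chronic perturbations applied on top
        assert st.config.v1_lateral_inhibitory.strength == pytest.approx(
            0.9 * pristine.v1_lateral_inhibitory.strength
        )

    def test_manifest_records_phases_and_config(self):
        bundle = run_protocol("fes_best", 0, config=tiny_config(), pretrain=5, post=5, log_every=0)
        m = bundle.manifest
        assert m["protocol"] == "fes_best"
        assert [p["name"] for p in m["phases"]] == ["pretrain", "perturbed"]
        assert m["config"]["lgn_to_v1"]["strength"] == pytest.approx(
            0.85 * g.default_config().lgn_to_v1.strength
        )
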
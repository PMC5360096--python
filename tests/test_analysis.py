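"""Sparseness indices, visual selection, GMIs and gain-field classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gainfields import RBM, SpaceConfig
from gainfields.analysis import (POSTURAL_VARS, activity_fraction,
                                 analyze_gain_fields, classify_gain_fields,
                                 compute_gmi, population_sparseness,
                                 receptive_field, render_receptive_fields,
                                 select_visual_neurons,
                                 single_neuron_sparseness,
                                 sparseness_report)
from gainfields.stimuli import input_size, input_slices


class TestActivityFraction:
    def test_uniform_rates_give_one(self):
        assert activity_fraction(np.full(12, 3.7)) == pytest.approx(1.0)

    def test_one_hot_gives_one_over_n(self):
        r = np.zeros(10); r[3] = 5.0
        assert activity_fraction(r) == pytest.approx(0.1)

    def test_half_active(self):
        assert activity_fraction([1.0, 1.0, 0.0, 0.0]) == pytest.approx(0.5)

    def test_rejects_negative_and_all_zero(self):
        with pytest.raises(ValueError, match="non-negative"):
            activity_fraction([1.0, -0.1])
        with pytest.raises(ValueError, match="all-zero"):
            activity_fraction(np.zeros(4))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(
        st.one_of(st.just(0.0),
                  st.floats(min_value=1e-6, max_value=100.0)),
        min_size=2, max_size=50).filter(lambda r: sum(r) > 0))
    def test_bounds_and_scale_invariance(self, rates):
        r = np.array(rates)
        a = activity_fraction(r)
        assert 1.0 / len(r) - 1e-9 <= a <= 1.0 + 1e-9
        assert activity_fraction(3.5 * r) == pytest.approx(a)


class TestSparsenessMatrices:
    def test_uniform_matrix(self):
        acts = np.full((20, 8), 0.3)
        assert single_neuron_sparseness(acts) == pytest.approx(1.0)
        assert population_sparseness(acts) == pytest.approx(1.0)

    def test_one_stimulus_per_neuron(self):
        acts = np.eye(10)  # each neuron fires to exactly 1 of 10 stimuli
        assert single_neuron_sparseness(acts) == pytest.approx(0.1)
        assert population_sparseness(acts) == pytest.approx(0.1)

    def test_silent_neurons_excluded(self):
        acts = np.ones((5, 4))
        acts[:, 2] = 0.0
        rep = sparseness_report(acts)
        assert rep.n_silent_neurons == 1
        assert rep.single_neuron == pytest.approx(1.0)


def _section_probe(cfg, task, fn):
    """Probe callable computed from raw input sections."""
    slices = input_slices(cfg, task)

    def probe(X):
        return fn(np.asarray(X), slices)

    return probe


class TestVisualSelection:
    def test_probe_ignoring_retina_is_not_visual(self, cfg):
        probe = _section_probe(
            cfg, "no_transformation",
            lambda X, sl: 0.2 + 0.5 * X[:, sl["eye_x"]].mean(
                axis=1, keepdims=True))
        frame = select_visual_neurons(probe, cfg, stride=4)
        assert not frame["is_visual"].any()

    def test_probe_reading_one_retinal_unit_is_visual(self, cfg):
        probe = _section_probe(
            cfg, "no_transformation",
            lambda X, sl: 0.05 + X[:, [sl["retinal"].start + 144]])
        frame = select_visual_neurons(probe, cfg, stride=4)
        assert frame["is_visual"].all()

    @pytest.mark.parametrize("peak,visual", [(0.54, False), (0.56, True)])
    def test_threshold_arithmetic(self, cfg, peak, visual):
        # no-visual max 0.50; 8% change is below threshold, 12% above
        def fn(X, sl):
            has_vis = X[:, sl["retinal"]].max(axis=1, keepdims=True) > 0
            return np.where(has_vis, peak, 0.50)

        frame = select_visual_neurons(_section_probe(
            cfg, "no_transformation", fn), cfg, stride=4)
        assert bool(frame["is_visual"].iloc[0]) is visual


class TestGMI:
    def test_constant_sweep_gives_zero(self, cfg):
        probe = _section_probe(cfg, "no_transformation",
                               lambda X, sl: 0.1 + X[:, [sl["retinal"].start
                                                         + 144]])
        gmi = compute_gmi(probe, cfg, stride=4)
        assert np.allclose(gmi.values, 0.0, atol=1e-12)

    def test_zero_minimum_gives_one(self, cfg):
        # response proportional to the eye-x encoding of one postural unit,
        # rescaled so the sweep bottoms out at exactly zero
        def fn(X, sl):
            e = X[:, [sl["eye_x"].start + 8]]
            lo = 1.0 / (1.0 + np.exp(0.125 * 18.0))
            return np.clip(e - lo, 0.0, None) + 0.0 * e

        gmi = compute_gmi(_section_probe(cfg, "no_transformation", fn), cfg)
        assert gmi["gmi_eye_x"].iloc[0] == pytest.approx(1.0)

    def test_formula_midpoint(self):
        # sweep from 0.8 down to 0.4 -> (0.8 - 0.4) / 0.8 = 0.5
        sweep = np.linspace(0.8, 0.4, 13)
        assert (sweep.max() - sweep.min()) / sweep.max() == pytest.approx(0.5)

    def test_scale_invariance(self, cfg, tiny_dataset):
        # GMI is invariant to positive rescaling of the probe output
        m = RBM(n_hidden=3, n_epochs=3, random_state=0).fit(
            tiny_dataset.inputs("train")[:100])
        W, c = m.hidden_affine()

        def probe(X, scale=1.0):
            return scale / (1 + np.exp(-(np.asarray(X) @ W.T + c)))

        base = compute_gmi(lambda X: probe(X), cfg, stride=4)
        scaled = compute_gmi(lambda X: probe(X, 4.0), cfg, stride=4)
        assert np.allclose(base.values, scaled.values, atol=1e-12)

    def test_affine_fast_path_matches_bruteforce(self, cfg, tiny_dataset):
        m = RBM(n_hidden=4, n_epochs=3, random_state=1).fit(
            tiny_dataset.inputs("train")[:100])
        fast = analyze_gain_fields(m, cfg)
        W, c = m.hidden_affine()
        brute = analyze_gain_fields(
            lambda X: 1 / (1 + np.exp(-(np.asarray(X) @ W.T + c))), cfg)
        pd.testing.assert_series_equal(
            fast.profiles["is_visual"], brute.profiles["is_visual"])
        for var in POSTURAL_VARS:
            assert np.allclose(fast.profiles[f"gmi_{var}"],
                               brute.profiles[f"gmi_{var}"], atol=1e-10)


class TestClassification:
    def _gmi_frame(self, rows):
        return pd.DataFrame(rows, columns=[f"gmi_{v}" for v in POSTURAL_VARS])

    def test_category_logic(self):
        gmi = self._gmi_frame([
            [0.0, 0.0, 0.0, 0.0],     # pure visual
            [0.9, 0.0, 0.0, 0.0],     # eye only
            [0.0, 0.0, 0.8, 0.1],     # effector only
            [0.0, 0.6, 0.7, 0.0],     # multiple
            [0.5, 0.0, 0.5, 0.0],     # threshold is inclusive
        ])
        cats = classify_gain_fields(gmi)
        assert list(cats) == ["pure_visual", "eye_only", "effector_only",
                              "multiple", "multiple"]

    def test_nonvisual_carry_no_category(self):
        gmi = self._gmi_frame([[0.9, 0, 0, 0], [0.9, 0, 0, 0]])
        cats = classify_gain_fields(gmi, is_visual=[True, False])
        assert cats.iloc[0] == "eye_only" and pd.isna(cats.iloc[1])

    def test_distribution_partitions_visual_neurons(self, cfg, tiny_dataset):
        m = RBM(n_hidden=12, n_epochs=5, sparsity_target=0.1,
                random_state=2).fit(tiny_dataset.inputs("train"))
        ga = analyze_gain_fields(m, cfg)
        fr = ga.distribution.fractions
        if ga.distribution.n_visual:
            assert sum(fr.values()) == pytest.approx(1.0)
            assert ga.profiles["category"].notna().sum() == \
                ga.distribution.n_visual


class TestReceptiveFields:
    def test_patch_is_retinal_weight_slice(self, cfg, tiny_dataset):
        m = RBM(n_hidden=5, n_epochs=2, random_state=0).fit(
            tiny_dataset.inputs("train")[:100])
        patch = receptive_field(m, 2, cfg)
        assert patch.shape == (17, 17)
        assert np.array_equal(patch.ravel(), m.weights_[2, :289])

    def test_gray_normalization(self):
        from gainfields.analysis import _to_gray
        assert np.allclose(_to_gray(np.zeros((3, 3))), 0.5)
        patch = np.array([[-1.0, 0.0], [0.0, 3.0]])
        gray = _to_gray(patch)
        assert gray.min() == 0.0 and gray.max() == 1.0

    def test_render_writes_png(self, cfg, tiny_dataset, tmp_path):
        m = RBM(n_hidden=4, n_epochs=2, random_state=0).fit(
            tiny_dataset.inputs("train")[:100])
        out = tmp_path / "rf.png"
        render_receptive_fields(m, range(4), out, cfg)
        assert out.exists() and out.stat().st_size > 0
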
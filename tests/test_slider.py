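"""Adapters, the slice-level 3D variant, model assembly and param accounting."""

import numpy as np
import pytest

from ctslider.slider import (AdapterParams, BackboneConfig, SliderClassifier,
                             SliderConfig, adapter_forward, assemble_model,
                             count_tunable_params, predict_case, slider_forward,
                             tokens_to_volume, volume_to_tokens)

TINY_BB = dict(embed_dim=16, depth=2, patch_size=7, image_size=14, n_heads=2)


def _adapter_params(rng, d=6, p=2, kernel=(3, 1, 1), zero_up=False, unit_conv=False):
    kt, kh, kw = kernel
    conv_w = rng.standard_normal((p, kt, kh, kw))
    if unit_conv:
        conv_w = np.zeros((p, kt, kh, kw))
        conv_w[:, kt // 2, kh // 2, kw // 2] = 1.0
    return AdapterParams(
        w_down=rng.standard_normal((d, p)),
        b_down=rng.standard_normal(p),
        w_up=np.zeros((p, d)) if zero_up else rng.standard_normal((p, d)),
        b_up=np.zeros(d),
        conv_weight=conv_w,
        conv_bias=np.zeros(p),
    )


class TestAdapterForward:
    def test_zero_up_projection_is_identity(self, rng):
        X = rng.standard_normal((5, 6))
        params = _adapter_params(rng, zero_up=True)
        np.testing.assert_array_equal(adapter_forward(X, params), X)

    def test_hand_computed_example(self):
        # d=2, p=1, identity activation: out = X + f(X Wd + bd) Wu + bu
        params = AdapterParams(w_down=np.array([[1.0], [3.0]]),
                               b_down=np.array([0.5]),
                               w_up=np.array([[2.0, -1.0]]),
                               b_up=np.array([0.0, 1.0]))
        out = adapter_forward(np.array([[1.0, 2.0]]), params, activation="identity")
        # hidden = 1*1 + 2*3 + 0.5 = 7.5; out = (1+15+0, 2-7.5+1)
        np.testing.assert_allclose(out, [[16.0, -4.5]])

    def test_shape_preserved_for_random_shapes(self, rng):
        for shape in [(3, 6), (2, 4, 6), (7, 1, 6)]:
            X = rng.standard_normal(shape)
            assert adapter_forward(X, _adapter_params(rng)).shape == shape

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            adapter_forward(rng.standard_normal((3, 5)), _adapter_params(rng))


class TestSliderForward:
    CFG = SliderConfig(d=6, delta=3, kernel=(3, 1, 1), n_blocks=1, grid=(2, 2))

    def test_zero_up_projection_is_identity(self, rng):
        cfg = self.CFG
        X = rng.standard_normal((4, 4, 6))
        params = _adapter_params(rng, d=6, p=2, zero_up=True)
        np.testing.assert_array_equal(slider_forward(X, params, cfg), X)

    def test_unit_pointwise_conv_reduces_to_plain_adapter(self, rng):
        cfg = SliderConfig(d=6, delta=3, kernel=(1, 1, 1), n_blocks=1, grid=(2, 2))
        params = _adapter_params(rng, d=6, p=2, kernel=(1, 1, 1), unit_conv=True)
        X = rng.standard_normal((3, 4, 6))
        out = slider_forward(X, params, cfg)
        per_slice = np.stack([adapter_forward(X[t], params) for t in range(3)])
        np.testing.assert_allclose(out, per_slice)

    def test_spatial_kernel_keeps_slices_independent(self, rng):
        cfg = SliderConfig(d=6, delta=3, kernel=(1, 3, 3), n_blocks=1, grid=(2, 2))
        params = _adapter_params(rng, d=6, p=2, kernel=(1, 3, 3))
        X = rng.standard_normal((4, 4, 6))
        base = slider_forward(X, params, cfg)
        X2 = X.copy()
        X2[3] += rng.standard_normal((4, 6))    # perturb a different slice
        pert = slider_forward(X2, params, cfg)
        np.testing.assert_array_equal(base[0], pert[0])
        np.testing.assert_array_equal(base[2], pert[2])
        assert not np.allclose(base[3], pert[3])

    def test_slice_kernel_mixes_neighbouring_slices(self, rng):
        cfg = self.CFG
        params = _adapter_params(rng, d=6, p=2)
        X = rng.standard_normal((4, 4, 6))
        X2 = X.copy()
        X2[1] += 1.0
        out, out2 = slider_forward(X, params, cfg), slider_forward(X2, params, cfg)
        assert not np.allclose(out[0], out2[0])     # neighbour affected
        np.testing.assert_array_equal(out[3], out2[3])  # two slices away: not

    def test_slice_kernel_equivariant_to_shared_token_permutation(self, rng):
        cfg = self.CFG
        params = _adapter_params(rng, d=6, p=2)
        X = rng.standard_normal((4, 4, 6))
        perm = rng.permutation(4)
        np.testing.assert_allclose(slider_forward(X[:, perm], params, cfg),
                                   slider_forward(X, params, cfg)[:, perm])

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            slider_forward(rng.standard_normal((4, 5, 6)),
                           _adapter_params(rng, d=6, p=2), self.CFG)


class TestTokenVolumeReshape:
    def test_roundtrip_is_lossless(self, rng):
        X = rng.standard_normal((5, 12, 3))
        np.testing.assert_array_equal(
            volume_to_tokens(tokens_to_volume(X, 3, 4)), X)

    def test_row_major_token_mapping(self):
        X = np.arange(4)[None, :, None].astype(float)  # tokens 0..3, p=1
        vol = tokens_to_volume(X, 2, 2)
        assert vol[0, 1, 1, 0] == 3.0  # last token lands at (1, 1)

    def test_mismatched_length_rejected(self):
        with pytest.raises(ValueError):
            tokens_to_volume(np.zeros((2, 5, 3)), 2, 2)


class TestSliderConfig:
    def test_bottleneck_division_enforced(self):
        with pytest.raises(ValueError):
            SliderConfig(d=768, delta=5)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            SliderConfig(d=768, delta=4, kernel=(2, 1, 1))


class TestParamCounting:
    def test_closed_form_matches_instantiated_tiny_model(self):
        bb = BackboneConfig(**TINY_BB)
        sl = SliderConfig(d=16, delta=4, kernel=(3, 1, 1), n_blocks=2, grid=(2, 2))
        for mode in ("slider", "full", "partial", "linear_probe"):
            model = assemble_model(bb, sl if mode == "slider" else None, mode, seed=0)
            assert model.n_trainable() == count_tunable_params(bb, sl, mode).count, mode

    def test_zero_blocks_degenerates_to_linear_probe(self):
        bb = BackboneConfig()
        sl = SliderConfig(d=768, delta=4, n_blocks=0)
        assert (count_tunable_params(bb, sl, "slider").count
                == count_tunable_params(bb, None, "linear_probe").count)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            count_tunable_params(BackboneConfig(), None, "adapters")

    def test_millions_rounding(self):
        rep = count_tunable_params(BackboneConfig(), None, "partial")
        assert rep.millions == round(rep.count / 1e6, 2)


class TestAssembledModel:
    def _data(self, rng, n=8, t=3):
        X = rng.random((n, t, 14, 14, 3))
        y = np.tile([0, 1], n // 2)
        return X, y

    def test_identity_at_initialisation(self, rng):
        bb = BackboneConfig(**TINY_BB)
        sl = SliderConfig(d=16, delta=4, n_blocks=2, grid=(2, 2))
        X, _ = self._data(rng)
        slider_logits = assemble_model(bb, sl, "slider", seed=5).forward(X)
        probe_logits = assemble_model(bb, None, "linear_probe", seed=5).forward(X)
        np.testing.assert_allclose(slider_logits, probe_logits, atol=1e-6)

    def test_training_step_leaves_frozen_backbone_bitwise_unchanged(self, rng):
        X, y = self._data(rng)
        clf = SliderClassifier(mode="slider", **{k: v for k, v in dict(
            embed_dim=16, depth=2, n_heads=2, patch_size=7, image_size=14).items()},
            epochs=1, batch_size=4, lr=1e-2, seed=0)
        # snapshot after building an identical model, then train one epoch
        ref = assemble_model(BackboneConfig(**TINY_BB),
                             SliderConfig(d=16, delta=4, n_blocks=2, grid=(2, 2)),
                             "slider", seed=0)
        frozen_before = {p.name: p.value.copy() for p in ref.parameters()
                         if not p.trainable}
        clf.fit(X, y)
        frozen_after = {p.name: p.value for p in clf.model_.parameters()
                        if not p.trainable}
        assert frozen_before.keys() == frozen_after.keys()
        for name, before in frozen_before.items():
            assert np.array_equal(before, frozen_after[name]), name

    def test_adapters_and_head_do_move_in_training(self, rng):
        X, y = self._data(rng)
        clf = SliderClassifier(mode="slider", embed_dim=16, depth=2, n_heads=2,
                               patch_size=7, image_size=14, epochs=2,
                               batch_size=4, lr=1e-2, seed=0).fit(X, y)
        up = clf.model_.adapters[0].up.weight.value
        assert np.abs(up).max() > 0
        assert np.abs(clf.model_.head.weight.grad).size  # head trainable

    def test_linear_probe_trains_exactly_the_head(self):
        bb = BackboneConfig(**TINY_BB)
        model = assemble_model(bb, None, "linear_probe", seed=0)
        trainable = [p.name for p in model.parameters() if p.trainable]
        assert sorted(trainable) == ["head.bias", "head.weight"]

    def test_partial_trains_last_block_and_head(self):
        bb = BackboneConfig(**TINY_BB)
        model = assemble_model(bb, None, "partial", seed=0)
        names = {p.name for p in model.parameters() if p.trainable}
        assert "head.weight" in names
        assert any(n.startswith("block1.") for n in names)
        assert not any(n.startswith("block0.") for n in names)

    def test_deterministic_training_and_prediction(self, rng):
        X, y = self._data(rng)
        cfg = dict(mode="slider", embed_dim=16, depth=2, n_heads=2, patch_size=7,
                   image_size=14, epochs=2, batch_size=4, seed=11)
        a = SliderClassifier(**cfg).fit(X, y).predict_proba(X)
        b = SliderClassifier(**cfg).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_scores_are_probabilities(self, rng):
        X, y = self._data(rng)
        clf = SliderClassifier(mode="linear_probe", embed_dim=16, depth=2,
                               n_heads=2, patch_size=7, image_size=14,
                               epochs=1, seed=0).fit(X, y)
        proba = clf.predict_proba(X)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_predict_case_repeatable_and_t_checked(self, rng):
        X, y = self._data(rng)
        clf = SliderClassifier(mode="linear_probe", embed_dim=16, depth=2,
                               n_heads=2, patch_size=7, image_size=14,
                               epochs=1, seed=0).fit(X, y)
        s1 = predict_case(clf, X[0])
        assert s1 == predict_case(clf, X[0]) and 0.0 <= s1 <= 1.0
        with pytest.raises(ValueError, match="T="):
            clf.predict_proba(X[:, :2])

    def test_single_class_training_rejected(self, rng):
        X, _ = self._data(rng)
        with pytest.raises(ValueError, match="both classes"):
            SliderClassifier(mode="slider", embed_dim=16, depth=2, n_heads=2,
                             patch_size=7, image_size=14,
                             epochs=1).fit(X, np.zeros(len(X), dtype=int))

    def test_zero_epoch_model_still_scores(self, rng):
        X, y = self._data(rng)
        clf = SliderClassifier(mode="slider", embed_dim=16, depth=2, n_heads=2,
                               patch_size=7, image_size=14, epochs=0,
                               seed=0).fit(X, y)
        assert clf.predict_proba(X).shape == (len(X), 2)
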
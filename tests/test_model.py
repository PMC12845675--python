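"""Architecture: parameter budget, attention-gate bounds, block contracts."""

import dataclasses

import numpy as np
import pytest

from mstsefnet import (ModelConfig, build_model, conv_complexity,
                       count_parameters, load_checkpoint, predict_proba,
                       reference_config, save_checkpoint)
from mstsefnet.model import (ConfigurationError, EfficientChannelAttention,
                             EnhancedAttentionGate, SERecalibrate,
                             SpatialAttention, architecture_summary)
from mstsefnet.nn import Tensor

RNG = np.random.default_rng(7)


def closed_form_tally(cfg: ModelConfig) -> int:
    """Independent per-layer parameter arithmetic.

    conv: (Cin/groups)·Cout·kh·kw (+Cout if biased); BN: 2C; FC: m·n+n.
    Written from the configuration alone — never from the built model.
    """
    F, C, E = cfg.filters_per_branch, cfg.feature_channels, cfg.n_channels
    total = 0
    if cfg.use_mtc:
        for k in cfg.temporal_kernels:
            total += 1 * F * 1 * k + F      # temporal conv, biased
            total += 2 * F                  # BN
    else:
        total += 3 * F * cfg.single_branch_kernel + 3 * F + 2 * (3 * F)
    total += (3 * F // (3 * F)) * C * E * 1  # depthwise spatial conv, no bias
    total += 2 * C                           # spatial BN
    if cfg.use_se:
        h = C // cfg.se_reduction
        total += C * h + h + h * C + C       # two biased FC layers
    if cfg.use_eff:
        total += C * E                       # shallow depthwise projection
        cg = C // cfg.eag_groups
        total += 2 * (cg * C + C)            # two grouped 1x1 convs, biased
        total += 2 * (2 * C)                 # their BNs
        total += C * 1                       # psi conv C->1, no bias
        total += 2 * cfg.eca_kernel + 1      # ECA conv (2-ch, 1 out), biased
        total += 2 * cfg.sa_kernel + 1       # SA conv (2-ch, 1 out), biased
    p1, p2 = cfg.pooling[1]
    t_out = (cfg.n_samples // p1) // p2
    total += C * t_out * cfg.n_classes + cfg.n_classes
    return total


class TestParameterBudget:
    def test_reference_build_matches_published_budget(self):
        """The pinned 22×750/4-class configuration totals 10,824 trainable
        scalars, and the framework count agrees with the closed form."""
        cfg = reference_config()
        model = build_model(cfg, seed=0)
        assert count_parameters(model) == 10824
        assert closed_form_tally(cfg) == 10824

    @pytest.mark.parametrize("variant_flags", [
        dict(use_mtc=False), dict(use_se=False), dict(use_eff=False),
        dict(use_mtc=False, use_se=False, use_eff=False),
    ])
    def test_tally_oracle_tracks_every_ablation(self, variant_flags):
        cfg = dataclasses.replace(reference_config(), **variant_flags)
        assert count_parameters(build_model(cfg, seed=1)) == closed_form_tally(cfg)

    def test_ablations_strictly_smaller(self):
        full = count_parameters(build_model(reference_config(), seed=0))
        for flag in ("use_mtc", "use_se", "use_eff"):
            cfg = dataclasses.replace(reference_config(), **{flag: False})
            assert count_parameters(build_model(cfg, seed=0)) < full

    def test_eff_removal_drops_exactly_the_fusion_parameters(self):
        """Ablating fusion removes EAG+ECA+SA plus the shallow projection."""
        cfg = reference_config()
        C, E = cfg.feature_channels, cfg.n_channels
        cg = C // cfg.eag_groups
        eff_params = (C * E                      # projection
                      + 2 * (cg * C + C) + 4 * C  # EAG convs + BNs
                      + C                         # psi
                      + 2 * cfg.eca_kernel + 1    # ECA
                      + 2 * cfg.sa_kernel + 1)    # SA
        wo = dataclasses.replace(cfg, use_eff=False)
        delta = (count_parameters(build_model(cfg, seed=0))
                 - count_parameters(build_model(wo, seed=0)))
        assert delta == eff_params

    def test_summary_sums_to_total(self):
        model = build_model(reference_config(), seed=0)
        rows = architecture_summary(model)
        assert sum(r["parameters"] for r in rows) == count_parameters(model)


class TestConfigValidation:
    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError, match="temporal_kernels"):
            build_model(reference_config(temporal_kernels=(12, 33, 67)))

    def test_non_increasing_kernels_rejected(self):
        with pytest.raises(ConfigurationError, match="temporal_kernels"):
            build_model(reference_config(temporal_kernels=(33, 33, 67)))

    def test_kernel_longer_than_epoch_rejected(self):
        with pytest.raises(ConfigurationError, match="longer than n_samples"):
            build_model(reference_config(n_samples=50, pooling=("avg", (5, 5))))

    def test_se_divisibility_enforced(self):
        with pytest.raises(ConfigurationError, match="se_reduction"):
            build_model(reference_config(se_reduction=7))

    def test_pooling_collapse_rejected(self):
        with pytest.raises(ConfigurationError, match="pooling"):
            build_model(reference_config(pooling=("avg", (100, 100))))


def random_feature_maps(n, shape=(2, 96, 1, 20)):
    for _ in range(n):
        yield Tensor(RNG.standard_normal(shape).astype(np.float32))


class TestAttentionBlocks:
    def test_se_weights_in_unit_interval_and_hidden_width(self):
        se = SERecalibrate(64, 16, RNG)
        assert se.fc1.weight.shape == (64, 4)
        for x in random_feature_maps(5, (3, 64, 1, 10)):
            w = se.weights(x).data
            assert ((w > 0) & (w < 1)).all()

    def test_se_symmetric_input_symmetric_weights(self):
        se = SERecalibrate(8, 4, RNG)
        # identical channels + channel-symmetric FCs -> equal weights
        for fc in (se.fc1, se.fc2):
            fc.weight.data[:] = 0.3
            fc.bias.data[:] = 0.1
        x = Tensor(np.tile(RNG.standard_normal((2, 1, 1, 6)), (1, 8, 1, 1)))
        w = se.weights(x).data
        np.testing.assert_allclose(w - w[:, :1], 0, atol=1e-6)

    def test_eag_multiplier_in_one_two(self):
        eag = EnhancedAttentionGate(96, 32, RNG)
        eag.eval()
        for x in random_feature_maps(5):
            a, b = x, Tensor(RNG.standard_normal(x.shape).astype(np.float32))
            mult = eag.multiplier(a, b).data
            assert ((mult > 1.0) & (mult < 2.0)).all()

    def test_eag_zero_logits_gives_exact_three_halves(self):
        eag = EnhancedAttentionGate(96, 32, RNG)
        eag.eval()
        eag.psi.weight.data[:] = 0.0
        a = Tensor(RNG.standard_normal((2, 96, 1, 12)).astype(np.float32))
        b = Tensor(RNG.standard_normal((2, 96, 1, 12)).astype(np.float32))
        np.testing.assert_allclose(eag(a, b).data, 1.5 * b.data, rtol=1e-6)

    def test_eag_zero_b_annihilates(self):
        eag = EnhancedAttentionGate(96, 32, RNG)
        eag.eval()
        a = Tensor(RNG.standard_normal((2, 96, 1, 12)).astype(np.float32))
        b = Tensor(np.zeros((2, 96, 1, 12), dtype=np.float32))
        assert not eag(a, b).data.any()

    def test_eag_shape_mismatch_rejected(self):
        eag = EnhancedAttentionGate(96, 32, RNG)
        with pytest.raises(ValueError):
            eag(Tensor(np.zeros((1, 96, 1, 4))), Tensor(np.zeros((1, 96, 1, 5))))

    def test_eca_weights_bounded_and_zero_fixed_point(self):
        eca = EfficientChannelAttention(7, RNG)
        for x in random_feature_maps(5):
            w = eca.weights(x).data
            assert ((w > 0) & (w < 1)).all()
        zero = Tensor(np.zeros((2, 96, 1, 20), dtype=np.float32))
        assert not eca(zero).data.any()

    def test_eca_gap_equals_gmp_on_constant_map(self):
        x = Tensor(np.full((2, 5, 1, 8), 3.0))
        gap = x.mean(axis=(2, 3)).data
        gmp = x.max(axis=(2, 3)).data
        np.testing.assert_array_equal(gap, gmp)

    def test_sa_constant_input_constant_attention(self):
        """Translation invariance of the same-padded conv on constants;
        the zero-padded boundary (3 samples each side) is excluded."""
        sa = SpatialAttention(7, RNG)
        x = Tensor(np.full((1, 96, 1, 30), 2.0, dtype=np.float32))
        w = sa.weights(x, x).data[..., 3:-3]
        np.testing.assert_allclose(w, w.ravel()[0], rtol=1e-5)

    def test_sa_output_shape_and_bounds(self):
        sa = SpatialAttention(7, RNG)
        for x in random_feature_maps(5):
            w = sa.weights(x, x).data
            assert w.shape == (x.shape[0], 1, 1, x.shape[3])
            assert ((w > 0) & (w < 1)).all()
            assert sa(x, x).shape == x.shape


class TestForward:
    def test_probability_rows_sum_to_one(self, small_model_config):
        model = build_model(small_model_config, seed=3)
        x = RNG.standard_normal((8, 3, 250))
        proba = predict_proba(model, x)
        assert proba.shape == (8, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_per_sample_independence_in_eval(self, small_model_config):
        model = build_model(small_model_config, seed=3)
        x = RNG.standard_normal((4, 3, 250))
        dup = np.concatenate([x, x[:1]], axis=0)
        proba = predict_proba(model, dup)
        np.testing.assert_allclose(proba[4], proba[0], atol=1e-6)

    def test_reference_shape(self):
        model = build_model(reference_config(), seed=0)
        x = RNG.standard_normal((4, 22, 750))
        assert predict_proba(model, x).shape == (4, 4)

    def test_input_shape_mismatch_rejected(self, small_model_config):
        model = build_model(small_model_config, seed=0)
        with pytest.raises(ValueError):
            predict_proba(model, RNG.standard_normal((2, 5, 250)))

    def test_spatial_conv_starts_near_zero(self, small_model_config):
        """Pre-BN electrode mixing is tiny at init for unit-scale input."""
        model = build_model(small_model_config, seed=5)
        x = Tensor(RNG.standard_normal((4, 48, 3, 250)).astype(np.float32))
        pre_bn = model.spatial.conv(x)
        assert np.abs(pre_bn.data).max() <= 1e-2 * np.abs(x.data).max()

    def test_single_branch_ablation_runs(self, small_model_config):
        cfg = dataclasses.replace(small_model_config, use_mtc=False)
        model = build_model(cfg, seed=0)
        assert predict_proba(model, RNG.standard_normal((2, 3, 250))).shape == (2, 2)


class TestConvComplexity:
    def test_identity_and_annihilation(self):
        assert conv_complexity(1, 1, 1, 1, 1) == 1
        assert conv_complexity(0, 3, 4, 5, 6) == 0

    def test_formula(self):
        assert conv_complexity(2, 3, 4, 5, 6) == 2 * 3 * 4 * 25 * 6

    def test_linear_in_data_volume(self):
        base = conv_complexity(5184, 22, 16, 13, 750)
        assert conv_complexity(2 * 5184, 22, 16, 13, 750) == 2 * base

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            conv_complexity(-1, 1, 1, 1, 1)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, small_model_config):
        model = build_model(small_model_config, seed=9)
        x = RNG.standard_normal((3, 3, 250))
        before = predict_proba(model, x)
        path = save_checkpoint(model, tmp_path / "model.npz")
        restored = load_checkpoint(path)
        np.testing.assert_allclose(predict_proba(restored, x), before, atol=1e-6)
        assert restored.cfg == small_model_config
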
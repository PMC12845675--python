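"""Cross-validation plans, the two-stage protocol, ablation factory."""

import dataclasses

import numpy as np
import pytest

from mstsefnet import (ABLATION_VARIANTS, TrainConfig, build_model,
                       count_parameters, kfold_split, make_ablation_variant,
                       run_cv_experiment)
from mstsefnet.model import reference_config
from mstsefnet.training import (Stage1Result, TrainingError, train_stage1,
                                train_stage2)


class TestKFold:
    @pytest.mark.parametrize("n,k", [(10, 5), (5184, 5), (17, 3)])
    def test_partition_invariants(self, n, k):
        plan = kfold_split(n, k, seed=4)
        val_sets = [set(va.tolist()) for _, va in plan]
        # disjoint and covering
        union = set().union(*val_sets)
        assert union == set(range(n))
        assert sum(len(v) for v in val_sets) == n
        sizes = sorted(len(v) for v in val_sets)
        assert sizes[-1] - sizes[0] <= 1
        # each fold's train indices are the complement of its validation set
        for tr, va in plan:
            assert set(tr.tolist()) == set(range(n)) - set(va.tolist())

    def test_5184_fold_sizes(self):
        sizes = sorted(len(va) for _, va in kfold_split(5184, 5, seed=0))
        assert sizes == [1036, 1037, 1037, 1037, 1037]

    def test_deterministic_in_seed(self):
        a = kfold_split(100, 5, seed=8)
        b = kfold_split(100, 5, seed=8)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(va, vb)
        c = kfold_split(100, 5, seed=9)
        assert any(not np.array_equal(va, vc)
                   for (_, va), (_, vc) in zip(a, c))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, 5, seed=0)


def _toy_sets(n=48, n_classes=2, n_samples=250, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3, n_samples))
    y = rng.integers(0, n_classes, n)
    return (x[: 3 * n // 4], y[: 3 * n // 4]), (x[3 * n // 4:], y[3 * n // 4:])


class TestStage1:
    def test_loss_decreases_on_separable_data(self, separable_dataset,
                                              small_model_config):
        sub = separable_dataset.select(np.arange(96))
        model = build_model(small_model_config, seed=2)
        cfg = TrainConfig(stage1_epochs=5, seed=2)
        res = train_stage1(model, (sub.data[:72], sub.labels[:72]),
                           (sub.data[72:], sub.labels[72:]), cfg)
        assert res.train_losses[-1] < res.train_losses[0]
        assert res.best_epoch >= 1
        assert res.best_val_loss == min(res.val_losses)

    def test_lr_trace_follows_cosine_schedule(self, small_model_config):
        train, val = _toy_sets()
        model = build_model(small_model_config, seed=0)
        cfg = TrainConfig(stage1_epochs=4, initial_lr=2e-3, min_lr=1e-6, seed=0)
        res = train_stage1(model, train, val, cfg)
        assert res.lr_trace[0] == pytest.approx(2e-3)
        # last epoch runs at the penultimate scheduler value, above the floor
        assert res.lr_trace[-1] > 1e-6
        assert res.lr_trace == sorted(res.lr_trace, reverse=True)

    def test_frozen_model_constant_validation_loss(self, small_model_config):
        """With no trainable parameters the loss never moves and the
        checkpoint is the first epoch."""
        train, val = _toy_sets()
        model = build_model(small_model_config, seed=0)
        for p in model.parameters():
            p.requires_grad = False
        model.dropout.p = 0.0
        cfg = TrainConfig(stage1_epochs=3, seed=0)
        res = train_stage1(model, train, val, cfg)
        assert res.best_epoch == 1
        np.testing.assert_allclose(res.val_losses, res.val_losses[0], rtol=1e-6)

    def test_empty_sets_rejected(self, small_model_config):
        model = build_model(small_model_config, seed=0)
        with pytest.raises(ValueError):
            train_stage1(model, (np.empty((0, 3, 250)), np.empty(0, int)),
                         _toy_sets()[1], TrainConfig())


class TestStage2:
    def test_infinite_reference_stops_after_one_epoch(self, small_model_config):
        train, _ = _toy_sets()
        model = build_model(small_model_config, seed=1)
        ckpt = model.state_dict()
        cfg = TrainConfig(stage1_epochs=1, stage2_max_epochs=50, seed=1)
        res = train_stage2(model, ckpt, train, np.inf, cfg)
        assert res.stopped_epoch == 1
        assert res.converged

    def test_zero_reference_hits_cap_and_flags(self, small_model_config):
        train, _ = _toy_sets(n=16)
        model = build_model(small_model_config, seed=1)
        ckpt = model.state_dict()
        cfg = TrainConfig(stage1_epochs=1, stage2_max_epochs=3, seed=1)
        res = train_stage2(model, ckpt, train, 0.0, cfg)
        assert res.stopped_epoch == 3
        assert not res.converged

    def test_stopping_epoch_reproducible(self, separable_dataset,
                                         small_model_config):
        sub = separable_dataset.select(np.arange(64))
        cfg = TrainConfig(stage1_epochs=1, stage2_max_epochs=10, seed=5)
        stops = []
        for _ in range(2):
            model = build_model(small_model_config, seed=5)
            ckpt = model.state_dict()
            res = train_stage2(model, ckpt, (sub.data, sub.labels), 0.65, cfg)
            stops.append(res.stopped_epoch)
        assert stops[0] == stops[1]


class TestAblationFactory:
    def test_all_is_identity(self):
        cfg = reference_config()
        assert make_ablation_variant(cfg, "all") == cfg

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            make_ablation_variant(reference_config(), "wo_everything")

    def test_flag_wiring(self):
        cfg = make_ablation_variant(reference_config(), "wo_mtc_se")
        assert not cfg.use_mtc and not cfg.use_se and cfg.use_eff

    def test_eight_variants_with_minimum_at_triple_ablation(self):
        counts = {v: count_parameters(
            build_model(make_ablation_variant(reference_config(), v), seed=0))
            for v in ABLATION_VARIANTS}
        assert len(counts) == 8
        assert min(counts, key=counts.get) == "wo_mtc_se_eff"
        assert max(counts, key=counts.get) == "all"

    def test_wo_se_delta_is_se_block_closed_form(self):
        cfg = reference_config()
        C, r = cfg.feature_channels, cfg.se_reduction
        se_params = C * (C // r) + (C // r) + (C // r) * C + C
        delta = (count_parameters(build_model(cfg, seed=0))
                 - count_parameters(build_model(
                     make_ablation_variant(cfg, "wo_se"), seed=0)))
        assert delta == se_params


class TestRunCv:
    def test_report_structure_and_fold_count(self, separable_dataset,
                                             small_model_config,
                                             quick_train_config):
        sub = separable_dataset.select(np.arange(80))
        report = run_cv_experiment(sub, small_model_config, quick_train_config)
        assert report.n_folds == quick_train_config.k_folds
        assert report.confusion.sum() == sub.n_trials
        assert 0 <= report.mean_accuracy <= 100
        assert all(k <= 1 for k in report.fold_kappa)

    def test_shape_mismatch_rejected(self, separable_dataset,
                                     quick_train_config):
        cfg = dataclasses.replace(reference_config(), n_channels=5)
        with pytest.raises(ValueError):
            run_cv_experiment(separable_dataset, cfg, quick_train_config)

    def test_seeded_repeatability(self, separable_dataset, small_model_config,
                                  quick_train_config):
        sub = separable_dataset.select(np.arange(60))
        r1 = run_cv_experiment(sub, small_model_config, quick_train_config)
        r2 = run_cv_experiment(sub, small_model_config, quick_train_config)
        assert r1.fold_accuracy == r2.fold_accuracy
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
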
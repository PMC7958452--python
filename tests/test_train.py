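"""Splitting rules, joint-step mechanics, checkpoint selection, determinism."""

import numpy as np
import pandas as pd
import pytest

from fieldgan import (
    DivergenceError,
    LossWeights,
    TrainConfig,
    ValidationError,
    joint_step,
    repeat_runs,
    split_cohort,
    train_joint,
    train_simple,
)
from fieldgan import nn


def tiny_config(**kw) -> TrainConfig:
    defaults = dict(
        epochs=1,
        steps_per_epoch=2,
        batch_size=2,
        patch_side=31,
        gen_channels=(2, 2, 1),
        disc_channels=(2, 2, 2, 2, 1),
        clf_channels=(2, 2, 2),
        n_patches_eval=3,
        seed=0,
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestSplit:
    def test_paper_scale_floor_rule(self):
        subjects = [(f"S{i:03d}", i % 2) for i in range(151)]
        plan = split_cohort(subjects, seed=3)
        assert (len(plan.train), len(plan.val), len(plan.test)) == (91, 30, 30)

    def test_minimum_cohort_exact_ratio(self):
        plan = split_cohort([(f"S{i}", i % 2) for i in range(5)], seed=0)
        assert (len(plan.train), len(plan.val), len(plan.test)) == (3, 1, 1)

    def test_deterministic_given_seed(self):
        subjects = [(f"S{i:03d}", i % 2) for i in range(40)]
        p1 = split_cohort(subjects, seed=9)
        p2 = split_cohort(subjects, seed=9)
        assert p1.train == p2.train and p1.val == p2.val and p1.test == p2.test

    def test_no_subject_in_two_parts(self):
        subjects = [(f"S{i:03d}", i % 2) for i in range(37)]
        plan = split_cohort(subjects, seed=1)
        parts = [set(plan.train), set(plan.val), set(plan.test)]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert parts[0] | parts[1] | parts[2] == {s for s, _ in subjects}

    def test_stratification_both_classes_in_every_part(self):
        subjects = [(f"S{i:03d}", i % 2) for i in range(20)]
        plan = split_cohort(subjects, seed=2)
        labels = dict(subjects)
        for part in (plan.train, plan.val, plan.test):
            assert {labels[s] for s in part} == {0, 1}

    def test_warns_when_a_class_cannot_reach_a_part(self):
        subjects = [("A", 0), ("B", 0), ("C", 0), ("D", 0), ("E", 1)]
        with pytest.warns(UserWarning, match="class"):
            split_cohort(subjects, seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            split_cohort([("A", 0), ("B", 1)], seed=0)


def make_step_inputs(side=31, batch=2, seed=0):
    rng = np.random.default_rng(seed)
    low = rng.standard_normal((batch, 1, side, side, side)).astype(np.float32)
    high = low + 0.1
    labels = np.arange(batch) % 2
    return low, high, labels


@pytest.fixture
def step_env():
    cfg = tiny_config()
    rng = np.random.default_rng(1)
    bundle = cfg.build_bundle(rng)
    opts = (
        nn.Adam(bundle.generator.params()),
        nn.Adam(bundle.discriminator.params()),
        nn.Adam(bundle.classifier.params()),
    )
    return cfg, bundle, opts


class TestJointStep:
    def test_loss_decomposition(self, step_env):
        cfg, bundle, (og, od, oc) = step_env
        low, high, labels = make_step_inputs()
        w = LossWeights(1.0, 10.0, 1.0)
        out = joint_step(low, high, labels, bundle, w, og, od, oc)
        expected = w.w_adv * out["adv_G"] + w.w_l1 * out["l1"] + w.w_cls * out["cls"]
        assert out["total_G"] == pytest.approx(expected, abs=1e-6)

    def test_l1_zero_when_generated_equals_high(self, step_env):
        cfg, bundle, (og, od, oc) = step_env
        low, _, labels = make_step_inputs()
        # zero-init head: generated == low, so compare against high == low
        out = joint_step(low, low.copy(), labels, bundle,
                         LossWeights(0.0, 1.0, 0.0), og, od, oc)
        assert out["l1"] == 0.0

    def test_classification_gradient_reaches_generator(self, step_env):
        cfg, bundle, (og, od, oc) = step_env
        low, high, labels = make_step_inputs(seed=3)
        before = [p.data.copy() for p in bundle.generator.params()]
        joint_step(low, high, labels, bundle, LossWeights(0.0, 0.0, 1.0), og, od, oc)
        moved = [
            not np.array_equal(b, p.data)
            for b, p in zip(before, bundle.generator.params())
        ]
        assert any(moved)

    def test_invalid_weights_rejected(self, step_env):
        cfg, bundle, (og, od, oc) = step_env
        low, high, labels = make_step_inputs()
        with pytest.raises(ValidationError):
            joint_step(low, high, labels, bundle, LossWeights(0, 0, 0), og, od, oc)

    def test_divergence_reported_with_component(self, step_env):
        cfg, bundle, (og, od, oc) = step_env
        low, high, labels = make_step_inputs()
        low[0] = np.nan
        with pytest.raises(DivergenceError):
            joint_step(low, high, labels, bundle, LossWeights(0, 1, 0), og, od, oc)


class TestTrainJoint:
    def test_history_shape_and_best_selection(self, prepared10, cohort10):
        split = split_cohort(cohort10, seed=0)
        cfg = tiny_config(epochs=2)
        res = train_joint(prepared10, split, cfg)
        assert len(res.epoch_log) == 2
        assert res.best_val_snr == res.epoch_log["val_snr"].max()
        assert len(res.step_log) == 4
        assert (res.epoch_log["best_val_snr"].diff().dropna() >= 0).all()

    def test_fixed_seed_bit_reproducible(self, prepared10, cohort10):
        split = split_cohort(cohort10, seed=0)
        cfg = tiny_config()
        r1 = train_joint(prepared10, split, cfg, seed=4)
        r2 = train_joint(prepared10, split, cfg, seed=4)
        pd.testing.assert_frame_equal(r1.step_log, r2.step_log)
        pd.testing.assert_frame_equal(r1.epoch_log, r2.epoch_log)

    def test_step_log_total_matches_weighted_sum(self, prepared10, cohort10):
        split = split_cohort(cohort10, seed=0)
        cfg = tiny_config()
        res = train_joint(prepared10, split, cfg)
        w = cfg.loss_weights
        recomputed = (
            w.w_adv * res.step_log["adv_G"]
            + w.w_l1 * res.step_log["l1"]
            + w.w_cls * res.step_log["cls"]
        )
        assert np.allclose(res.step_log["total_G"], recomputed, atol=1e-6)


class TestTrainSimple:
    def test_classifier_untouched_during_gan_only_training(self, prepared10, cohort10):
        split = split_cohort(cohort10, seed=0)
        cfg = tiny_config(loss_weights=LossWeights(1.0, 10.0, 0.0))
        res = train_joint(prepared10, split, cfg, seed=6)
        fresh = cfg.build_bundle(np.random.default_rng(6))
        for trained, init in zip(
            res.bundle.classifier.params(), fresh.classifier.params()
        ):
            assert np.array_equal(trained.data, init.data)

    def test_two_phases_logged(self, prepared10, cohort10):
        split = split_cohort(cohort10, seed=0)
        res = train_simple(prepared10, split, tiny_config(), seed=1)
        assert set(res.step_log["phase"]) == {"simpleGAN", "simpleFCN"}

    def test_identity_mode_skips_gan_phase(self, prepared10, cohort10):
        split = split_cohort(cohort10, seed=0)
        res = train_simple(prepared10, split, tiny_config(), seed=1,
                           generator="identity")
        assert set(res.step_log["phase"]) == {"simpleFCN"}
        fresh = tiny_config().build_bundle(np.random.default_rng(1))
        for trained, init in zip(
            res.bundle.generator.params(), fresh.generator.params()
        ):
            assert np.array_equal(trained.data, init.data)

    def test_deterministic_under_fixed_seed(self, prepared10, cohort10):
        split = split_cohort(cohort10, seed=0)
        r1 = train_simple(prepared10, split, tiny_config(), seed=2)
        r2 = train_simple(prepared10, split, tiny_config(), seed=2)
        pd.testing.assert_frame_equal(r1.step_log, r2.step_log)


class TestRepeatRuns:
    def test_run_count_and_seed_keys(self, prepared10, cohort10):
        split = split_cohort(cohort10, seed=0)
        cfg = tiny_config(epochs=1, steps_per_epoch=1)
        results, failures = repeat_runs(
            lambda seed: train_joint(prepared10, split, cfg, seed=seed),
            n_runs=2, base_seed=10,
        )
        assert sorted(results) == [10, 11]
        assert failures == {}

    def test_distinct_seeds_give_distinct_histories(self, prepared10, cohort10):
        split = split_cohort(cohort10, seed=0)
        cfg = tiny_config(epochs=1, steps_per_epoch=2)
        results, _ = repeat_runs(
            lambda seed: train_joint(prepared10, split, cfg, seed=seed),
            n_runs=2, base_seed=0,
        )
        assert not results[0].step_log.equals(results[1].step_log)

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(ValidationError):
            repeat_runs(lambda seed: None, n_runs=1)
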
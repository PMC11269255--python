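"""Training loop, subject splitting, loss, sampling and early stopping."""
import numpy as np
import pytest

from noisemapnet.network import UNetConfig, build_model
from noisemapnet.preprocess import apply_standardization, standardize
from noisemapnet.training import (EarlyStopping, TrainConfig, TrainingFrame,
                                  frame_standardization, l2_loss,
                                  make_training_sample, split_by_subject,
                                  train)


class TestSplit:
    def test_fifty_subjects_80_20(self):
        train_ids, val_ids = split_by_subject(list(range(50)), 0.8, seed=0)
        assert len(train_ids) == 40 and len(val_ids) == 10
        assert train_ids.isdisjoint(val_ids)

    def test_two_subjects_half(self):
        a, b = split_by_subject(["p1", "p2"], 0.5, seed=1)
        assert len(a) == 1 and len(b) == 1

    def test_deterministic_per_seed(self):
        assert split_by_subject(list(range(20)), 0.8, seed=4) == \
            split_by_subject(list(range(20)), 0.8, seed=4)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            split_by_subject(["only", "only"], 0.8)


class TestLoss:
    def test_identical_inputs_give_zero(self, rng):
        x = rng.normal(size=(8, 8))
        assert l2_loss(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros((5, 5))
        assert l2_loss(x + 2.0, x) == pytest.approx(4.0)

    def test_matches_brute_force_sum(self, rng):
        pred = rng.normal(size=(5, 5))
        target = rng.normal(size=(5, 5))
        brute = sum((pred[i, j] - target[i, j]) ** 2
                    for i in range(5) for j in range(5)) / 25
        assert l2_loss(pred, target) == pytest.approx(brute, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l2_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestTrainingSample:
    def setup_method(self):
        self.cfg = TrainConfig(master_seed=11)
        rng = np.random.default_rng(0)
        self.patch = rng.uniform(0, 400, (64, 64))

    def test_noise_regenerated_across_epochs(self):
        a = make_training_sample(self.patch, 0, 7, self.cfg, 10.0)
        b = make_training_sample(self.patch, 1, 7, self.cfg, 10.0)
        assert not np.array_equal(a[0], b[0])

    def test_same_epoch_index_reproducible(self):
        a = make_training_sample(self.patch, 0, 7, self.cfg, 10.0)
        b = make_training_sample(self.patch, 0, 7, self.cfg, 10.0)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_ground_truth_is_standardized_difference(self):
        noisy_std, target = make_training_sample(self.patch, 2, 3, self.cfg, 10.0)
        # reconstruct: target == std(noisy) - std-with-same-params(clean)
        rng = np.random.default_rng([11, 1, 2, 3])
        noise = rng.standard_normal(self.patch.shape) * 10.0
        expect_std, params = standardize(self.patch + noise)
        np.testing.assert_array_equal(noisy_std, expect_std)
        np.testing.assert_array_equal(
            target, expect_std - apply_standardization(self.patch, params))

    def test_frame_params_scale_noise_consistently(self):
        params = frame_standardization(self.patch, 10.0)
        noisy_std, target = make_training_sample(self.patch, 0, 0, self.cfg, 10.0,
                                                 frame_params=params)
        # the standardized target is exactly noise / frame sigma
        assert target.std() == pytest.approx(10.0 / params.sigma, rel=0.1)

    def test_degenerate_patch_skipped_with_warning(self):
        cfg = TrainConfig(master_seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            out = make_training_sample(np.zeros((8, 8)), 0, 0, cfg, 0.0)
        assert out is None


class TestEarlyStopping:
    def run_sequence(self, losses, patience=20, max_epochs=500):
        stopper = EarlyStopping(patience)
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                return stopper.best_epoch, epoch
            if epoch == max_epochs:
                break
        return stopper.best_epoch, min(len(losses), max_epochs)

    def test_stops_at_best_plus_patience(self):
        losses = [1.0, 0.9] + [0.95] * 30
        best, stopped = self.run_sequence(losses)
        assert (best, stopped) == (2, 22)

    def test_monotone_decrease_never_stops_early(self):
        losses = [1.0 / (1 + e) for e in range(500)]
        best, stopped = self.run_sequence(losses)
        assert stopped == 500 and best == 500

    def test_tiny_improvement_does_not_rearm_patience(self):
        stopper = EarlyStopping(patience=3, min_delta=1e-7)
        stopper.update(1, 1.0)
        for epoch in range(2, 10):
            stopped = stopper.update(epoch, 1.0 - 1e-9 * epoch)
            if stopped:
                break
        assert stopper.best_epoch == 1 and epoch == 4

    def test_invariant_stop_within_patience_of_best(self, rng):
        for trial in range(20):
            losses = rng.uniform(0.5, 1.5, size=60)
            best, stopped = self.run_sequence(list(losses), patience=5, max_epochs=60)
            assert stopped - best <= 5


def micro_training_setup(master_seed=21):
    """A few 64x64 cine-like frames and a tiny model: fast but real."""
    from noisemapnet.phantom import PhantomSpec, generate_cine_phantom
    frames = []
    for subj in range(3):
        spec = PhantomSpec(image_size=(64, 64), lv_radius=10.0 + subj,
                           myocardium_outer_radius=20.0 + subj,
                           n_dynamics=2, seed=subj)
        series = generate_cine_phantom(spec)
        for t in range(2):
            frames.append(TrainingFrame(series.voxels[0, t], sigma=40.0,
                                        subject_id=subj))
    cfg = TrainConfig(lr=1e-3, patches_per_frame=4, max_epochs=8, patience=20,
                      master_seed=master_seed)
    model = build_model(UNetConfig(depth=1, init_filters=4, dropout_rate=0.5),
                        seed=7)
    return model, frames[:4], frames[4:], cfg


class TestTrainLoop:
    def test_progress_and_history_invariants(self):
        model, train_frames, val_frames, cfg = micro_training_setup()
        model, history = train(model, train_frames, val_frames, cfg)
        assert history.val_losses[-1] < history.val_losses[0]
        assert history.stopped_epoch <= cfg.max_epochs
        assert history.stopped_epoch - history.best_epoch <= cfg.patience
        assert len(history.train_losses) == history.stopped_epoch

    def test_restored_model_reproduces_best_val_loss(self):
        from noisemapnet.training import _frozen_validation_set, _validation_loss
        model, train_frames, val_frames, cfg = micro_training_setup()
        model, history = train(model, train_frames, val_frames, cfg)
        val_samples = _frozen_validation_set(val_frames, cfg)
        assert _validation_loss(model, val_samples) == pytest.approx(
            history.best_val_loss, rel=1e-6)

    def test_fixed_seed_reproduces_history(self):
        m1, tr1, va1, cfg = micro_training_setup()
        _, h1 = train(m1, tr1, va1, cfg)
        m2, tr2, va2, cfg2 = micro_training_setup()
        _, h2 = train(m2, tr2, va2, cfg2)
        assert h1.val_losses == h2.val_losses
        assert h1.train_losses == h2.train_losses

    def test_empty_sets_rejected(self):
        model, train_frames, val_frames, cfg = micro_training_setup()
        with pytest.raises(ValueError):
            train(model, [], val_frames, cfg)
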
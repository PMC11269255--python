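"""Patch-based training of the noise-map network.

The regime: L2 loss between predicted and ground-truth noise maps, Adam
(beta1 0.9, beta2 0.99), batch size 1, 64x64 patches, a subject-level
80/20 train/validation split, at most 500 epochs with patience-20 early
stopping on the validation loss. Noise is regenerated independently for
every patch at every epoch from a counter-based substream of the master
seed, so the network never sees the same noise realization twice but any
(epoch, sample) pair is exactly reproducible.

The validation set uses one frozen noise realization (drawn once, before
the first epoch) so the early-stopping signal is not resampled; this
removes stochastic jitter from the stopping decision.

An epoch is one pass over (frames x patches_per_frame) random patches;
patch positions are redrawn each epoch.
"""
from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import UNet
from .preprocess import apply_standardization, extract_patches, standardize

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "TrainingFrame", "EarlyStopping",
           "split_by_subject", "l2_loss", "make_training_sample", "train"]


@dataclass
class TrainConfig:
    lr: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.99
    batch_size: int = 1
    patch_size: int = 64
    patches_per_frame: int = 4
    max_epochs: int = 500
    patience: int = 20
    train_fraction: float = 0.8
    target_snr: float = 10.0
    master_seed: int = 0
    min_delta: float = 1e-7   # improvement below this does not re-arm patience

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")


@dataclass
class TrainHistory:
    train_losses: list = field(default_factory=list)   # per epoch (1-based)
    val_losses: list = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0
    best_val_loss: float = float("inf")


@dataclass
class TrainingFrame:
    """One raw-intensity clean frame with its subject's noise calibration.

    ``sigma`` is the Gaussian noise standard deviation calibrated from the
    subject's blood-pool signal (ROI mean / target SNR).
    """
    image: np.ndarray
    sigma: float
    subject_id: object = None


class EarlyStopping:
    """Patience-based stopping on the validation loss.

    "Improvement" means strictly lower than the best so far by at least
    ``min_delta`` (guards against float noise re-arming patience). Stop
    when ``epoch - best_epoch >= patience``. Epochs are 1-based.
    """

    def __init__(self, patience: int, min_delta: float = 1e-7):
        self.patience = patience
        self.min_delta = min_delta
        self.best = float("inf")
        self.best_epoch = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch's validation loss; return True to stop."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.best_epoch = epoch
        return epoch - self.best_epoch >= self.patience


def split_by_subject(subject_ids, train_fraction: float = 0.8, seed: int = 0):
    """Disjoint train/validation subject sets (no leak across the split).

    ``train count = round(train_fraction * n)`` over the *distinct*
    subjects, each subject landing wholly on one side.
    """
    distinct = list(dict.fromkeys(subject_ids))   # order-preserving unique
    if len(distinct) < 2:
        raise ValueError("need at least 2 distinct subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(distinct))
    n_train = int(round(train_fraction * len(distinct)))
    n_train = min(max(n_train, 1), len(distinct) - 1)   # both sides nonempty
    train = {distinct[i] for i in order[:n_train]}
    val = {distinct[i] for i in order[n_train:]}
    return train, val


def l2_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean of squared elementwise differences."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(diff * diff))


def l2_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d(mean squared error)/d(pred)."""
    return 2.0 * (np.asarray(pred, dtype=np.float64) - target) / pred.size


def frame_standardization(frame_image: np.ndarray, sigma: float) -> "StandardizationParams":
    """Standardization parameters a noisy version of this frame would have.

    The mean is the clean frame's mean; the standard deviation folds the
    known noise level in quadrature (Var(clean + noise) = Var(clean) +
    sigma^2 in expectation). Scaling training patches with their source
    frame's parameters keeps the standardized noise amplitude identical
    between patch-based training and full-frame inference — z-scoring each
    patch by its own statistics would train the network at a different
    noise scale than it sees at test time.
    """
    from .preprocess import StandardizationParams
    mu = float(np.mean(frame_image))
    sig = float(np.sqrt(np.var(frame_image) + sigma ** 2))
    return StandardizationParams(mu=mu, sigma=sig)


def make_training_sample(clean_patch: np.ndarray, epoch: int, index: int,
                         config: TrainConfig, sigma: float, frame_params=None):
    """Noise one raw clean patch and standardize the pair.

    The noise realization is seeded by (master_seed, epoch, index): the
    same patch gets fresh noise each epoch, and any (epoch, index) pair is
    reproducible. Both noisy and clean patch are scaled with the same
    standardization parameters — ``frame_params`` (the source frame's, see
    :func:`frame_standardization`) when given, else the noisy patch's own —
    so the ground-truth noise map is exactly their standardized
    difference. Returns ``(noisy_std, noise_map_std)``, or ``None`` (with
    a warning) for a degenerate sample whose noisy patch is constant.
    """
    rng = np.random.default_rng([config.master_seed, 1, epoch, index])
    noise = rng.standard_normal(clean_patch.shape) * sigma
    noisy = np.asarray(clean_patch, dtype=np.float64) + noise
    if noisy.std() == 0.0:
        warnings.warn(f"degenerate (constant) patch at epoch {epoch}, index {index}; skipped")
        return None
    if frame_params is None:
        noisy_std, params = standardize(noisy)
    else:
        params = frame_params
        noisy_std = apply_standardization(noisy, params)
    clean_std = apply_standardization(clean_patch, params)
    return noisy_std, noisy_std - clean_std


def _frozen_validation_set(frames, config: TrainConfig):
    """Patches + one fixed noise realization for the validation frames."""
    samples = []
    idx = 0
    for fi, frame in enumerate(frames):
        params = frame_standardization(frame.image, frame.sigma)
        pset = extract_patches(frame.image, config.patch_size, "random-n",
                               config.patches_per_frame,
                               seed=[config.master_seed, 3, 0, fi])
        for patch in pset.patches:
            rng = np.random.default_rng([config.master_seed, 2, 0, idx])
            noise = rng.standard_normal(patch.shape) * frame.sigma
            noisy = patch.astype(np.float64) + noise
            if noisy.std() == 0.0:
                idx += 1
                continue
            noisy_std = apply_standardization(noisy, params)
            samples.append((noisy_std, noisy_std - apply_standardization(patch, params)))
            idx += 1
    if not samples:
        raise ValueError("validation set produced no usable samples")
    return samples


def _validation_loss(model: UNet, samples) -> float:
    total = 0.0
    for noisy_std, target in samples:
        pred = model.forward(noisy_std[None], training=False)[0]
        total += l2_loss(pred, target)
    return total / len(samples)


def train(model: UNet, train_frames, val_frames, config: TrainConfig):
    """Run the training loop; returns ``(best model, TrainHistory)``.

    ``train_frames`` / ``val_frames`` are lists of :class:`TrainingFrame`.
    The model returned carries the weights of the best-validation epoch
    (restore-best, not last). Non-finite losses abort with a diagnostic.
    """
    if not train_frames or not val_frames:
        raise ValueError("train and validation sets must be nonempty")
    val_samples = _frozen_validation_set(val_frames, config)
    optimizer = model.make_optimizer(config.lr, config.beta1, config.beta2)
    stopper = EarlyStopping(config.patience, config.min_delta)
    history = TrainHistory()
    best_state = model.state_dict()

    for epoch in range(1, config.max_epochs + 1):
        epoch_losses = []
        index = 0
        for fi, frame in enumerate(train_frames):
            params = frame_standardization(frame.image, frame.sigma)
            pset = extract_patches(frame.image, config.patch_size, "random-n",
                                   config.patches_per_frame,
                                   seed=[config.master_seed, 3, epoch, fi])
            for patch in pset.patches:
                sample = make_training_sample(patch, epoch, index, config, frame.sigma,
                                              frame_params=params)
                index += 1
                if sample is None:
                    continue
                noisy_std, target = sample
                rng = np.random.default_rng([config.master_seed, 4, epoch, index])
                pred = model.forward(noisy_std[None], training=True, rng=rng)[0]
                loss = l2_loss(pred, target)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss {loss} at epoch {epoch}, sample {index}")
                epoch_losses.append(loss)
                model.backward(l2_loss_grad(pred, target)[None])
                optimizer.step()
        train_loss = float(np.mean(epoch_losses)) if epoch_losses else float("nan")
        val_loss = _validation_loss(model, val_samples)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_losses.append(train_loss)
        history.val_losses.append(val_loss)
        stop = stopper.update(epoch, val_loss)
        if stopper.best_epoch == epoch:
            best_state = model.state_dict()
        logger.info("epoch %d: train %.6f val %.6f (best %.6f @ %d)",
                    epoch, train_loss, val_loss, stopper.best, stopper.best_epoch)
        if stop:
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = config.max_epochs
    history.best_epoch = stopper.best_epoch
    history.best_val_loss = stopper.best
    model.load_state_dict(best_state)
    return model, history
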
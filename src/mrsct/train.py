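"""Loss functions, augmentation and the training loop.

The voxel-wise loss is the mean absolute difference between the predicted
and reference CT, optionally weighted by the per-voxel equalization map:

    L_eq = 1/(N*B) * sum_p sum_k MAP_eq(p, k) * |CT_reg(p, k) - sCT(p, k)|

With every enhancing factor zero the map is identically one and the
weighted loss reduces exactly to the unweighted one.  An MSE variant squares
the difference with the same weighting.

Two augmentation modes are provided.  *Per-epoch* augmentation draws a fresh
random flip/rotation of every example at the start of each epoch: the
dataset size stays constant, but no input image repeats across epochs.
*Traditional* augmentation pre-expands the dataset once with k random copies
plus the originals and trains on the fixed expanded set (k = 5 gives a
six-fold dataset).  Both use mirroring about the median (left-right) plane
and rotations uniform in [-10, 10] degrees about the image center.

Optimization follows the reference protocol: Adam with beta1 = 0.975,
beta2 = 0.999, learning rate 0.001, batch size 4, with a model checkpoint
after every epoch.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .core import CT_BACKGROUND, MRI_BACKGROUND, TrainingExample
from .model import MRI_SCALE, UNet, hu_to_unit, save_checkpoint, clone_state
from .nn import Adam

LOSS_MODES = ("weighted-l1", "unweighted-l1", "weighted-mse")
AUGMENT_MODES = ("none", "per-epoch", "traditional")


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the reference protocol)."""

    batch_size: int = 4
    learning_rate: float = 0.001
    beta1: float = 0.975
    beta2: float = 0.999
    epochs: int = 15
    loss_mode: str = "weighted-l1"
    augment_mode: str = "per-epoch"
    augment_copies: int = 5  # traditional mode: k extra copies
    rotation_range: float = 10.0  # degrees, symmetric
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.epochs < 1 or self.epochs > 100:
            raise ValueError("epochs must be in [1, 100]")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        if self.augment_mode not in AUGMENT_MODES:
            raise ValueError(f"augment_mode must be one of {AUGMENT_MODES}")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def loss_unweighted(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute voxel-wise difference over the whole batch."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean(np.abs(np.asarray(target, np.float64) - np.asarray(pred, np.float64))))


def loss_weighted(
    pred: np.ndarray, target: np.ndarray, eqmap: np.ndarray, squared: bool = False
) -> float:
    """Equalization-weighted mean absolute (or squared) difference.

    With ``eqmap`` identically one this equals ``loss_unweighted`` exactly.
    """
    if pred.shape != target.shape or eqmap.shape != target.shape:
        raise ValueError("pred/target/eqmap shapes must match")
    if np.min(eqmap) < 1.0:
        raise ValueError("equalization weights must be >= 1 everywhere")
    diff = np.asarray(target, np.float64) - np.asarray(pred, np.float64)
    err = diff**2 if squared else np.abs(diff)
    return float(np.mean(np.asarray(eqmap, np.float64) * err))


def _loss_and_grad(pred, target, weights, squared: bool):
    """Scaled-space loss and its gradient w.r.t. the prediction."""
    diff = target - pred
    m = diff.size
    w = weights if weights is not None else 1.0
    if squared:
        loss = float(np.mean(w * diff.astype(np.float64) ** 2))
        grad = (-2.0 / m) * (w * diff)
    else:
        loss = float(np.mean(w * np.abs(diff.astype(np.float64))))
        grad = (-1.0 / m) * (w * np.sign(diff))
    return loss, grad.astype(pred.dtype)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def draw_augmentation(rng: np.random.Generator, rotation_range: float = 10.0) -> tuple[bool, float]:
    """One (flip, angle) draw: flip with probability 1/2, angle uniform in ±range."""
    return bool(rng.random() < 0.5), float(rng.uniform(-rotation_range, rotation_range))


def augment_pair(
    example: TrainingExample,
    rng: np.random.Generator,
    flip: bool | None = None,
    angle: float | None = None,
    rotation_range: float = 10.0,
) -> TrainingExample:
    """Randomly mirrored/rotated copy of a training example.

    One flip decision (probability 1/2, about the median plane) and one
    rotation angle (uniform in ±``rotation_range`` degrees) are drawn and
    applied identically to the three MRI channels, the CT target and the
    equalization-map plane.  The MRI input channels are interpolated
    linearly; the CT target and the equalization map rotate by nearest
    neighbour — the target is supervision, and linear interpolation would
    invent intermediate HU at air/bone boundaries that exist in no real
    tissue, biasing the loss wherever structures are only a few voxels
    across.  Out-of-frame voxels are filled with each plane's background
    value.  ``flip``/``angle`` override the draws (used by tests); a
    no-flip, zero-angle call returns a bit-identical copy.  The input
    example is never mutated.
    """
    drawn_flip, drawn_angle = draw_augmentation(rng, rotation_range)
    if flip is None:
        flip = drawn_flip
    if angle is None:
        angle = drawn_angle
    mri, ct, eqmap = example.mri, example.ct, example.eqmap
    if flip:
        mri, ct, eqmap = mri[:, :, ::-1], ct[:, ::-1], eqmap[:, ::-1]
    if angle == 0.0:
        return TrainingExample(
            mri.copy(), ct.copy(), eqmap.copy(), example.patient_id, example.slice_index
        )

    def rot(plane, order, cval, axes=(0, 1)):
        return ndimage.rotate(
            plane, angle, axes=axes, reshape=False, order=order, mode="constant", cval=cval
        )

    mri = rot(np.ascontiguousarray(mri), 1, MRI_BACKGROUND, axes=(1, 2))
    ct = rot(ct, 0, CT_BACKGROUND)
    eqmap = rot(eqmap, 0, 1.0)
    return TrainingExample(mri, ct, eqmap, example.patient_id, example.slice_index)


def expand_traditional(
    examples: Sequence[TrainingExample],
    copies: int,
    seed: int,
    rotation_range: float = 10.0,
) -> list[TrainingExample]:
    """Originals plus ``copies`` random variations of each example."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA06)))
    out = [ex.copy() for ex in examples]
    for _ in range(copies):
        out.extend(augment_pair(ex, rng, rotation_range=rotation_range) for ex in examples)
    return out


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainingHistory:
    """Per-epoch artifacts of one training run."""

    losses: list[float] = field(default_factory=list)  # mean scaled-space loss
    checkpoints: list[list[np.ndarray]] = field(default_factory=list)  # model states
    eval_records: list[object] = field(default_factory=list)
    examples_per_epoch: list[int] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)


def _batch_arrays(examples: Sequence[TrainingExample], weighted: bool, dtype):
    x = np.stack([ex.mri.transpose(1, 2, 0) for ex in examples]).astype(dtype) * MRI_SCALE
    t = hu_to_unit(np.stack([ex.ct for ex in examples]))[..., None].astype(dtype)
    w = None
    if weighted:
        w = np.stack([ex.eqmap for ex in examples])[..., None].astype(dtype)
    return x, t, w


def run_training(
    atlas,
    model: UNet,
    config: TrainConfig,
    eval_hook: Callable[[int, UNet], object] | None = None,
    checkpoint_dir=None,
) -> TrainingHistory:
    """Train a model on an atlas (or plain example list) per the protocol.

    Each epoch reshuffles the examples from a seeded epoch-indexed stream —
    so resuming at epoch k reproduces the same order and augmentations —
    draws fresh augmentations in per-epoch mode, then runs Adam over
    mini-batches.  The model state is checkpointed after every epoch
    (in memory always, to ``checkpoint_dir/epoch_{k}.ckpt`` when given) and
    the per-epoch mean training loss is recorded.  ``eval_hook`` is invoked
    after each epoch with the trained-so-far model.
    """
    examples = list(atlas.examples) if hasattr(atlas, "examples") else list(atlas)
    if not examples:
        raise ValueError("empty atlas")
    if config.augment_mode == "traditional":
        examples = expand_traditional(
            examples, config.augment_copies, config.seed, config.rotation_range
        )
    weighted = config.loss_mode.startswith("weighted")
    squared = config.loss_mode.endswith("mse")
    dtype = model.config.np_dtype
    optimizer = Adam(
        model.params(), lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2
    )
    history = TrainingHistory()
    n = len(examples)
    for epoch in range(config.epochs):
        t_start = time.time()
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, epoch)))
        order = rng.permutation(n)
        if config.augment_mode == "per-epoch":
            epoch_examples = [
                augment_pair(examples[i], rng, rotation_range=config.rotation_range)
                for i in order
            ]
        else:
            epoch_examples = [examples[i] for i in order]
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = epoch_examples[start : start + config.batch_size]
            x, t, w = _batch_arrays(batch, weighted, dtype)
            pred = model.forward(x, train=True)
            loss, grad = _loss_and_grad(pred, t, w, squared)
            model.backward(grad)
            optimizer.step(model.grads())
            epoch_losses.append(loss)
        history.losses.append(float(np.mean(epoch_losses)))
        history.examples_per_epoch.append(len(epoch_examples))
        history.epoch_seconds.append(time.time() - t_start)
        history.checkpoints.append(clone_state(model))
        if checkpoint_dir is not None:
            save_checkpoint(model, f"{checkpoint_dir}/epoch_{epoch + 1}.ckpt")
        if eval_hook is not None:
            history.eval_records.append(eval_hook(epoch, model))
    return history


def nested_subsets(
    patients: Sequence, sizes: Sequence[int], seed: int = 0
) -> dict[int, list]:
    """Nested training subsets: subset(s1) is a prefix of subset(s2) for s1 < s2.

    A patient used in the 1-patient dataset is guaranteed to appear in the
    2-patient dataset and so on, implemented as prefixes of one seeded
    shuffle.
    """
    sizes = list(sizes)
    if sorted(sizes) != sizes:
        raise ValueError("sizes must be ascending")
    if sizes and sizes[-1] > len(patients):
        raise ValueError(f"size {sizes[-1]} exceeds cohort of {len(patients)}")
    if sizes and sizes[0] < 1:
        raise ValueError("sizes must be >= 1")
    order = np.random.default_rng(seed).permutation(len(patients))
    return {s: [patients[i] for i in order[:s]] for s in sizes}
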
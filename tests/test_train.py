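"""Losses, augmentation, the training loop, and nested subsets."""

import numpy as np
import pytest

from mrsct.core import TrainingExample
from mrsct.evaluate import capacity_per_patient, run_split, ExperimentConfig
from mrsct.model import UNetConfig, build_unet
from mrsct.train import (
    TrainConfig,
    augment_pair,
    draw_augmentation,
    expand_traditional,
    loss_unweighted,
    loss_weighted,
    nested_subsets,
    run_training,
    _loss_and_grad,
)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def test_loss_unweighted_basics(rng):
    assert loss_unweighted(np.ones((2, 2)), np.ones((2, 2))) == 0.0
    assert loss_unweighted(np.ones((2, 2)), np.zeros((2, 2))) == 1.0
    pred = rng.normal(size=(2, 5, 5))
    target = rng.normal(size=(2, 5, 5))
    brute = sum(
        abs(target[k, i, j] - pred[k, i, j])
        for k in range(2)
        for i in range(5)
        for j in range(5)
    ) / 50.0
    assert loss_unweighted(pred, target) == pytest.approx(brute, rel=1e-12)
    with pytest.raises(ValueError):
        loss_unweighted(np.ones((2, 2)), np.ones((3, 2)))


def test_loss_weighted_reduces_to_unweighted(rng):
    pred = rng.normal(size=(3, 4, 4))
    target = rng.normal(size=(3, 4, 4))
    ones = np.ones_like(pred)
    assert loss_weighted(pred, target, ones) == loss_unweighted(pred, target)


def test_loss_weighted_values_and_oracle(rng):
    # single voxel: weight 22.4, |diff| 2 -> 44.8
    assert loss_weighted(np.array([[[0.0]]]), np.array([[[2.0]]]), np.array([[[22.4]]])) == (
        pytest.approx(44.8)
    )
    pred = rng.normal(size=(2, 6, 6))
    target = rng.normal(size=(2, 6, 6))
    w = 1.0 + rng.random(size=(2, 6, 6)) * 20.0
    brute_l1 = np.mean([
        w[k, i, j] * abs(target[k, i, j] - pred[k, i, j])
        for k in range(2) for i in range(6) for j in range(6)
    ])
    brute_mse = np.mean([
        w[k, i, j] * (target[k, i, j] - pred[k, i, j]) ** 2
        for k in range(2) for i in range(6) for j in range(6)
    ])
    assert loss_weighted(pred, target, w) == pytest.approx(brute_l1, rel=1e-6)
    assert loss_weighted(pred, target, w, squared=True) == pytest.approx(brute_mse, rel=1e-6)
    with pytest.raises(ValueError):
        loss_weighted(pred, target, w * 0.5)  # weights below one


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def make_example(rng, n=12):
    return TrainingExample(
        mri=rng.random((3, n, n)) * 500.0,
        ct=rng.normal(0.0, 300.0, (n, n)),
        eqmap=1.0 + rng.random((n, n)) * 10.0,
    )


def test_augment_identity_short_circuit(rng):
    ex = make_example(rng)
    out = augment_pair(ex, rng, flip=False, angle=0.0)
    assert np.array_equal(out.mri, ex.mri)
    assert np.array_equal(out.ct, ex.ct)
    assert np.array_equal(out.eqmap, ex.eqmap)
    assert out.mri is not ex.mri  # a copy, not an alias


def test_forced_flip_is_an_involution(rng):
    ex = make_example(rng)
    once = augment_pair(ex, rng, flip=True, angle=0.0)
    assert not np.array_equal(once.ct, ex.ct)
    twice = augment_pair(once, rng, flip=True, angle=0.0)
    assert np.array_equal(twice.mri, ex.mri)
    assert np.array_equal(twice.ct, ex.ct)
    assert np.array_equal(twice.eqmap, ex.eqmap)


def test_rotation_angles_within_range(rng):
    draws = [draw_augmentation(rng, 10.0) for _ in range(1000)]
    angles = np.array([a for _, a in draws])
    flips = np.array([f for f, _ in draws])
    assert np.all(angles >= -10.0) and np.all(angles <= 10.0)
    assert 0.4 < flips.mean() < 0.6
    assert np.std(angles) > 1.0  # actually spread over the range


def test_augment_applies_same_geometry_to_all_planes(rng):
    ex = make_example(rng, n=16)
    # identical input channels must remain identical after augmentation
    plane = np.abs(ex.ct) + 100.0
    ref = augment_pair(
        TrainingExample(mri=np.stack([plane] * 3), ct=plane, eqmap=ex.eqmap),
        rng,
        flip=True,
        angle=7.0,
    )
    assert np.array_equal(ref.mri[0], ref.mri[1])
    assert np.array_equal(ref.mri[1], ref.mri[2])
    # CT and eq-map rotate by nearest neighbour: no values are invented
    out = augment_pair(ex, rng, flip=True, angle=7.0)
    assert set(np.unique(out.ct)) <= set(np.unique(ex.ct)) | {-1000.0}
    assert set(np.unique(out.eqmap)) <= set(np.unique(ex.eqmap)) | {1.0}
    assert out.eqmap.min() >= 1.0  # valid weights everywhere


def test_traditional_expansion_is_six_fold(rng):
    examples = [make_example(rng) for _ in range(4)]
    expanded = expand_traditional(examples, copies=5, seed=0)
    assert len(expanded) == 6 * len(examples)
    # originals are preserved at the front
    assert np.array_equal(expanded[0].ct, examples[0].ct)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def tiny_examples(rng, n=8, size=16):
    return [make_example(rng, size) for _ in range(n)]


def test_run_training_contracts(rng):
    examples = tiny_examples(rng)
    net = build_unet(UNetConfig(depth=1, base_filters=2, seed=0))
    config = TrainConfig(epochs=3, seed=5, augment_mode="per-epoch")
    history = run_training(examples, net, config)
    assert len(history.losses) == 3
    assert len(history.checkpoints) == 3
    assert history.examples_per_epoch == [len(examples)] * 3  # constant size

    net2 = build_unet(UNetConfig(depth=1, base_filters=2, seed=0))
    trad = TrainConfig(epochs=1, seed=5, augment_mode="traditional", augment_copies=5)
    history2 = run_training(examples, net2, trad)
    assert history2.examples_per_epoch == [6 * len(examples)]

    with pytest.raises(ValueError):
        run_training([], net, config)


def test_training_is_deterministic(rng):
    examples = tiny_examples(rng)
    losses = []
    for _ in range(2):
        net = build_unet(UNetConfig(depth=1, base_filters=2, seed=0))
        history = run_training(examples, net, TrainConfig(epochs=2, seed=9))
        losses.append(history.losses)
    assert losses[0] == losses[1]


def test_per_epoch_augmentation_never_mutates_the_atlas(rng):
    examples = tiny_examples(rng)
    before = [(ex.mri.copy(), ex.ct.copy(), ex.eqmap.copy()) for ex in examples]
    net = build_unet(UNetConfig(depth=1, base_filters=2, seed=0))
    run_training(examples, net, TrainConfig(epochs=2, seed=1, augment_mode="per-epoch"))
    for ex, (mri, ct, eq) in zip(examples, before):
        assert np.array_equal(ex.mri, mri)
        assert np.array_equal(ex.ct, ct)
        assert np.array_equal(ex.eqmap, eq)


def test_single_step_decreases_loss(rng):
    # gradient sanity: one Adam step on one example lowers that example's loss
    ex = make_example(rng, 16)
    net = build_unet(UNetConfig(depth=1, base_filters=4, seed=2))
    from mrsct.model import MRI_SCALE, hu_to_unit

    x = ex.mri.transpose(1, 2, 0)[None].astype(np.float32) * MRI_SCALE
    t = hu_to_unit(ex.ct)[None, :, :, None].astype(np.float32)
    from mrsct.nn import Adam

    opt = Adam(net.params(), lr=1e-3, beta1=0.975, beta2=0.999)
    pred = net.forward(x, train=True)
    loss0, grad = _loss_and_grad(pred, t, None, squared=False)
    net.backward(grad)
    opt.step(net.grads())
    pred1 = net.forward(x, train=True)
    loss1, _ = _loss_and_grad(pred1, t, None, squared=False)
    assert loss1 < loss0


def test_equalized_loss_improves_bone_mae_direction(tiny_cohort):
    """Desk-scale analogue of the bone-MAE improvement from loss weighting."""
    train, test = tiny_cohort[:4], tiny_cohort[4:]
    medians = {}
    for mode in ("weighted-l1", "unweighted-l1"):
        bones = []
        for seed in (0, 1, 2):
            cfg = ExperimentConfig(
                unet=UNetConfig(depth=2, base_filters=8),
                train=TrainConfig(epochs=8, seed=seed, loss_mode=mode, augment_mode="none"),
                out_shape=(48, 48),
                eval_epochs=[6, 7, 8],
            )
            cap = capacity_per_patient(run_split(train, test, cfg), window=3)
            bones.append(cap["bone"].mean())
        medians[mode] = float(np.median(bones))
    assert medians["weighted-l1"] < medians["unweighted-l1"]


def test_nested_subsets():
    patients = list(range(20))
    subsets = nested_subsets(patients, [1, 2, 5], seed=3)
    assert set(subsets[1]) < set(subsets[2]) < set(subsets[5])
    assert nested_subsets(patients, [20], seed=0)[20] == [
        patients[i] for i in np.random.default_rng(0).permutation(20)
    ]
    assert nested_subsets(patients, [1, 3], seed=4) == nested_subsets(patients, [1, 3], seed=4)
    with pytest.raises(ValueError):
        nested_subsets(patients, [5, 2], seed=0)
    with pytest.raises(ValueError):
        nested_subsets(patients, [25], seed=0)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(loss_mode="huber")
    with pytest.raises(ValueError):
        TrainConfig(beta1=1.5)
    with pytest.raises(ValueError):
        TrainConfig(epochs=101)
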
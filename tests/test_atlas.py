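"""Equalization factors, equalization maps, geometric normalization, slices."""

import numpy as np
import pytest

from mrsct.atlas import (
    CropError,
    POSTERIOR_MARGIN,
    build_atlas,
    center_and_crop,
    cohort_weights,
    contributing_factor,
    enhancing_factor,
    equalization_map,
    make_three_channel,
)
from mrsct.core import TISSUES, TissueMaps, Volume3D
from mrsct.phantom import generate_cohort


def random_maps(rng, shape=(2, 6, 6)):
    body = rng.random(shape) < 0.7
    r = rng.random(shape)
    fat = body & (r < 0.3)
    muscle = body & (r >= 0.3) & (r < 0.6)
    bone = body & (r >= 0.6) & (r < 0.75)
    return TissueMaps(body=body, fat=fat, muscle=muscle, bone=bone)


# ---------------------------------------------------------------------------
# CF / EF / MAP_eq
# ---------------------------------------------------------------------------


def test_contributing_factor_ratios():
    full = np.ones((10, 10), dtype=bool)
    assert contributing_factor(full, 100) == 1.0
    assert contributing_factor(np.zeros((10, 10), bool), 100) == 0.0
    quarter = np.zeros(100, dtype=bool)
    quarter[:25] = True
    assert contributing_factor(quarter, 100) == 0.25
    with pytest.raises(ValueError):
        contributing_factor(full, 0)


def test_enhancing_factor_reciprocal_mean():
    assert enhancing_factor([0.5]) == 2.0
    assert enhancing_factor([0.25, 0.25]) == 4.0
    assert enhancing_factor([0.1, 0.2, 0.3]) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        enhancing_factor([0.2, 0.0])
    with pytest.raises(ValueError):
        enhancing_factor([])


def test_ef_times_mean_cf_is_one(rng):
    maps = [random_maps(rng) for _ in range(5)]
    weights = cohort_weights(maps)
    for t in TISSUES:
        assert weights.efs[t] * np.mean(weights.cfs[t]) == pytest.approx(1.0)


def test_single_patient_identity_ef_nt_equals_ntotal(rng):
    maps = random_maps(rng)
    weights = cohort_weights([maps])
    total = maps.body.size
    for t, m in maps:
        assert weights.efs[t] * np.count_nonzero(m) == pytest.approx(total)


def test_equalization_map_values_and_oracle(rng):
    maps = random_maps(rng)
    efs = {"body": 1.4, "fat": 3.0, "muscle": 2.0, "bone": 20.0}
    eq = equalization_map(maps, efs)
    # outside body: the all-ones term only
    assert np.all(eq[~maps.body & ~maps.fat & ~maps.muscle & ~maps.bone] == 1.0)
    # body+bone voxel: 1 + EF_body + EF_bone
    if np.any(maps.bone):
        assert np.all(eq[maps.bone] == pytest.approx(1.0 + 1.4 + 20.0))
    # brute-force voxel-by-voxel oracle
    expected = np.ones(maps.shape)
    for idx in np.ndindex(*maps.shape):
        for t, m in maps:
            if m[idx]:
                expected[idx] += efs[t]
    assert np.allclose(eq, expected)


def test_equalization_map_conservation(rng):
    maps = random_maps(rng)
    efs = {"body": 1.5, "fat": 2.5, "muscle": 3.5, "bone": 12.0}
    eq = equalization_map(maps, efs)
    expected_excess = sum(efs[t] * np.count_nonzero(m) for t, m in maps)
    assert (eq - 1.0).sum() == pytest.approx(expected_excess)


def test_equalization_map_missing_ef():
    maps = random_maps(np.random.default_rng(0))
    with pytest.raises(ValueError):
        equalization_map(maps, {"body": 1.0})


def test_per_fold_efs_differ_with_tissue_fractions(rng):
    lean = [random_maps(rng) for _ in range(3)]
    # a cohort with systematically more bone
    bony = []
    for m in lean:
        extra = m.muscle & (rng.random(m.shape) < 0.5)
        bony.append(
            TissueMaps(body=m.body, fat=m.fat, muscle=m.muscle & ~extra, bone=m.bone | extra)
        )
    assert cohort_weights(lean).efs["bone"] != pytest.approx(cohort_weights(bony).efs["bone"])


# ---------------------------------------------------------------------------
# geometric normalization
# ---------------------------------------------------------------------------


def _ellipse_volume(shape=(2, 40, 40), center=(12, 14), radii=(8, 10)):
    z, r, c = shape
    rr, cc = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
    body2d = ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1
    body = np.broadcast_to(body2d, shape).copy()
    mri = np.where(body, 500.0, 0.0) + np.arange(r * c).reshape(r, c) * 0.001
    ct = np.where(body, 40.0, -1000.0)
    return Volume3D(np.broadcast_to(mri, shape).copy()), Volume3D(ct), body


def test_center_and_crop_posterior_rule_and_com():
    mri, ct, body = _ellipse_volume()
    out_mri, out_ct, out_body, _ = center_and_crop(mri, ct, body, (48, 48))
    _, r_idx, c_idx = np.nonzero(out_body)
    assert r_idx.max() == 48 - 1 - POSTERIOR_MARGIN
    assert abs(c_idx.mean() - (48 - 1) / 2.0) <= 0.5
    # background fills
    assert np.all(out_ct.data[~out_body] == -1000.0)
    assert np.all(out_mri.data[~out_body] == 0.0)
    # pure translation: in-body values preserved exactly
    assert np.array_equal(np.sort(out_ct.data[out_body]), np.sort(ct.data[body]))


def test_center_and_crop_identity_when_already_placed():
    shape = (1, 32, 32)
    rr, cc = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
    # construct a body already satisfying both placement rules
    body2d = ((rr - 16.0) / 5.0) ** 2 + ((cc - 15.5) / 6.0) ** 2 <= 1
    # posterior-most row must be rows-1-margin = 21 -> shift template
    shift = (32 - 1 - POSTERIOR_MARGIN) - np.nonzero(body2d)[0].max()
    body2d = np.roll(body2d, shift, axis=0)
    body = body2d[None]
    mri = Volume3D(np.where(body, 300.0, 0.0))
    ct = Volume3D(np.where(body, 40.0, -1000.0))
    out_mri, out_ct, out_body, _ = center_and_crop(mri, ct, body, (32, 32))
    assert np.array_equal(out_body, body)
    assert np.array_equal(out_mri.data, mri.data)
    assert np.array_equal(out_ct.data, ct.data)


def test_center_and_crop_rejects_oversized_body():
    mri, ct, body = _ellipse_volume()
    with pytest.raises(CropError):
        center_and_crop(mri, ct, body, (16, 16))


def test_extra_volumes_ride_along():
    mri, ct, body = _ellipse_volume()
    labels = body.astype(np.int8) * 2
    *_, out_body, extras = center_and_crop(mri, ct, body, (48, 48), extra_volumes=[labels])
    assert np.array_equal(extras[0] > 0, out_body)


# ---------------------------------------------------------------------------
# three-channel construction
# ---------------------------------------------------------------------------


def test_make_three_channel_rules():
    data = np.stack([np.full((4, 4), float(i)) for i in range(5)])
    v = Volume3D(data)
    interior = make_three_channel(v, 2)
    assert [p[0, 0] for p in interior] == [1.0, 2.0, 3.0]
    first = make_three_channel(v, 0)
    assert [p[0, 0] for p in first] == [1.0, 0.0, 1.0]  # second slice fills channel one
    last = make_three_channel(v, 4)
    assert [p[0, 0] for p in last] == [3.0, 4.0, 3.0]
    single = make_three_channel(Volume3D(data[:1]), 0)
    assert all(p[0, 0] == 0.0 for p in single)
    with pytest.raises(IndexError):
        make_three_channel(v, 5)


# ---------------------------------------------------------------------------
# atlas assembly
# ---------------------------------------------------------------------------


def test_build_atlas_counts_and_frozen_weights(tiny_spec):
    cohort = generate_cohort(tiny_spec, 4)
    items = [(p.patient_id, p.mri, p.ct, p.body) for p in cohort]
    train = build_atlas(items[:2], (48, 48))
    n_slices = tiny_spec.shape[0]
    assert all(len(p.examples) == n_slices for p in train.patients)
    assert len(train.examples) == 2 * n_slices

    # determinism of the enhancing factors
    again = build_atlas(items[:2], (48, 48))
    assert train.weights.efs == again.weights.efs

    # leakage guard: a test atlas built with frozen training weights keeps
    # them; weights recomputed from the test cohort itself would differ
    test_atlas = build_atlas(items[2:], (48, 48), weights=train.weights)
    assert test_atlas.weights is train.weights
    own = build_atlas(items[2:], (48, 48))
    assert own.weights.efs != train.weights.efs

    # every eq-map weight >= 1, exactly 1 outside all maps
    for p in train.patients:
        assert p.eqmap.min() >= 1.0
        outside = ~(p.maps.body | p.maps.fat | p.maps.muscle | p.maps.bone)
        assert np.all(p.eqmap[outside] == 1.0)
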
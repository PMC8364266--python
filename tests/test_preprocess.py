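"""MRI standardization, CT air masking, FCM clustering, intensity matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsct.core import AIR, BONE, FAT, MUSCLE, TissueMaps, Volume3D
from mrsct.preprocess import (
    ClusteringError,
    LandmarkError,
    LandmarkSet,
    MatchingError,
    classify_ct,
    ct_air_mask,
    extract_landmarks,
    fcm_cluster,
    match_ct_intensity,
    standardize_mri,
)


def vol(data):
    return Volume3D(np.asarray(data, dtype=np.float64).reshape(1, 1, -1))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def test_standardize_anchor_exactness():
    lm = LandmarkSet(muscle_median=317.0, fat_median=611.0)
    out = standardize_mri(vol([0.0, 317.0, 611.0]), lm).data.ravel()
    assert out[0] == 0.0
    assert out[1] == 400.0
    assert out[2] == 800.0


def test_standardize_piecewise_interpolation():
    # independent evaluation of the interpolant: 400 is midway between the
    # muscle (200) and fat (600) landmarks -> maps midway between 400 and 800
    lm = LandmarkSet(muscle_median=200.0, fat_median=600.0)
    out = standardize_mri(vol([100.0, 400.0, 800.0]), lm).data.ravel()
    assert out[0] == pytest.approx(200.0)  # 100/200 * 400
    assert out[1] == pytest.approx(600.0)
    # above fat: continue the second segment's slope (400 per 400 input units)
    assert out[2] == pytest.approx(1000.0)


@settings(max_examples=50, deadline=None)
@given(
    muscle=st.floats(1.0, 500.0),
    spread=st.floats(1.0, 500.0),
    values=st.lists(st.floats(0.0, 2000.0), min_size=2, max_size=30),
)
def test_standardize_is_monotone(muscle, spread, values):
    lm = LandmarkSet(muscle_median=muscle, fat_median=muscle + spread)
    ordered = np.sort(np.asarray(values))
    out = standardize_mri(vol(ordered), lm).data.ravel()
    assert np.all(np.diff(out) >= -1e-9)


def test_landmark_validation():
    with pytest.raises(LandmarkError):
        LandmarkSet(muscle_median=500.0, fat_median=400.0)
    with pytest.raises(LandmarkError):
        LandmarkSet(muscle_median=0.0, fat_median=400.0)


def test_extract_landmarks_median_conventions():
    data = np.zeros((1, 1, 5))
    data[0, 0] = [10.0, 20.0, 30.0, 100.0, 200.0]
    muscle_roi = np.array([[[True, True, True, False, False]]])
    fat_roi = np.array([[[False, False, False, True, True]]])
    lm = extract_landmarks(Volume3D(data), muscle_roi, fat_roi)
    assert lm.muscle_median == 20.0  # odd count: middle order statistic
    assert lm.fat_median == 150.0  # even count: midpoint convention
    with pytest.raises(LandmarkError):
        extract_landmarks(Volume3D(data), np.zeros_like(muscle_roi), fat_roi)


def test_landmarks_on_zero_noise_phantom(zero_noise_spec, zero_noise_phantom):
    p = zero_noise_phantom
    lm = extract_landmarks(p.mri, p.labels == MUSCLE, p.labels == FAT)
    assert lm.muscle_median == zero_noise_spec.mri_stats["muscle"][0]
    assert lm.fat_median == zero_noise_spec.mri_stats["fat"][0]


# ---------------------------------------------------------------------------
# air masking
# ---------------------------------------------------------------------------


def test_ct_air_mask_threshold():
    ct = vol([-400.0, 0.0, -251.0, -250.0])
    body = np.ones(ct.shape, dtype=bool)
    mask = ct_air_mask(ct, body)
    assert mask.ravel().tolist() == [True, False, True, False]


def test_ct_air_mask_outside_body_is_air():
    ct = vol([100.0, 100.0])
    body = np.array([[[True, False]]])
    assert ct_air_mask(ct, body).ravel().tolist() == [False, True]


def test_ct_air_mask_on_zero_noise_phantom(zero_noise_phantom):
    p = zero_noise_phantom
    mask = ct_air_mask(p.ct, p.body)
    assert np.array_equal(mask, p.labels == AIR)


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------


def reference_fcm(x, centers, m=2.0, iters=300):
    """Textbook FCM iteration, written independently of the implementation."""
    x = np.asarray(x, dtype=np.float64)
    centers = np.array(centers, dtype=np.float64)
    for _ in range(iters):
        d = np.abs(x[:, None] - centers[None, :])
        d = np.maximum(d, 1e-12)
        u = 1.0 / ((d[:, :, None] / d[:, None, :]) ** (2.0 / (m - 1.0))).sum(axis=2)
        centers = (u**m * x[:, None]).sum(axis=0) / (u**m).sum(axis=0)
    return np.sort(centers)


def test_fcm_k1_is_sample_mean(rng):
    x = rng.normal(50.0, 5.0, size=40)
    result = fcm_cluster(x, k=1)
    assert result.centers[0] == pytest.approx(x.mean())
    assert np.all(result.memberships == 1.0)


def test_fcm_two_well_separated_clusters():
    x = np.concatenate([np.zeros(50), np.full(50, 100.0)])
    result = fcm_cluster(x, k=2)
    expected = reference_fcm(x, [10.0, 90.0])
    assert np.allclose(result.centers, expected, atol=1.0)
    assert abs(result.centers[0] - 0.0) < 1.0
    assert abs(result.centers[1] - 100.0) < 1.0


def test_fcm_three_cluster_hu_mixture(rng):
    x = np.concatenate(
        [rng.normal(mu, 10.0, size=200) for mu in (-100.0, 40.0, 700.0)]
    )
    result = fcm_cluster(x, k=3)
    assert np.all(np.abs(result.centers - np.array([-100.0, 40.0, 700.0])) < 5.0)
    expected = reference_fcm(x, np.percentile(x, [10, 50, 90]))
    assert np.allclose(result.centers, expected, atol=0.5)


def test_fcm_objective_nonincreasing_and_memberships_normalized(rng):
    x = rng.normal(0.0, 1.0, 300) + np.repeat([0.0, 5.0, 20.0], 100)
    result = fcm_cluster(x, k=3)
    assert np.all(np.diff(result.objective) <= 1e-9)
    assert np.allclose(result.memberships.sum(axis=1), 1.0, atol=1e-9)
    assert result.centers[0] < result.centers[1] < result.centers[2]


def test_fcm_errors():
    with pytest.raises(ClusteringError):
        fcm_cluster(np.arange(5.0), k=0)
    with pytest.raises(ClusteringError):
        fcm_cluster(np.ones(10), k=2)  # degenerate: all identical
    with pytest.raises(ClusteringError):
        fcm_cluster(np.arange(2.0), k=3)  # sample smaller than k
    with pytest.raises(ClusteringError):
        fcm_cluster(np.arange(5.0), k=2, fuzziness=1.0)


# ---------------------------------------------------------------------------
# CT classification and intensity matching
# ---------------------------------------------------------------------------


def test_classify_ct_zero_noise_recovers_labels(zero_noise_phantom):
    p = zero_noise_phantom
    maps = classify_ct(p.ct, p.body)
    assert np.array_equal(maps.fat, p.labels == FAT)
    assert np.array_equal(maps.muscle, p.labels == MUSCLE)
    assert np.array_equal(maps.bone, p.labels == BONE)
    # partition invariants: disjoint sub-tissues, all inside the body map,
    # nothing outside the body
    assert not np.any(maps.fat & maps.muscle)
    assert not np.any((maps.fat | maps.muscle | maps.bone) & ~maps.body)
    assert np.array_equal(maps.body, p.body)
    for name in ("fat", "muscle", "bone"):
        assert not np.any(maps[name][~p.body])


def test_classify_ct_needs_three_levels():
    data = np.full((1, 4, 4), -1000.0)
    data[0, 1:3, 1:3] = 40.0  # one non-air level only
    body = np.zeros((1, 4, 4), dtype=bool)
    body[0, 1:3, 1:3] = True
    with pytest.raises(ClusteringError):
        classify_ct(Volume3D(data), body)


def _maps_for(values, fat_idx, muscle_idx, bone_idx):
    shape = (1, 1, len(values))
    body = np.ones(shape, dtype=bool)
    fat = np.zeros(shape, dtype=bool)
    muscle = np.zeros(shape, dtype=bool)
    bone = np.zeros(shape, dtype=bool)
    fat[0, 0, fat_idx] = True
    muscle[0, 0, muscle_idx] = True
    bone[0, 0, bone_idx] = True
    return TissueMaps(body=body, fat=fat, muscle=muscle, bone=bone)


def test_match_ct_affine_map_with_known_centers():
    # fat center -100, muscle center 40 (values symmetric around 40):
    # voxel at -30 HU -> 400 + (-30-40)*400/(-100-40) = 600
    values = [-100.0, -100.0, -30.0, 110.0, 40.0, 40.0, 700.0]
    maps = _maps_for(values, fat_idx=[0, 1], muscle_idx=[2, 3, 4, 5], bone_idx=[6])
    ct = vol(values)
    out = match_ct_intensity(ct, maps.body, maps=maps).data.ravel()
    assert out[0] == pytest.approx(800.0)  # fat center
    assert out[2] == pytest.approx(600.0)  # derived affine point
    assert out[4] == pytest.approx(400.0)  # muscle center
    assert out[6] == 0.0  # bone replaced by air value


def test_match_ct_on_zero_noise_phantom(zero_noise_phantom):
    p = zero_noise_phantom
    out = match_ct_intensity(p.ct, p.body)
    assert np.allclose(out.data[p.labels == FAT], 800.0, atol=1e-6)
    assert np.allclose(out.data[p.labels == MUSCLE], 400.0, atol=1e-6)
    assert np.all(out.data[p.labels == BONE] == 0.0)
    assert np.all(out.data[~p.body] == 0.0)


def test_match_ct_coincident_centers_error():
    values = [10.0, 10.0, 10.0, 10.0, 700.0]
    maps = _maps_for(values, fat_idx=[0, 1], muscle_idx=[2, 3], bone_idx=[4])
    with pytest.raises(MatchingError):
        match_ct_intensity(vol(values), maps.body, maps=maps)
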
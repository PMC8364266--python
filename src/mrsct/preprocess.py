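"""MRI landmark standardization and CT intensity matching.

Two preprocessing streams prepare a co-registered MRI/CT pair for atlas
construction:

* **MRI standardization** — a landmark-based piecewise-linear intensity
  remapping that pins air to 0, the muscle median to 400 and the fat median
  to 800, removing scanner-dependent intensity variation between patients.
* **CT intensity matching** — air voxels are excluded by thresholding
  (HU < -250), the remaining body voxels are classified into fat, muscle and
  bone by fuzzy c-means on the HU histogram, bone is replaced by the air
  value (bone is dark on TRUFI, like air), and an affine map sends the
  muscle/fat cluster centers onto the 400/800 MRI landmarks.  Because fat
  sits *below* muscle in HU but *above* it on TRUFI, the affine slope is
  negative: the CT contrast is inverted to resemble the MR image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TissueMaps, Volume3D

#: Threshold below which a CT voxel counts as air (HU).
AIR_HU_THRESHOLD = -250.0

#: Standardized intensity targets.
TARGET_AIR, TARGET_MUSCLE, TARGET_FAT = 0.0, 400.0, 800.0


class LandmarkError(ValueError):
    """Invalid landmark configuration (e.g. fat median <= muscle median)."""


class ClusteringError(ValueError):
    """FCM cannot run: too few samples, degenerate data, or bad k."""


class MatchingError(ValueError):
    """CT intensity matching failed (coincident fat/muscle centers)."""


@dataclass
class LandmarkSet:
    """Per-patient intensity landmarks for MRI standardization."""

    muscle_median: float
    fat_median: float
    target_muscle: float = TARGET_MUSCLE
    target_fat: float = TARGET_FAT
    target_air: float = TARGET_AIR

    def __post_init__(self) -> None:
        if not (0.0 < self.muscle_median < self.fat_median):
            raise LandmarkError(
                f"need 0 < muscle_median < fat_median, got "
                f"({self.muscle_median}, {self.fat_median})"
            )


def extract_landmarks(mri: Volume3D, muscle_roi: np.ndarray, fat_roi: np.ndarray) -> LandmarkSet:
    """Median intensity of a muscle and a fat region of interest.

    The even-count median is the midpoint of the two central order
    statistics; landmark-exactness guarantees elsewhere rely on this
    convention.
    """
    if not muscle_roi.any():
        raise LandmarkError("muscle ROI is empty")
    if not fat_roi.any():
        raise LandmarkError("fat ROI is empty")
    return LandmarkSet(
        muscle_median=float(np.median(mri.data[muscle_roi])),
        fat_median=float(np.median(mri.data[fat_roi])),
    )


def standardize_mri(mri: Volume3D, landmarks: LandmarkSet) -> Volume3D:
    """Piecewise-linear monotone intensity remapping.

    0 -> 0, muscle median -> 400, fat median -> 800, linear in between;
    values above the fat landmark continue with the slope of the
    muscle-to-fat segment.  Landmark values map exactly (the map is built
    from ratios of differences, so ``muscle_median`` yields 400.0 bit-exact).
    """
    v = np.asarray(mri.data, dtype=np.float64)
    if v.min() < 0:
        raise ValueError("standardize_mri expects non-negative MRI intensities")
    mm, fm = landmarks.muscle_median, landmarks.fat_median
    t_m, t_f = landmarks.target_muscle, landmarks.target_fat
    lower = t_m * (v / mm)
    upper = t_m + (t_f - t_m) * ((v - mm) / (fm - mm))  # also the >fat continuation
    out = np.where(v <= mm, lower, upper)
    return mri.with_data(out)


def ct_air_mask(ct: Volume3D, body: np.ndarray) -> np.ndarray:
    """Air voxels: HU < -250 inside the body, plus everything outside it."""
    return (ct.data < AIR_HU_THRESHOLD) | ~body.astype(bool)


@dataclass
class FcmResult:
    """Fuzzy c-means output on a 1-D sample.

    Centers are sorted ascending; membership columns follow the same order
    and sum to one per sample.  ``labels`` is the argmax membership with ties
    resolved toward the lowest cluster index.
    """

    centers: np.ndarray  # (k,)
    memberships: np.ndarray  # (n, k)
    labels: np.ndarray  # (n,)
    objective: list[float] = field(default_factory=list)
    n_iter: int = 0


def fcm_cluster(
    values: np.ndarray,
    k: int,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int | None = None,
) -> FcmResult:
    """Fuzzy c-means on a 1-D scalar sample.

    Alternates the standard membership / center updates until the maximum
    center shift falls below ``tol``.  Initialization is deterministic —
    centers start at evenly spaced percentiles (10th..90th) of the sample —
    so ``seed`` is accepted for interface symmetry but unused.
    """
    del seed  # deterministic percentile initialization
    x = np.asarray(values, dtype=np.float64).ravel()
    if k < 1:
        raise ClusteringError(f"k must be >= 1, got {k}")
    if fuzziness <= 1.0:
        raise ClusteringError("fuzziness must be > 1")
    if x.size < k:
        raise ClusteringError(f"sample size {x.size} < k={k}")
    if k > 1 and np.ptp(x) == 0.0:
        raise ClusteringError("degenerate sample: all values identical with k > 1")

    if k == 1:
        centers = np.array([x.mean()])
        memberships = np.ones((x.size, 1))
        return FcmResult(centers, memberships, np.zeros(x.size, dtype=int), [0.0], 0)

    centers = np.percentile(x, np.linspace(10.0, 90.0, k))
    # Percentile ties (heavily discrete samples) would collapse clusters;
    # nudge apart deterministically.
    for j in range(1, k):
        if centers[j] <= centers[j - 1]:
            centers[j] = centers[j - 1] + max(1e-6, 1e-6 * np.ptp(x))

    expo = 2.0 / (fuzziness - 1.0)
    objective: list[float] = []
    n_iter = 0
    memberships = np.empty((x.size, k))
    for n_iter in range(1, max_iter + 1):
        d = np.abs(x[:, None] - centers[None, :])
        zero = d < 1e-12
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** -expo
            memberships = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            memberships[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        um = memberships**fuzziness
        objective.append(float((um * d**2).sum()))
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            break

    order = np.argsort(centers)
    centers = centers[order]
    memberships = memberships[:, order]
    labels = np.argmax(memberships, axis=1)
    return FcmResult(centers, memberships, labels, objective, n_iter)


def _classify_ct_with_centers(
    ct: Volume3D,
    body: np.ndarray,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> tuple[TissueMaps, np.ndarray]:
    body = body.astype(bool)
    if not body.any():
        raise ValueError("body mask is empty")
    air = ct_air_mask(ct, body)
    tissue = body & ~air
    values = ct.data[tissue]
    if np.unique(values).size < 3:
        raise ClusteringError("fewer than 3 distinct HU levels among non-air body voxels")
    result = fcm_cluster(values, k=3, fuzziness=fuzziness, tol=tol, max_iter=max_iter)
    maps = {}
    for idx, name in enumerate(("fat", "muscle", "bone")):
        m = np.zeros(ct.shape, dtype=bool)
        m[tissue] = result.labels == idx
        maps[name] = m
    return TissueMaps(body=body, **maps), result.centers


def classify_ct(
    ct: Volume3D,
    body: np.ndarray,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> TissueMaps:
    """Four binary classification maps (body, fat, muscle, bone) from a CT.

    Air is excluded by thresholding (HU < -250); the remaining body voxels
    are clustered into three groups by FCM and labeled fat/muscle/bone in
    ascending HU-center order.  Internal air belongs to the body map only.
    """
    maps, _ = _classify_ct_with_centers(ct, body, fuzziness, tol, max_iter)
    return maps


def match_ct_intensity(
    ct: Volume3D,
    body: np.ndarray,
    maps: TissueMaps | None = None,
    air_value: float = TARGET_AIR,
) -> Volume3D:
    """Remap a CT so its fat/muscle cluster centers hit the MRI landmarks.

    Bone voxels are replaced by the air value (bone is dark on TRUFI); fat
    and muscle intensities are sent through the affine map taking the muscle
    cluster center to 400 and the fat center to 800.  Since fat HU < muscle
    HU, the slope is negative — the CT contrast inverts to match the MR
    appearance.  Air (outside the body or HU < -250 inside it) maps to 0.
    """
    if maps is None:
        maps, centers = _classify_ct_with_centers(ct, body)
        c_fat, c_muscle = float(centers[0]), float(centers[1])
    else:
        # Externally supplied maps carry no FCM centers; fall back to the
        # masked means, which coincide with the centers at convergence for
        # well-separated clusters.
        c_fat = float(ct.data[maps.fat].mean())
        c_muscle = float(ct.data[maps.muscle].mean())
    if abs(c_fat - c_muscle) < 1e-9:
        raise MatchingError("fat and muscle cluster centers coincide")
    out = np.full(ct.shape, air_value, dtype=np.float64)
    soft = maps.fat | maps.muscle
    out[soft] = TARGET_MUSCLE + (TARGET_FAT - TARGET_MUSCLE) * (
        (ct.data[soft] - c_muscle) / (c_fat - c_muscle)
    )
    # Bone voxels were already initialized to the air value above.
    return ct.with_data(out)


def flatten_bias(
    mri: Volume3D, body: np.ndarray, degree: int = 2, enabled: bool = False
) -> Volume3D:
    """Optional polynomial bias-flattening utility (disabled by default).

    Fits a low-order polynomial in the voxel coordinates to the in-body
    log-intensities and divides it out, normalized to preserve the in-body
    mean.  The phantoms control their bias field explicitly, so this stays
    off unless requested.
    """
    if not enabled:
        return mri
    body = body.astype(bool)
    z, r, c = np.nonzero(body)
    coords = np.stack([z, r, c], axis=1).astype(np.float64)
    coords -= coords.mean(axis=0)
    scale = coords.std(axis=0)
    scale[scale == 0] = 1.0
    coords /= scale
    cols = [np.ones(len(z))]
    for d in range(1, degree + 1):
        cols.extend(coords[:, a] ** d for a in range(3))
    design = np.stack(cols, axis=1)
    intensity = np.log1p(np.maximum(mri.data[body], 0.0))
    coeffs, *_ = np.linalg.lstsq(design, intensity, rcond=None)
    fit = design @ coeffs
    field = np.expm1(fit - fit.mean()) + 1.0
    out = mri.data.copy()
    out[body] = mri.data[body] / np.maximum(field, 1e-6)
    return mri.with_data(out)
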
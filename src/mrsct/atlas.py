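"""Training-ready atlas construction.

Turns preprocessed, co-registered MRI/CT pairs into the inputs the network
trains on:

* **Contributing factor** CF_T = N_T / N_Total — the fraction of a patient's
  voxels occupied by tissue T.
* **Enhancing factor** EF_T = n / sum_i CF_T(i) — the reciprocal of the
  cohort-mean contributing factor.  Rare tissues (bone) get large enhancing
  factors, which is the entire point: the voxel-wise loss would otherwise be
  dominated by background, fat and muscle.
* **Equalization map** MAP_eq = 1 + sum_T EF_T * MAP_T — a per-voxel loss
  weight; the all-ones term guarantees background air still contributes.
* **Geometric normalization** — pure integer translations placing the body
  center of mass at the image center and the most posterior body voxel a
  fixed margin from the posterior edge, followed by a crop/pad to the
  network's input shape.  No resampling: voxel values are preserved exactly.
* **Three-channel slices** — each training example stacks slices
  (Z-1, Z, Z+1); at the volume ends the missing neighbor is replaced by the
  second slice from that end.

Enhancing factors are a *training-cohort* statistic: they are computed from
training patients only and frozen before any test-set use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CT_BACKGROUND, MRI_BACKGROUND, TISSUES, TissueMaps, TrainingExample, Volume3D
from .preprocess import classify_ct

#: Background rows between the most posterior body voxel and the image edge.
POSTERIOR_MARGIN = 10


class CropError(ValueError):
    """The body does not fit inside the requested output shape."""


@dataclass
class EqualizationWeights:
    """Per-patient contributing factors and the cohort enhancing factors."""

    cfs: dict[str, list[float]]  # tissue -> CF per training patient
    efs: dict[str, float]  # tissue -> EF
    n: int  # number of training patients

    def __post_init__(self) -> None:
        for t, values in self.cfs.items():
            if any(not (0.0 <= v <= 1.0) for v in values):
                raise ValueError(f"CF values for {t} outside [0, 1]")


def contributing_factor(map_t: np.ndarray, total_voxels: int) -> float:
    """CF_T = N_T / N_Total: fraction of the volume occupied by tissue T."""
    if total_voxels <= 0:
        raise ValueError(f"total_voxels must be positive, got {total_voxels}")
    return float(np.count_nonzero(map_t)) / float(total_voxels)


def enhancing_factor(cfs: list[float]) -> float:
    """EF_T = n / sum_i CF_T(i): reciprocal of the cohort-mean CF.

    A tissue absent in any patient (CF = 0) makes the cohort mean
    ill-defined as an equal-contribution target, so it is rejected.
    """
    if len(cfs) == 0:
        raise ValueError("need at least one contributing factor")
    if any(cf <= 0.0 for cf in cfs):
        raise ValueError("a patient has CF = 0 for this tissue (tissue absent)")
    return float(len(cfs)) / float(sum(cfs))


def cohort_weights(maps_per_patient: list[TissueMaps]) -> EqualizationWeights:
    """Contributing and enhancing factors over a training cohort."""
    cfs: dict[str, list[float]] = {t: [] for t in TISSUES}
    for maps in maps_per_patient:
        total = int(np.prod(maps.shape))
        for t, m in maps:
            cfs[t].append(contributing_factor(m, total))
    efs = {t: enhancing_factor(v) for t, v in cfs.items()}
    return EqualizationWeights(cfs=cfs, efs=efs, n=len(maps_per_patient))


def equalization_map(maps: TissueMaps, efs: dict[str, float]) -> np.ndarray:
    """MAP_eq = 1 + sum_T EF_T * MAP_T over T in {body, fat, muscle, bone}.

    The body map overlaps its sub-tissue maps, so a bone voxel weighs
    1 + EF_body + EF_bone; a voxel outside the body weighs exactly 1.
    Internal air sits in the body map only, hence 1 + EF_body.
    """
    missing = [t for t in TISSUES if t not in efs]
    if missing:
        raise ValueError(f"enhancing factors missing for: {missing}")
    out = np.ones(maps.shape, dtype=np.float64)
    for t, m in maps:
        if m.shape != maps.shape:
            raise ValueError("tissue map grid mismatch")
        out += efs[t] * m
    return out


def _body_shifts(body: np.ndarray, out_shape: tuple[int, int]) -> tuple[int, int]:
    """Integer (row, col) shifts: COM to center, posterior rule on rows."""
    rows_out, cols_out = out_shape
    _, r_idx, c_idx = np.nonzero(body)
    com_c = c_idx.mean()
    shift_c = int(np.round((cols_out - 1) / 2.0 - com_c))
    # The posterior rule overrides the COM result on the anterior-posterior
    # (row) axis: the most posterior body voxel lands POSTERIOR_MARGIN rows
    # from the posterior edge.
    p_body = r_idx.max()
    shift_r = (rows_out - 1 - POSTERIOR_MARGIN) - p_body
    return shift_r, shift_c


def center_and_crop(
    mri: Volume3D,
    ct: Volume3D,
    body: np.ndarray,
    out_shape: tuple[int, int] = (224, 320),
    extra_volumes: list[np.ndarray] | None = None,
) -> tuple[Volume3D, Volume3D, np.ndarray, list[np.ndarray]]:
    """Center the body and crop/pad to the network input shape.

    A single integer in-plane translation is applied to the whole stack: the
    body center of mass goes to the image center column-wise, and the most
    posterior body voxel is placed ``POSTERIOR_MARGIN`` rows from the
    posterior (bottom) edge, overriding the center-of-mass row.  Voxels
    outside the body become background: 0 for MRI, -1000 HU for CT (air must
    stay physically sensible because losses and MAE are computed in HU).

    ``extra_volumes`` (e.g. label volumes) ride along with the same
    translation, nearest-neighbour semantics (integer shift, so exact),
    background fill 0.
    """
    body = body.astype(bool)
    if not body.any():
        raise ValueError("body mask is empty")
    n_slices = body.shape[0]
    rows_out, cols_out = out_shape
    _, r_idx, c_idx = np.nonzero(body)
    extent_r = r_idx.max() - r_idx.min() + 1
    extent_c = c_idx.max() - c_idx.min() + 1
    if extent_r > rows_out - POSTERIOR_MARGIN or extent_c > cols_out:
        raise CropError(
            f"body extent ({extent_r}x{extent_c}) does not fit in {out_shape} "
            f"with a {POSTERIOR_MARGIN}-row posterior margin"
        )
    shift_r, shift_c = _body_shifts(body, out_shape)

    def place(src: np.ndarray, fill: float, dtype=None) -> np.ndarray:
        out = np.full((n_slices, rows_out, cols_out), fill, dtype=dtype or src.dtype)
        rows_in, cols_in = src.shape[1:]
        # Overlap of the shifted source with the output window.
        r0_out, r1_out = max(shift_r, 0), min(rows_in + shift_r, rows_out)
        c0_out, c1_out = max(shift_c, 0), min(cols_in + shift_c, cols_out)
        if r0_out < r1_out and c0_out < c1_out:
            out[:, r0_out:r1_out, c0_out:c1_out] = src[
                :, r0_out - shift_r : r1_out - shift_r, c0_out - shift_c : c1_out - shift_c
            ]
        return out

    body_out = place(body, False)
    mri_out = place(mri.data, MRI_BACKGROUND, dtype=np.float64)
    ct_out = place(ct.data, CT_BACKGROUND, dtype=np.float64)
    mri_out[~body_out] = MRI_BACKGROUND
    ct_out[~body_out] = CT_BACKGROUND
    extras = [place(v, 0) for v in (extra_volumes or [])]
    return mri.with_data(mri_out), ct.with_data(ct_out), body_out, extras


def make_three_channel(mri: Volume3D, z: int) -> np.ndarray:
    """Stack slices (Z-1, Z, Z+1) as a three-channel image.

    At the first and last slice the missing neighbor is replaced by the
    second slice from that end, mirroring the volume boundary.
    """
    n = mri.shape[0]
    if not 0 <= z < n:
        raise IndexError(f"slice {z} out of range for {n}-slice volume")
    if n == 1:
        lo = hi = 0
    else:
        lo = z - 1 if z > 0 else 1
        hi = z + 1 if z < n - 1 else n - 2
    return np.stack([mri.data[lo], mri.data[z], mri.data[hi]], axis=0)


@dataclass
class PatientAtlas:
    """Training-ready products for one patient."""

    patient_id: int
    examples: list[TrainingExample]
    maps: TissueMaps
    eqmap: np.ndarray
    mri: Volume3D
    ct: Volume3D
    body: np.ndarray


@dataclass
class Atlas:
    """A cohort atlas: per-patient training examples plus the frozen EFs."""

    patients: list[PatientAtlas]
    weights: EqualizationWeights

    @property
    def examples(self) -> list[TrainingExample]:
        return [ex for p in self.patients for ex in p.examples]


def build_atlas(
    cohort: list[tuple[int, Volume3D, Volume3D, np.ndarray]],
    out_shape: tuple[int, int] = (224, 320),
    weights: EqualizationWeights | None = None,
) -> Atlas:
    """Build per-patient training examples, tissue maps and equalization maps.

    ``cohort`` holds preprocessed, co-registered ``(patient_id, mri, ct,
    body)`` tuples.  When ``weights`` is None the enhancing factors are
    computed from this cohort (training mode); passing frozen training
    weights builds a test-set atlas without leaking test statistics.
    """
    if not cohort:
        raise ValueError("empty cohort")
    prepared = []
    for pid, mri, ct, body in cohort:
        mri_c, ct_c, body_c, _ = center_and_crop(mri, ct, body, out_shape)
        maps = classify_ct(ct_c, body_c)
        prepared.append((pid, mri_c, ct_c, body_c, maps))
    if weights is None:
        weights = cohort_weights([maps for *_, maps in prepared])
    patients = []
    for pid, mri_c, ct_c, body_c, maps in prepared:
        eqmap = equalization_map(maps, weights.efs)
        examples = [
            TrainingExample(
                mri=make_three_channel(mri_c, z),
                ct=ct_c.data[z],
                eqmap=eqmap[z],
                patient_id=pid,
                slice_index=z,
            )
            for z in range(mri_c.shape[0])
        ]
        patients.append(
            PatientAtlas(
                patient_id=pid,
                examples=examples,
                maps=maps,
                eqmap=eqmap,
                mri=mri_c,
                ct=ct_c,
                body=body_c,
            )
        )
    return Atlas(patients=patients, weights=weights)
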
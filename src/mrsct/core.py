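"""Core in-memory containers shared across the pipeline.

The internal axis convention for every volume is ``(slice, row, col)`` with
rows running anterior -> posterior (row 0 is the most anterior row, the last
row is the most posterior — the patient lies supine, so the table side is at
the bottom of the image).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Integer tissue codes used by the phantom ground truth and the classifiers.
AIR, FAT, MUSCLE, BONE = 0, 1, 2, 3

#: Tissue names in classification-map order.
TISSUES = ("body", "fat", "muscle", "bone")

#: Background fill values per modality (HU for CT, arbitrary units for MRI).
CT_BACKGROUND = -1000.0
MRI_BACKGROUND = 0.0


@dataclass
class Volume3D:
    """A 3-D scalar voxel grid with spacing, in ``(slice, row, col)`` order.

    Parameters
    ----------
    data
        Voxel values; MRI intensity or CT Hounsfield units.
    spacing
        Voxel size in mm per axis, ``(slice, row, col)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 1.5, 1.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), tuple(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same grid metadata, new voxel values."""
        return Volume3D(np.asarray(data), tuple(self.spacing))


@dataclass
class TissueMaps:
    """The four binary classification maps MAP_T on one volume grid.

    ``fat``, ``muscle`` and ``bone`` are pairwise disjoint and each is a
    subset of ``body``.  Internal air (e.g. a rectal gas pocket) belongs to
    ``body`` only.
    """

    body: np.ndarray
    fat: np.ndarray
    muscle: np.ndarray
    bone: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.body, self.fat, self.muscle, self.bone)}
        if len(shapes) != 1:
            raise ValueError(f"maps live on different grids: {shapes}")
        for name in ("fat", "muscle", "bone"):
            m = getattr(self, name)
            if np.any(m & ~self.body):
                raise ValueError(f"{name} map extends outside the body map")
        if np.any((self.fat & self.muscle) | (self.fat & self.bone) | (self.muscle & self.bone)):
            raise ValueError("fat/muscle/bone maps overlap")

    def __iter__(self):
        yield from ((t, getattr(self, t)) for t in TISSUES)

    def __getitem__(self, tissue: str) -> np.ndarray:
        if tissue not in TISSUES:
            raise KeyError(tissue)
        return getattr(self, tissue)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.body.shape


@dataclass
class TrainingExample:
    """One network input/target pair built from a single axial slice.

    ``mri`` holds the three consecutive MRI planes (Z-1, Z, Z+1) stacked on
    the leading axis; ``ct`` is the target CT plane in HU; ``eqmap`` is the
    per-voxel loss weight plane (>= 1 everywhere).
    """

    mri: np.ndarray  # (3, rows, cols)
    ct: np.ndarray  # (rows, cols), HU
    eqmap: np.ndarray  # (rows, cols), weights >= 1
    patient_id: int = 0
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.mri.ndim != 3 or self.mri.shape[0] != 3:
            raise ValueError(f"mri must be (3, rows, cols), got {self.mri.shape}")
        if self.ct.shape != self.mri.shape[1:] or self.eqmap.shape != self.ct.shape:
            raise ValueError("mri/ct/eqmap planes do not share one shape")

    def copy(self) -> "TrainingExample":
        return TrainingExample(
            self.mri.copy(), self.ct.copy(), self.eqmap.copy(), self.patient_id, self.slice_index
        )
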
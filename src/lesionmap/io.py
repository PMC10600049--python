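"""Cohort assembly and NIfTI input/output.

All lesion masks are consumed already co-registered to one shared template
grid (e.g. the MNI ICBM-152 space).  Registration and resampling are out of
scope here: a grid mismatch is an error, never silently resampled, because
implicit resampling corrupts voxel-wise counts.

Coordinate conventions: voxel indices are 0-based; world coordinates come
from the NIfTI affine; under an RAS-oriented affine the left hemisphere is
world x < 0 and the right is x > 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from . import scoring
from .scoring import (
    MissingItemError,
    ScoreInconsistencyError,
    score_cognitive_subscale,
    validate_score,
)

__all__ = [
    "TemplateGrid",
    "LesionMask",
    "Patient",
    "Cohort",
    "GridMismatchError",
    "MaskFormatError",
    "CohortError",
    "load_mask",
    "load_cohort",
    "write_map",
    "write_mask",
    "MANIFEST_ITEM_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Max absolute elementwise affine difference tolerated between co-registered files.
AFFINE_TOL = 1e-4
#: Voxel values must be within this tolerance of 0 or 1.
BINARY_TOL = 1e-6

MANIFEST_ITEM_COLUMNS = (
    "pre_item_memory",
    "pre_item_concentration",
    "post_item_memory",
    "post_item_concentration",
)
_KNOWN_COLUMNS = set(MANIFEST_ITEM_COLUMNS) | {
    "patient_id",
    "pre_score",
    "post_score",
    "pre_volume_ml",
    "post_volume_ml",
    "mask_path",
}


class GridMismatchError(ValueError):
    """Two images do not share the template grid (shape and/or affine)."""


class MaskFormatError(ValueError):
    """A lesion mask is not a valid binary segmentation."""


class CohortError(ValueError):
    """The cohort manifest is malformed or internally inconsistent."""


@dataclass(frozen=True)
class TemplateGrid:
    """A shared voxel lattice: shape plus the voxel-index -> world-mm affine."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "affine", aff)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be strictly positive on all axes")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.sqrt((np.asarray(self.affine)[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.affine)[:3, :3])))

    @classmethod
    def centered(cls, shape=(32, 32, 32), voxel_size_mm=4.0) -> "TemplateGrid":
        """An RAS grid with isotropic voxels and the world origin at its center."""
        shape = tuple(int(s) for s in shape)
        vs = float(voxel_size_mm)
        affine = np.diag([vs, vs, vs, 1.0])
        affine[:3, 3] = -vs * (np.array(shape) - 1) / 2.0
        return cls(shape=shape, affine=affine)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (…, 3) to world mm coordinates (…, 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)

    def matches(self, other: "TemplateGrid", tol: float = AFFINE_TOL) -> bool:
        return self.shape == other.shape and bool(
            np.max(np.abs(self.affine - other.affine)) <= tol
        )

    def require_match(self, other: "TemplateGrid", context: str = "") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"grid mismatch{' for ' + context if context else ''}: "
                f"shape {self.shape} vs {other.shape}, affines\n{self.affine}\nvs\n{other.affine}"
            )


@dataclass
class LesionMask:
    """A binary tumor segmentation for one patient on a template grid."""

    patient_id: str
    voxels: np.ndarray  # boolean, 3D

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.dtype != bool:
            v = self._binarize(v)
        if v.ndim != 3:
            raise MaskFormatError(f"{self.patient_id}: mask must be 3D, got ndim={v.ndim}")
        if not v.any():
            raise MaskFormatError(f"{self.patient_id}: lesion mask is empty")
        self.voxels = v

    @staticmethod
    def _binarize(data: np.ndarray) -> np.ndarray:
        near0 = np.abs(data) <= BINARY_TOL
        near1 = np.abs(data - 1.0) <= BINARY_TOL
        if not np.all(near0 | near1):
            bad = data[~(near0 | near1)]
            raise MaskFormatError(
                f"mask contains non-binary values (e.g. {bad.flat[0]!r}); "
                "segmentations must be strictly 0/1"
            )
        return near1

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class Patient:
    patient_id: str
    mask: LesionMask
    pre_score: float
    post_score: Optional[float] = None
    pre_volume_ml: Optional[float] = None
    post_volume_ml: Optional[float] = None

    @property
    def change(self) -> Optional[float]:
        if self.post_score is None:
            return None
        return scoring.change_score(self.pre_score, self.post_score)


@dataclass
class Cohort:
    """Patients with grid-consistent lesion masks and cognitive scores.

    The preoperative analysis set is every patient (all have a pre score);
    the change analysis set is the subset with a postoperative score.
    """

    grid: TemplateGrid
    patients: list = field(default_factory=list)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CohortError(f"duplicate patient_id(s): {sorted(dupes)}")
        for p in self.patients:
            if p.mask.voxels.shape != self.grid.shape:
                raise GridMismatchError(
                    f"{p.patient_id}: mask shape {p.mask.voxels.shape} != grid {self.grid.shape}"
                )

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list:
        return [p.patient_id for p in self.patients]

    def pre_scores(self) -> np.ndarray:
        return np.array([p.pre_score for p in self.patients], dtype=float)

    def change_scores(self) -> np.ndarray:
        """Post-minus-pre change for the change analysis set (see :meth:`with_post`)."""
        return np.array([p.change for p in self.with_post().patients], dtype=float)

    def with_post(self) -> "Cohort":
        """The sub-cohort of patients with a postoperative score."""
        return Cohort(self.grid, [p for p in self.patients if p.post_score is not None])

    def mask_stack(self) -> np.ndarray:
        """Boolean array ``(n_patients, *grid.shape)`` of lesion membership."""
        return np.stack([p.mask.voxels for p in self.patients], axis=0)


def load_mask(path, reference: Optional[TemplateGrid] = None) -> LesionMask:
    """Load a binary lesion mask from a NIfTI file.

    If *reference* is given the image grid must match it exactly in shape and
    within :data:`AFFINE_TOL` in the affine; mismatches raise
    :class:`GridMismatchError` rather than resampling.
    """
    path = Path(path)
    img = nib.load(str(path))
    grid = TemplateGrid(shape=img.shape[:3], affine=img.affine)
    if reference is not None:
        reference.require_match(grid, context=str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        data = np.squeeze(data)
    mask = LesionMask(patient_id=path.stem.replace(".nii", ""), voxels=data)
    return mask


def _cell(row, name):
    if name not in row.index:
        return None
    v = row[name]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip() == "":
        return None
    return v


def _score_from_row(row, prefix: str):
    """0-100 score from a manifest row, from raw items and/or a precomputed column.

    Returns None when the subscale is missing (e.g. no postoperative
    follow-up).  Raw items and a precomputed score that disagree beyond the
    score tolerance raise :class:`ScoreInconsistencyError`.
    """
    mem = _cell(row, f"{prefix}_item_memory")
    con = _cell(row, f"{prefix}_item_concentration")
    pre_computed = _cell(row, f"{prefix}_score")

    implied = None
    if mem is not None or con is not None:
        if mem is None or con is None:
            raise MissingItemError(
                f"{prefix}: one of the two subscale items is missing; "
                "the two-item scale cannot be half-completed"
            )
        implied = score_cognitive_subscale(mem, con)

    if pre_computed is not None:
        value = validate_score(float(pre_computed), f"{prefix}_score")
        if implied is not None and not scoring.scores_consistent(value, implied):
            raise ScoreInconsistencyError(
                f"{prefix}_score={value} disagrees with items "
                f"({mem}, {con}) -> {implied}"
            )
        return value
    return implied


def load_cohort(manifest, mask_dir=None) -> Cohort:
    """Assemble a :class:`Cohort` from a manifest CSV and a mask directory.

    The manifest provides either raw item responses
    (``pre_item_memory``/``pre_item_concentration``, optional ``post_*``) or
    precomputed ``pre_score``/``post_score`` columns, an optional
    ``mask_path`` column (default ``<patient_id>.nii.gz`` under *mask_dir*),
    and optional ``pre_volume_ml``/``post_volume_ml``.

    Patients without a valid preoperative score are excluded with a logged
    reason, mirroring exclusion-based handling of missing baseline data.
    """
    manifest = Path(manifest)
    mask_dir = Path(mask_dir) if mask_dir is not None else manifest.parent
    table = pd.read_csv(manifest, dtype={"patient_id": str})
    if "patient_id" not in table.columns:
        raise CohortError("manifest must contain a 'patient_id' column")
    unknown = [c for c in table.columns if c not in _KNOWN_COLUMNS]
    if unknown:
        logger.warning("manifest has unknown columns (ignored): %s", unknown)
    if table["patient_id"].duplicated().any():
        dupes = table.loc[table["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortError(f"duplicate patient_id(s) in manifest: {dupes}")

    grid = None
    patients = []
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        try:
            pre = _score_from_row(row, "pre")
        except MissingItemError as exc:
            logger.info("excluding %s: %s", pid, exc)
            pre = None
        if pre is None:
            logger.info("excluding %s: missing preoperative cognitive score", pid)
            continue
        post = _score_from_row(row, "post")  # None = no follow-up; inconsistency raises

        rel = _cell(row, "mask_path") or f"{pid}.nii.gz"
        mask_path = mask_dir / rel
        if not mask_path.exists():
            raise CohortError(f"mask file for {pid} not found: {mask_path}")
        mask = load_mask(mask_path, reference=grid)
        mask.patient_id = pid
        if grid is None:
            img = nib.load(str(mask_path))
            grid = TemplateGrid(shape=img.shape[:3], affine=img.affine)

        pre_vol = _cell(row, "pre_volume_ml")
        post_vol = _cell(row, "post_volume_ml")
        patients.append(
            Patient(
                patient_id=pid,
                mask=mask,
                pre_score=pre,
                post_score=post,
                pre_volume_ml=float(pre_vol) if pre_vol is not None else None,
                post_volume_ml=float(post_vol) if post_vol is not None else None,
            )
        )
    if not patients:
        raise CohortError("no patient with a valid preoperative score in manifest")
    return Cohort(grid=grid, patients=patients)


def write_map(vmap, grid: TemplateGrid, path) -> None:
    """Write a voxel map as NIfTI on *grid*.

    Count maps are written as int32 with 0 background; float maps are written
    as float32 with NaN at invalid voxels, which NIfTI viewers render as
    background unambiguously.
    """
    values = np.asarray(vmap.values)
    valid = np.asarray(vmap.valid, dtype=bool)
    if vmap.kind == "count":
        data = np.where(valid, values, 0).astype(np.int32)
    else:
        data = np.where(valid, values, np.nan).astype(np.float32)
    img = nib.Nifti1Image(data, affine=grid.affine)
    nib.save(img, str(path))


def write_mask(mask: LesionMask, grid: TemplateGrid, path) -> None:
    """Write a binary lesion mask as uint8 NIfTI on *grid*."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine=grid.affine)
    nib.save(img, str(path))
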
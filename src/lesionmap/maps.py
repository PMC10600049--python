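"""Descriptive voxel-wise brain maps from binary lesion cohorts.

Three map families: the tumor *distribution* map (how many patients have a
lesion in each voxel), the *descriptive* mean-score map (mean preoperative
score over the patients lesioned at each voxel) and the mean *change* map
(same, for the post-minus-pre change in the sub-cohort with follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Cohort

__all__ = ["VoxelMap", "distribution_map", "descriptive_map", "MAP_KINDS"]

MAP_KINDS = ("count", "mean_score", "mean_change", "t", "z", "significance")


@dataclass
class VoxelMap:
    """A per-voxel scalar field with a validity mask.

    ``values`` is only meaningful where ``valid`` is True; invalid voxels
    serialize as NaN (float maps) or 0 (count maps).
    """

    values: np.ndarray
    valid: np.ndarray
    kind: str

    def __post_init__(self):
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}")
        self.values = np.asarray(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have identical shape")


def distribution_map(cohort: Cohort) -> VoxelMap:
    """Number of patients with a tumor in each voxel."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    counts = cohort.mask_stack().sum(axis=0).astype(np.int64)
    return VoxelMap(values=counts, valid=np.ones(counts.shape, dtype=bool), kind="count")


def descriptive_map(cohort: Cohort, which: str = "pre", min_patients: int = 1) -> VoxelMap:
    """Mean score over patients with a tumor in each voxel.

    Parameters
    ----------
    which:
        ``"pre"`` for the mean preoperative score over all patients, or
        ``"change"`` for the mean post-minus-pre change over the sub-cohort
        with postoperative follow-up.
    min_patients:
        Voxels with fewer contributing patients are marked invalid.  The
        default of 1 shows a mean wherever any tumor lies; voxel-wise
        statistical eligibility (the >=3-tumor rule) is a separate, stricter
        filter owned by the VLSM stage.
    """
    if which not in ("pre", "change"):
        raise ValueError(f"which must be 'pre' or 'change', got {which!r}")
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    if which == "change":
        cohort = cohort.with_post()
        if len(cohort) == 0:
            raise ValueError("change map requested but no patient has a postoperative score")
        scores = cohort.change_scores()
        kind = "mean_change"
    else:
        if len(cohort) == 0:
            raise ValueError("cohort is empty")
        scores = cohort.pre_scores()
        kind = "mean_score"

    stack = cohort.mask_stack()
    counts = stack.sum(axis=0)
    totals = np.tensordot(scores, stack.astype(float), axes=(0, 0))
    valid = counts >= min_patients
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(valid, totals / np.maximum(counts, 1), np.nan)
    return VoxelMap(values=means, valid=valid, kind=kind)
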
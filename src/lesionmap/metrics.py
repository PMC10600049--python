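"""Per-patient segmentation-derived tumor metrics.

Volume from the binary segmentation, extent of resection (relative
postoperative reduction of the preoperative tumor volume, dichotomized as
gross total resection at exactly 100% vs subtotal below), and
lateralization by the lesion's center of mass in world coordinates, with
multifocal bilateral tumors as a separate category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Cohort, LesionMask, TemplateGrid

__all__ = [
    "ResectionMetrics",
    "volume_ml",
    "extent_of_resection",
    "lateralization",
    "metrics_table",
    "GTR_TOL",
]

#: "100%" is literal: GTR requires eor_percent >= 100 - GTR_TOL, i.e. residual 0.
GTR_TOL = 1e-9

# 26-connectivity: the most inclusive standard choice for multifocality.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ResectionMetrics:
    pre_volume_ml: float
    post_volume_ml: float
    eor_percent: float
    gtr: bool


def volume_ml(mask: LesionMask, grid: TemplateGrid) -> float:
    """Lesion volume in ml: nonzero-voxel count x voxel volume (mm^3) / 1000."""
    return mask.n_voxels * grid.voxel_volume_mm3 / 1000.0


def extent_of_resection(pre_volume_ml: float, post_volume_ml: float) -> ResectionMetrics:
    """Relative postoperative reduction of the preoperative tumor volume.

    ``eor_percent = (pre - post) / pre * 100``; gross total resection (GTR)
    iff the residual volume is exactly zero (100%), subtotal otherwise.
    A residual larger than the preoperative volume flags a segmentation
    inconsistency and is an error.
    """
    if pre_volume_ml <= 0:
        raise ValueError(f"preoperative volume must be positive, got {pre_volume_ml}")
    if post_volume_ml < 0:
        raise ValueError(f"postoperative volume must be >= 0, got {post_volume_ml}")
    if post_volume_ml > pre_volume_ml:
        raise ValueError(
            f"postoperative volume {post_volume_ml} exceeds preoperative {pre_volume_ml}; "
            "check segmentations"
        )
    eor = (pre_volume_ml - post_volume_ml) / pre_volume_ml * 100.0
    return ResectionMetrics(
        pre_volume_ml=float(pre_volume_ml),
        post_volume_ml=float(post_volume_ml),
        eor_percent=eor,
        gtr=eor >= 100.0 - GTR_TOL,
    )


def _side_of_x(x: float, mask_world_x: np.ndarray, half_voxel: float) -> str:
    """left/right by the sign of world x, with a deterministic midline tie-break.

    Within half a voxel of the midline, the side holding more lesion voxels
    wins; an exact tie goes to the left.
    """
    if abs(x) >= half_voxel:
        return "left" if x < 0 else "right"
    n_left = int((mask_world_x < 0).sum())
    n_right = int((mask_world_x > 0).sum())
    if n_left >= n_right:
        return "left"
    return "right"


def lateralization(mask: LesionMask, grid: TemplateGrid) -> str:
    """``"left"``, ``"right"`` or ``"bilateral"`` for a lesion mask.

    Multifocal lesions (>= 2 connected components, 26-connectivity) with
    component centers of mass on both sides of the midline are bilateral.
    Everything else — including a unifocal lesion straddling the midline —
    takes the side of the whole-lesion center of mass in world coordinates
    (RAS: left = x < 0).
    """
    voxels = mask.voxels
    world = grid.world_coordinates()
    world_x = world[..., 0]
    half_voxel = grid.voxel_size[0] / 2.0
    mask_x = world_x[voxels]

    labels, n_comp = ndimage.label(voxels, structure=_STRUCT_26)
    if n_comp >= 2:
        sides = set()
        for comp in range(1, n_comp + 1):
            comp_idx = np.argwhere(labels == comp)
            com_x = float(grid.voxel_to_world(comp_idx.mean(axis=0))[0])
            sides.add(_side_of_x(com_x, world_x[labels == comp], half_voxel))
        if sides == {"left", "right"}:
            return "bilateral"

    com_x = float(grid.voxel_to_world(np.argwhere(voxels).mean(axis=0))[0])
    return _side_of_x(com_x, mask_x, half_voxel)


def metrics_table(cohort: Cohort) -> pd.DataFrame:
    """Per-patient metrics CSV-ready table.

    Extent of resection uses the manifest's pre/post volumes when both are
    present; otherwise the pre volume is measured from the mask and the EOR
    columns are left empty.
    """
    rows = []
    for p in cohort.patients:
        pre_vol = p.pre_volume_ml if p.pre_volume_ml is not None else volume_ml(p.mask, cohort.grid)
        eor: Optional[float] = None
        gtr: Optional[bool] = None
        if p.post_volume_ml is not None:
            rm = extent_of_resection(pre_vol, p.post_volume_ml)
            eor, gtr = rm.eor_percent, rm.gtr
        rows.append(
            {
                "patient_id": p.patient_id,
                "pre_volume_ml": pre_vol,
                "post_volume_ml": p.post_volume_ml,
                "eor_percent": eor,
                "gtr": gtr,
                "lateralization": lateralization(p.mask, cohort.grid),
            }
        )
    return pd.DataFrame(rows)
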
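import numpy as np
import pytest

from lesionmap import Cohort, LesionMask, Patient, TemplateGrid


@pytest.fixture
def small_grid():
    """A 6x6x6 grid with 2 mm isotropic voxels, world origin at its center."""
    return TemplateGrid.centered((6, 6, 6), 2.0)


def make_mask(grid, voxels, patient_id="p"):
    m = np.zeros(grid.shape, dtype=bool)
    for v in voxels:
        m[tuple(v)] = True
    return LesionMask(patient_id=patient_id, voxels=m)


def make_cohort(grid, spec):
    """Cohort from [(voxel_list, pre_score, post_score_or_None), ...]."""
    patients = []
    for i, (voxels, pre, post) in enumerate(spec):
        pid = f"p{i}"
        patients.append(
            Patient(patient_id=pid, mask=make_mask(grid, voxels, pid), pre_score=pre, post_score=post)
        )
    return Cohort(grid=grid, patients=patients)
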
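"""Voxel-based lesion-symptom mapping with permutation FWER correction.

For each voxel covered by at least ``min_lesion_patients`` tumors (and with
at least ``min_nonlesion_patients`` patients spared), patients are split
into lesioned/non-lesioned groups and their scores compared with a Student
pooled-variance t-test (df = n1 + n2 - 2); t statistics are mapped to the
standard-normal scale through their tail probability.  Family-wise error is
controlled by the min-statistic (max-statistic for positive/two-sided
tails) permutation method: scores are randomly reassigned to patients as
whole vectors, the extreme Z across all eligible voxels is recorded per
permutation, and the corrected threshold is the alpha-quantile of those
extremes.  Permuting the complete score vector jointly preserves the
spatial dependence of the lesion maps, which is what makes the single
threshold family-wise valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import ndtri, stdtr

from .io import Cohort
from .maps import VoxelMap

__all__ = [
    "VlsmParams",
    "VlsmResult",
    "pooled_t",
    "t_to_z",
    "eligible_voxels",
    "permutation_threshold",
    "run_vlsm",
    "Z_CAP",
]

#: |Z| values are capped here; also the sentinel for zero-pooled-variance
#: voxels with unequal means (scores live on a 7-point lattice, so such
#: degenerate voxels genuinely occur).
Z_CAP = 10.0

_MEAN_TOL = 1e-8
_TAILS = ("negative", "positive", "two_sided")


@dataclass(frozen=True)
class VlsmParams:
    """Tuning parameters of the VLSM inference.

    alpha:
        Significance level for the corrected threshold (default 0.05).
    n_permutations:
        Number of score permutations for the FWER correction (default 2000).
    min_lesion_patients:
        A voxel is only tested when at least this many patients have a tumor
        there (default 3).
    min_nonlesion_patients:
        Minimum size of the complement group (default 3); prevents
        degenerate degrees of freedom in tiny cohorts and is vacuous at
        realistic cohort sizes.
    tail:
        ``negative`` (lesion associated with worse scores, min-statistic),
        ``positive``, or ``two_sided`` (max |Z|).
    seed:
        Seed of the single generator driving all permutations.
    """

    alpha: float = 0.05
    n_permutations: int = 2000
    min_lesion_patients: int = 3
    min_nonlesion_patients: int = 3
    tail: str = "negative"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_lesion_patients < 2:
            raise ValueError("min_lesion_patients must be >= 2")
        if self.min_nonlesion_patients < 2:
            raise ValueError("min_nonlesion_patients must be >= 2")
        if self.tail not in _TAILS:
            raise ValueError(f"tail must be one of {_TAILS}, got {self.tail!r}")


@dataclass
class VlsmResult:
    """Observed maps, eligibility, corrected threshold and significance."""

    t_map: VoxelMap
    z_map: VoxelMap
    eligible: np.ndarray
    z_threshold: float
    significant: np.ndarray
    params: VlsmParams
    n_eligible_voxels: int
    n_patients: int
    which: str
    null_extremes: np.ndarray = field(repr=False, default=None)

    @property
    def n_significant_voxels(self) -> int:
        return int(self.significant.sum())

    def summary(self) -> dict:
        return {
            "which": self.which,
            "n_patients": self.n_patients,
            "n_eligible_voxels": self.n_eligible_voxels,
            "z_threshold": float(self.z_threshold),
            "n_significant_voxels": self.n_significant_voxels,
            "alpha": self.params.alpha,
            "n_permutations": self.params.n_permutations,
            "min_lesion_patients": self.params.min_lesion_patients,
            "min_nonlesion_patients": self.params.min_nonlesion_patients,
            "tail": self.params.tail,
            "seed": self.params.seed,
        }


def pooled_t(scores_in, scores_out) -> float:
    """Two-sample Student pooled-variance t statistic.

    Sign convention: t < 0 when the lesion group's mean is lower.  Zero
    pooled variance gives t = 0 for equal means and a +-inf sentinel for
    unequal means (capped at the Z stage).
    """
    a = np.asarray(scores_in, dtype=float)
    b = np.asarray(scores_out, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 scores for a pooled-variance t-test")
    n1, n2 = a.size, b.size
    m1, m2 = a.mean(), b.mean()
    ss = ((a - m1) ** 2).sum() + ((b - m2) ** 2).sum()
    sp2 = ss / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    if se == 0.0:
        if abs(diff) <= _MEAN_TOL:
            return 0.0
        return float(np.sign(diff) * np.inf)
    return float(diff / se)


def t_to_z(t, df: int):
    """Map t statistics to standard-normal Z through the tail probability.

    ``z = Phi^-1(T_df(t))``, evaluated on the smaller tail for numerical
    symmetry, monotone in t, with |z| capped at :data:`Z_CAP` (infinite t
    sentinels map to +-Z_CAP).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t_arr = np.asarray(t, dtype=float)
    sign = np.sign(t_arr)
    with np.errstate(invalid="ignore"):
        p_small = stdtr(df, -np.abs(np.where(np.isfinite(t_arr), t_arr, 0.0)))
    # ndtri(p) for tiny p underflows to -inf beyond ~1e-300; the cap handles it
    with np.errstate(divide="ignore"):
        z_mag = -ndtri(p_small)
    z = sign * np.minimum(z_mag, Z_CAP)
    z = np.where(np.isfinite(t_arr), z, sign * Z_CAP)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(z)
    return z


def eligible_voxels(cohort: Cohort, params: VlsmParams = VlsmParams()) -> np.ndarray:
    """Boolean field of voxels entering the analysis.

    A voxel is eligible iff >= ``min_lesion_patients`` patients have a tumor
    there AND >= ``min_nonlesion_patients`` do not.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    counts = cohort.mask_stack().sum(axis=0)
    n = len(cohort)
    return (counts >= params.min_lesion_patients) & (
        (n - counts) >= params.min_nonlesion_patients
    )


def _t_matrix(lesion: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pooled-variance t at every (voxel, score-column) pair.

    ``lesion`` is (n_patients, n_voxels) float 0/1; ``scores`` is
    (n_patients, n_columns) — one column per permutation (or the single
    observed column).  Returns (n_voxels, n_columns).
    """
    n = lesion.shape[0]
    n1 = lesion.sum(axis=0)  # (V,)
    n2 = n - n1
    s = scores
    s2 = s * s
    sum1 = lesion.T @ s  # (V, P)
    sq1 = lesion.T @ s2
    tot = s.sum(axis=0)  # (P,)
    sqtot = s2.sum(axis=0)
    n1c = n1[:, None]
    n2c = n2[:, None]
    m1 = sum1 / n1c
    m2 = (tot[None, :] - sum1) / n2c
    ss1 = sq1 - sum1 * sum1 / n1c
    ss2 = (sqtot[None, :] - sq1) - (tot[None, :] - sum1) ** 2 / n2c
    ss = np.clip(ss1, 0.0, None) + np.clip(ss2, 0.0, None)
    sp2 = ss / (n - 2)
    se = np.sqrt(sp2 * (1.0 / n1c + 1.0 / n2c))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = se == 0.0
    if degenerate.any():
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate & (np.abs(diff) <= _MEAN_TOL), 0.0, t)
            t = np.where(degenerate & (np.abs(diff) > _MEAN_TOL), np.sign(diff) * np.inf, t)
    return t


def _extreme(z: np.ndarray, tail: str) -> np.ndarray:
    """Per-column extreme statistic across voxels."""
    if tail == "negative":
        return z.min(axis=0)
    if tail == "positive":
        return z.max(axis=0)
    return np.abs(z).max(axis=0)


def _null_extremes(
    lesion: np.ndarray,
    scores: np.ndarray,
    params: VlsmParams,
    chunk: int = 128,
) -> np.ndarray:
    """Extreme null Z per permutation, shape (n_permutations,).

    A single seeded generator drives all permutations; permutation r uses
    the r-th draw, so results are reproducible and independent of voxel
    evaluation order.  Permutations are evaluated in chunks to bound memory.
    """
    n = lesion.shape[0]
    df = n - 2
    rng = np.random.default_rng(params.seed)
    perms = np.stack([rng.permutation(n) for _ in range(params.n_permutations)], axis=0)
    extremes = np.empty(params.n_permutations, dtype=float)
    for start in range(0, params.n_permutations, chunk):
        block = perms[start : start + chunk]
        s = scores[block].T  # (n, chunk)
        t = _t_matrix(lesion, s)
        z = t_to_z(t, df)
        extremes[start : start + block.shape[0]] = _extreme(z, params.tail)
    return extremes


def _threshold_from_extremes(extremes: np.ndarray, params: VlsmParams) -> float:
    """The corrected threshold: the ceil(alpha*P)-th most extreme null value.

    Sorted toward the tested tail (ascending minima for the negative tail,
    descending maxima otherwise); the observed labeling is not added to the
    null set, which keeps the rule conservative within one rank.
    """
    k = int(np.ceil(params.alpha * extremes.size))
    k = max(1, min(k, extremes.size))
    ordered = np.sort(extremes)
    if params.tail == "negative":
        return float(ordered[k - 1])
    return float(ordered[extremes.size - k])


def _significant(z: np.ndarray, eligible: np.ndarray, thr: float, tail: str) -> np.ndarray:
    """Closed comparison against the threshold, restricted to the tested tail.

    The tail restriction (z strictly below/above 0) means a voxel with no
    effect at all (z = 0) can never be flagged, even in the degenerate case
    where every permutation yields an extreme of exactly 0.
    """
    if tail == "negative":
        hit = (z <= thr) & (z < 0)
    elif tail == "positive":
        hit = (z >= thr) & (z > 0)
    else:
        hit = (np.abs(z) >= thr) & (np.abs(z) > 0)
    return eligible & hit


def permutation_threshold(cohort: Cohort, scores, params: VlsmParams = VlsmParams()) -> float:
    """Permutation-corrected Z threshold for a cohort and score vector.

    For each of ``n_permutations`` permutations the scores are randomly
    reassigned to patients (masks fixed), the full eligible-voxel Z map is
    recomputed, and the extreme statistic recorded; the threshold is the
    alpha-quantile of those extremes.  Deterministic given ``params.seed``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(cohort):
        raise ValueError("scores must have one entry per patient")
    eligible = eligible_voxels(cohort, params)
    if not eligible.any():
        raise ValueError(
            "no voxel is eligible; relax min_lesion_patients/min_nonlesion_patients "
            "or provide a larger cohort"
        )
    lesion = cohort.mask_stack().reshape(len(cohort), -1)[:, eligible.ravel()].astype(float)
    extremes = _null_extremes(lesion, scores, params)
    return _threshold_from_extremes(extremes, params)


def run_vlsm(cohort: Cohort, which: str = "pre", params: VlsmParams = VlsmParams()) -> VlsmResult:
    """Full VLSM analysis of a cohort.

    ``which='pre'`` analyses preoperative scores over the whole cohort;
    ``which='change'`` analyses post-minus-pre change over the sub-cohort
    with postoperative scores.  Observed t and Z maps are deterministic;
    only the permutation threshold depends on ``params.seed``.
    """
    if which == "change":
        cohort = cohort.with_post()
        if len(cohort) == 0:
            raise ValueError("change analysis requested but no patient has a postoperative score")
        scores = cohort.change_scores()
    elif which == "pre":
        scores = cohort.pre_scores()
    else:
        raise ValueError(f"which must be 'pre' or 'change', got {which!r}")

    n = len(cohort)
    eligible = eligible_voxels(cohort, params)
    if not eligible.any():
        raise ValueError(
            "no voxel is eligible; relax min_lesion_patients/min_nonlesion_patients "
            "or provide a larger cohort"
        )
    flat_idx = eligible.ravel()
    lesion = cohort.mask_stack().reshape(n, -1)[:, flat_idx].astype(float)
    df = n - 2

    t_obs = _t_matrix(lesion, scores[:, None])[:, 0]
    z_obs = t_to_z(t_obs, df)

    t_field = np.full(eligible.shape, np.nan)
    z_field = np.full(eligible.shape, np.nan)
    t_field.ravel()[flat_idx] = np.where(np.isfinite(t_obs), t_obs, np.sign(t_obs) * Z_CAP)
    z_field.ravel()[flat_idx] = z_obs

    extremes = _null_extremes(lesion, scores, params)
    thr = _threshold_from_extremes(extremes, params)

    z_for_sig = np.where(eligible, np.nan_to_num(z_field, nan=0.0), 0.0)
    significant = _significant(z_for_sig, eligible, thr, params.tail)

    return VlsmResult(
        t_map=VoxelMap(values=t_field, valid=eligible, kind="t"),
        z_map=VoxelMap(values=z_field, valid=eligible, kind="z"),
        eligible=eligible,
        z_threshold=thr,
        significant=significant,
        params=params,
        n_eligible_voxels=int(eligible.sum()),
        n_patients=n,
        which=which,
        null_extremes=extremes,
    )
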
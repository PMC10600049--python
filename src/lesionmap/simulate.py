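"""Synthetic lesion cohorts with known ground truth.

Real glioma cohorts with patient-reported outcomes are rarely shareable, so
every pipeline stage here is exercised on generated cohorts that have the
statistical structure the analysis assumes: binary spherical lesions on one
shared template grid, an "eloquent" effect region E whose involvement
lowers the latent cognitive score by ``effect_beta`` points, Gaussian
noise, and quantization of the latent score onto the 7-value lattice
attainable from the two 4-point questionnaire items.

Lesions are spheres (a voxel belongs to a lesion iff its center lies within
the sphere) with centers uniform inside an ellipsoidal brain mask, subject
to a hemispheric bias, and radii uniform in ``lesion_radius_range``.  Shape
realism is deliberately not attempted: the analysis consumes only binary
per-voxel membership, so spheres are sufficient for correctness testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import scoring
from .io import Cohort, LesionMask, Patient, TemplateGrid, write_mask

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_cohort", "quantize_score", "write_cohort"]

_ATTAINABLE = np.array(sorted(scoring.attainable_scores()))  # k * 100/6, k = 0..6


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated cohort.

    Defaults emulate a population-based glioblastoma resection cohort on a
    coarse (4 mm) template: 162 patients, balanced hemispheres, tumor radii
    4-20 mm (the clinical tumor-volume range scaled to the miniature brain
    volume of the template), an eloquent sphere E of radius 12 mm in the
    left deep hemisphere whose involvement costs 40 points of cognitive
    function, and 10 points of latent score noise around a mildly
    symptomatic baseline of 500/6 ~ 83.3.
    """

    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 4.0
    n_patients: int = 162
    lesion_radius_range: Tuple[float, float] = (4.0, 20.0)
    effect_center: Tuple[float, float, float] = (-16.0, 0.0, 8.0)  # world mm
    effect_radius: float = 12.0
    effect_beta: float = 40.0
    noise_sd: float = 10.0
    overlap_mode: str = "binary"
    baseline_mean: float = 500.0 / 6.0
    hemispheric_bias: float = 0.5
    brain_axes_fraction: float = 0.45
    make_post: bool = False
    change_gamma: float = -20.0
    change_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.effect_beta < 0:
            raise ValueError("effect_beta must be >= 0")
        if self.noise_sd < 0 or self.change_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")
        extent = min(s * self.voxel_size_mm for s in self.grid_shape)
        if hi >= extent:
            raise ValueError("maximum lesion radius must be below the grid extent")
        if self.overlap_mode not in ("binary", "fractional"):
            raise ValueError("overlap_mode must be 'binary' or 'fractional'")
        if not (0.0 <= self.hemispheric_bias <= 1.0):
            raise ValueError("hemispheric_bias must be in [0, 1]")

    def grid(self) -> TemplateGrid:
        return TemplateGrid.centered(self.grid_shape, self.voxel_size_mm)

    def brain_semi_axes(self) -> np.ndarray:
        """Semi-axes (mm) of the ellipsoidal brain mask."""
        extent = np.array(self.grid_shape) * self.voxel_size_mm
        return self.brain_axes_fraction * extent


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    effect_mask: np.ndarray
    overlap: np.ndarray  # per-patient indicator (binary) or fraction of E covered
    latent_pre: np.ndarray
    latent_post: Optional[np.ndarray] = None
    config: SyntheticConfig = None


def quantize_score(latent: float) -> float:
    """Nearest attainable two-item score after clamping to [0, 100].

    Ties round toward the worse (lower) score.
    """
    if not np.isfinite(latent):
        raise ValueError(f"latent score must be finite, got {latent}")
    v = min(max(float(latent), 0.0), 100.0)
    k = int(np.ceil(v * 6.0 / 100.0 - 0.5))  # half-way cases round down
    return float(_ATTAINABLE[k])


def _sphere_mask(grid_world: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    d2 = ((grid_world - center) ** 2).sum(axis=-1)
    return d2 <= radius * radius


def _sample_center(rng: np.random.Generator, semi_axes: np.ndarray, bias: float) -> np.ndarray:
    """Uniform point in the brain ellipsoid, with P(left half) = bias."""
    # uniform in the unit ball, then scale by the semi-axes
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u**2).sum() <= 1.0:
            break
    p = u * semi_axes
    left = rng.uniform() < bias
    p[0] = -abs(p[0]) if left else abs(p[0])
    return p


def generate_cohort(config: SyntheticConfig) -> Tuple[Cohort, SyntheticTruth]:
    """Generate a cohort and its ground truth, fully reproducible from the seed.

    Latent preoperative score: ``baseline_mean - effect_beta * g + N(0, noise_sd)``
    where g is the overlap indicator (binary mode) or the fraction of E
    covered (fractional mode); the observed score is the latent score
    quantized onto the attainable lattice.  With ``make_post`` the change
    model adds ``change_gamma * g + N(0, change_noise_sd)`` to the latent
    preoperative score before quantization.
    """
    grid = config.grid()
    world = grid.world_coordinates()
    semi_axes = config.brain_semi_axes()
    center_e = np.asarray(config.effect_center, dtype=float)
    if ((center_e / semi_axes) ** 2).sum() > 1.0:
        raise ValueError(
            f"effect region center {tuple(center_e)} lies outside the brain ellipsoid "
            f"(semi-axes {tuple(semi_axes)})"
        )
    effect_mask = _sphere_mask(world, center_e, config.effect_radius)
    if config.effect_beta > 0 and not effect_mask.any():
        raise ValueError("effect region contains no voxel; increase effect_radius")
    n_effect = max(int(effect_mask.sum()), 1)

    rng = np.random.default_rng(config.seed)
    patients = []
    overlap = np.empty(config.n_patients)
    latent_pre = np.empty(config.n_patients)
    latent_post = np.empty(config.n_patients) if config.make_post else None

    for i in range(config.n_patients):
        center = _sample_center(rng, semi_axes, config.hemispheric_bias)
        radius = rng.uniform(*config.lesion_radius_range)
        voxels = _sphere_mask(world, center, radius)
        if not voxels.any():
            # tiny sphere between voxel centers: claim the nearest voxel
            nearest = np.unravel_index(
                np.argmin(((world - center) ** 2).sum(axis=-1)), grid.shape
            )
            voxels = np.zeros(grid.shape, dtype=bool)
            voxels[nearest] = True
        inter = int((voxels & effect_mask).sum())
        g = float(inter > 0) if config.overlap_mode == "binary" else inter / n_effect
        overlap[i] = g

        lat = config.baseline_mean - config.effect_beta * g + rng.normal(0.0, config.noise_sd)
        latent_pre[i] = lat
        post_score = None
        if config.make_post:
            lat_post = lat + config.change_gamma * g + rng.normal(0.0, config.change_noise_sd)
            latent_post[i] = lat_post
            post_score = quantize_score(lat_post)

        patients.append(
            Patient(
                patient_id=f"syn{i:04d}",
                mask=LesionMask(patient_id=f"syn{i:04d}", voxels=voxels),
                pre_score=quantize_score(lat),
                post_score=post_score,
            )
        )

    cohort = Cohort(grid=grid, patients=patients)
    truth = SyntheticTruth(
        effect_mask=effect_mask,
        overlap=overlap,
        latent_pre=latent_pre,
        latent_post=latent_post,
        config=config,
    )
    return cohort, truth


def write_cohort(cohort: Cohort, truth: SyntheticTruth, out_dir) -> Path:
    """Write masks, manifest CSV and a ground-truth sidecar JSON to *out_dir*.

    The layout is exactly the manifest dialect :func:`lesionmap.io.load_cohort`
    reads back.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        name = f"{p.patient_id}.nii.gz"
        write_mask(p.mask, cohort.grid, out_dir / name)
        rows.append(
            {
                "patient_id": p.patient_id,
                "pre_score": p.pre_score,
                "post_score": p.post_score,
                "mask_path": name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)

    cfg = asdict(truth.config) if truth.config is not None else {}
    sidecar = {
        "config": cfg,
        "effect_center": list(cfg.get("effect_center", [])),
        "effect_radius": cfg.get("effect_radius"),
        "n_effect_voxels": int(truth.effect_mask.sum()),
        "overlap": truth.overlap.tolist(),
    }
    (out_dir / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return manifest
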
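# Methods

## Cognitive score

The EORTC QLQ-C30 cognitive-function subscale has two items ("difficulty
remembering things", "difficulty concentrating"), each answered 1 ("not at
all") to 4 ("very much"). The raw score is the item mean RS and the
functional-scale linear transform gives

    score = (1 − (RS − 1)/3) × 100 ∈ [0, 100],  higher = better.

Only 7 values are attainable (k·100/6, k = 0…6), so scores live on a
16.67-point lattice. The two-item scale cannot be half-completed: a missing
item makes the subscale missing, and patients without a preoperative score
are excluded at cohort assembly (patients without a postoperative score are
kept for preoperative analyses and dropped from change analyses). Score
equality is tested at 1e-6, comfortably below the lattice spacing. When a
manifest supplies both raw items and a pre-computed score, disagreement
beyond that tolerance is an error rather than a silent preference.

## Cohort and grid conventions

All masks must share one template grid: identical shape, affines equal
within 1e-4 elementwise (resampling artifacts in otherwise co-registered
files). A mismatch is an error — the package never resamples implicitly,
because resampling corrupts voxel-wise counts. Mask voxels must be within
1e-6 of 0 or 1; anything else is rejected rather than thresholded, since
segmentations are deliverables, not probability maps. Voxel indices are
0-based; world coordinates come from the affine; under RAS orientation the
left hemisphere is world x < 0. Empty masks are invalid.

## Tumor metrics

- **Volume**: nonzero-voxel count × voxel volume / 1000 (ml).
- **Extent of resection**: (pre − post)/pre × 100; *gross total resection*
  iff the residual is exactly zero (tolerance 1e-9 on the percentage) —
  "100 %" is literal, any measurable residual is subtotal. A postoperative
  volume above the preoperative one flags a segmentation inconsistency and
  is an error.
- **Lateralization**: by the side of the whole-lesion center of mass in
  world coordinates. Multifocal lesions (≥ 2 connected components under
  26-connectivity, the most inclusive standard choice) with component
  centers of mass on both sides are *bilateral*; a unifocal lesion
  straddling the midline is not — it takes its center-of-mass side.
  Midline tie-break: a center of mass within half a voxel of x = 0 is
  assigned to the side holding more lesion voxels, an exact tie to the
  left. These conventions (connectivity, tie-breaks) are package choices,
  stated here because the field has no single standard.

## Maps

The distribution map counts patients lesioned per voxel. Descriptive maps
average the selected score (preoperative, or post-minus-pre change over
the follow-up subset) over patients lesioned per voxel, valid wherever at
least `min_patients` (default 1) contribute; the ≥3-lesion rule is a
property of the statistical map only, not of the descriptive maps. Invalid
voxels serialize as NaN in float NIfTI maps and 0 in count maps.

## VLSM inference

At each eligible voxel (≥ `min_lesion_patients` = 3 lesioned AND
≥ `min_nonlesion_patients` = 3 spared; the second bound prevents degenerate
degrees of freedom in tiny cohorts and is vacuous at realistic n), patients
are split by lesion membership and compared with the classic
pooled-variance t (df = n − 2), negative when the lesioned group scores
worse. t maps to Z through its tail probability, Z = Φ⁻¹(T_df(t)),
evaluated on the smaller tail for numerical symmetry and capped at
|Z| = 10. Because scores live on a 7-point lattice, voxels with zero pooled
variance genuinely occur: equal group means give t = 0, unequal means give
a ±∞ sentinel that the Z cap absorbs (also inside permutations).

**Multiple comparisons.** Family-wise error is controlled by the
min-statistic permutation method: for each of `n_permutations` (default
2000) permutations the complete per-patient score vector is reassigned
jointly — never per-voxel independently, since preserving the spatial
dependence of the lesion maps is exactly what makes a single threshold
family-wise valid — the full eligible-voxel Z map is recomputed and its
minimum recorded (maximum, or maximum |Z|, for the positive and two-sided
tails). The corrected threshold is the ⌈αP⌉-th smallest of the P minima
(for P = 2000, α = 0.05: the 100th); the observed labeling is not added to
the null set, leaving the rule conservative within one rank
(≈ ⌈αP⌉/(P+1) ≤ α). A single seeded generator drives all permutations, and
permutation r uses the r-th draw, so results are reproducible and
independent of voxel evaluation order or permutation chunking.

**Significance rule.** A voxel is significant when Z ≤ threshold (closed,
mirroring "p ≤ 0.05") *and* Z lies strictly on the tested tail (Z < 0 for
the negative tail). The tail restriction matters only in degenerate cases:
when every score is identical, every permuted extreme is exactly 0, the
threshold is 0, and a no-effect voxel (Z = 0) must not be flagged. In the
generic continuous case the threshold is strictly negative and the
restriction is inert.

Observed t and Z maps are deterministic functions of the cohort; only the
threshold is stochastic through the permutation seed. The default tail is
negative (lesion associated with worse scores), matching how
lesion-deficit maps are usually reported; positive and two-sided variants
are available.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with known
ground truth: binary spherical lesions (a voxel belongs to a lesion iff its
center lies inside the sphere) with centers uniform in an ellipsoidal
"brain" (semi-axes 0.45 × grid extent) and a hemispheric bias parameter
(default 0.5, i.e. balanced left/right as in typical glioblastoma series),
and a planted eloquent sphere E whose involvement lowers the latent score:

    latent = baseline − β·g(lesion, E) + N(0, σ),    observed = quantize(latent),

where g is the overlap indicator (default) or the covered fraction of E,
and `quantize` clamps to [0, 100] and snaps to the nearest attainable
lattice value, ties rounding toward the worse score. The optional change
model adds γ·g + N(0, σΔ) to the latent preoperative score before
quantization (γ < 0: worsening when the eloquent region is involved).

Defaults, chosen once as a realistic miniature of a population-based
glioblastoma cohort: 162 patients; 32³ grid at 4 mm; lesion radii uniform
in 4–20 mm — clinical glioblastoma volumes (≈1–160 ml, median ≈27 ml)
scaled down by the volume ratio between a real brain (~1400 ml) and the
template's ellipsoid, giving a median radius of ≈12 mm; E of radius 12 mm
at world (−16, 0, 8) mm (left deep hemisphere); β = 40 points; σ = 10
points; baseline 500/6 ≈ 83.3 (a mildly symptomatic cohort); γ = −20,
σΔ = 10. Cohorts are bit-reproducible from the seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: tumor shape and infiltration (spheres suffice
because the analysis consumes only binary per-voxel membership),
registration error, mass effect and edema, spatially heterogeneous lesion
prevalence beyond the hemispheric bias, and covariates (age, treatment,
steroids) correlated with both location and score.

## Verification problem sizes

The test suite validates the statistics at sizes a laptop handles in
seconds to a minute per experiment: family-wise error under the global
null over 200 replicate cohorts (n = 60, 24³ grid, 500 permutations),
planted-effect recovery over 20 replicate cohorts (n = 120, β = 40,
σ = 10, 1000 permutations; detection in ≥ 90 % of replicates with ≥ 80 %
of significant voxels inside a 2-voxel dilation of E), and exact oracle
equivalence of the vectorized t against an independent scalar
implementation (1e-10) and of t→Z against direct quadrature of the t
density (1e-8).

## Known limitations

- No covariate adjustment, nonparametric alternatives, cluster-extent or
  FDR inference, or lesion-volume regression-out.
- Registration/normalization is out of scope; masks are trusted as given.
- Significant voxels in VLSM indicate association at lesioned voxels, not
  causation; spatial leakage onto voxels co-lesioned with a true effect
  region is inherent to the mass-univariate design (the recovery test's
  dilation margin quantifies it rather than hiding it).
- Statistical power is spatially heterogeneous: voxels with few tumors are
  either ineligible or weakly powered, so absence of significance is not
  evidence of absence.
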
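# lesionmap

Voxel-based lesion-symptom mapping (VLSM) of patient-reported cognitive
function for brain-tumor cohorts.

**The problem.** Which brain locations matter for how glioma patients
themselves experience their cognition? Given per-patient binary tumor
segmentations co-registered to one template grid (e.g. MNI / ICBM-152) and
the EORTC QLQ-C30 cognitive-function subscale (two 4-point items on memory
and concentration, linearly transformed to a 0–100 score with higher =
better), `lesionmap` builds the three standard map families and runs the
mass-univariate inference:

- **distribution map** — number of patients with a tumor in each voxel;
- **descriptive maps** — mean preoperative score, and mean post-minus-pre
  change, over the patients lesioned at each voxel;
- **VLSM statistical map** — for each voxel with at least 3 tumors (and at
  least 3 patients spared), a Student pooled-variance t-test comparing
  scores between lesioned and non-lesioned patients,

      t_v = (x̄_in − x̄_out) / √(s_p² (1/n_in + 1/n_out)),   df = n_in + n_out − 2,

  mapped to the normal scale as Z_v = Φ⁻¹(T_df(t_v)), with family-wise
  error controlled by the min-statistic permutation method: scores are
  randomly reassigned to patients as whole vectors, the minimum Z across
  all eligible voxels is recorded per permutation, and the corrected
  threshold is the α-quantile of those minima (default α = 0.05, 2000
  permutations, negative tail: lesion ⇒ worse function).

Patient-level tumor metrics (volume in ml, extent of resection with the
gross-total-resection dichotomy at exactly 100 %, and left/right/bilateral
lateralization by center of mass) are included, as is a synthetic cohort
generator with known ground truth — spherical lesions in an ellipsoidal
brain, a planted "eloquent" region whose involvement lowers the latent
score, and quantization onto the 7 values attainable from two 4-point
items — so the whole pipeline is testable without patient data.

## Worked example

Simulate a cohort of 80 patients on a 24³ grid (4 mm voxels) with the
default planted effect (a 12 mm sphere in the left deep hemisphere costing
40 points of cognitive function), then score, map, and run VLSM:

```sh
lesionmap simulate --config sim.yaml --out-dir demo        # sim.yaml: grid_shape: [24,24,24], n_patients: 80, make_post: true, seed: 7
lesionmap score    --manifest demo/manifest.csv --out-dir demo/out
lesionmap maps     --manifest demo/manifest.csv --out-dir demo/out
lesionmap vlsm     --manifest demo/manifest.csv --out-dir demo/out --config vlsm.yaml --seed 3
```

The `vlsm` step prints (and writes to `pre_vlsm_summary.json`):

```json
{
  "which": "pre",
  "n_patients": 80,
  "n_eligible_voxels": 1437,
  "z_threshold": -4.046648902347902,
  "n_significant_voxels": 18,
  "alpha": 0.05,
  "n_permutations": 500,
  "tail": "negative",
  "seed": 3
}
```

Reading this: 1437 voxels carried ≥3 tumors and entered the analysis; the
permutation-corrected significance cutoff for this cohort is Z ≤ −4.05
(far beyond the uncorrected one-tailed −1.64, as it must be when ~1400
voxels are tested jointly); 18 voxels fall below it — clustered, as
`pre_sig.nii.gz` shows, around the planted effect region. The observed t
and Z maps are deterministic; only the threshold depends on `--seed`.
Descriptive NIfTI maps (`cohort_ndist`, `cohort_meanpre`,
`cohort_meanchange`) and per-patient `scores.csv` / `metrics.csv` land in
the same directory.

The same pipeline runs from Python:

```python
from lesionmap import SyntheticConfig, VlsmParams, generate_cohort, run_vlsm

cohort, truth = generate_cohort(SyntheticConfig(n_patients=120, seed=1))
result = run_vlsm(cohort, which="pre", params=VlsmParams(n_permutations=2000, seed=2))
print(result.summary())
```

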
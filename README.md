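# canalkit

Curve-distance metrics, centerline extraction and multigrader variability
analysis for mandibular-canal segmentations.

## The problem

The mandibular canal carries the inferior alveolar nerve through the lower
jaw, from the mandibular foramen (posterior) to the mental foramen
(anterior). Locating it accurately in cone-beam CT (CBCT) is critical in
implantology: an implant placed within 2 mm of the nerve risks permanent
damage. Automatic segmentation systems are now good enough that the
interesting question is no longer "is the system close to one expert?" but
"is the system-to-expert disagreement smaller than the disagreement between
experts themselves?" — which requires multigrader validation machinery, not
just a Dice score.

`canalkit` provides that machinery for canal-shaped (curvilinear)
structures:

- **Curve metrics.** For point sets T (ground truth) and E (estimator),
  the point-to-curve distance d(x, S) = min_{s∈S} ‖x − s‖₂, the mean curve
  distance MCD(T, E) = (1/|T|) Σ_{t∈T} d(t, E) (asymmetric), its
  symmetrised form SMCD(T, E) = ½(MCD(T, E) + MCD(E, T)), the proportion of
  the canal path within a 2 mm safety margin, Dice overlap, positional
  distance profiles (200 uniform arc-length samples), spline densification
  of sparse control-point annotations, and posterior endpoint
  harmonization.
- **Centerline extraction** from a binary segmentation volume:
  3D medial-axis thinning, skeleton-graph decomposition into branch-free
  route segments with spur pruning, greedy gap concatenation, anatomical
  filtering by length and curvature, and selection of the left/right pair
  that is most mirror-symmetric about the midsagittal plane.
- **Consensus references.** Fixed-diameter rasterization of grader curves,
  per-voxel majority vote (ties labelled canal), and skeleton-based
  reference curves per side.
- **Variability analysis.** Pairwise assessor matrices (median [IQR] MCD,
  mean (SD) margin proportion), highest interobserver (IV) and
  system-to-expert (DV) variability per canal, exact/approximate two-tailed
  Wilcoxon signed-rank tests at α = 0.001, and device/clarity-stratified
  comparisons.
- **Synthetic cohorts.** Because clinical CBCT studies of this kind use
  private data, a phantom generator produces arch-shaped canal pairs with
  known ground truth, four simulated expert annotations per canal (control
  points ~3 mm apart, smooth systematic offsets, perpendicular jitter, rare
  gross errors) and segmentation-style volumes at 0.4 mm isotropic spacing
  with gaps, spurious components and boundary noise.

## Worked example

```python
import numpy as np
from canalkit import (
    generate_cohort, run_pipeline, PipelineConfig,
    mean_curve_distance, symmetric_mean_curve_distance,
)

# the two directed mean curve distances differ; SMCD symmetrises them
T = [(0, 0, 0), (4, 0, 0), (8, 0, 0)]
E = [(0, 1, 0)]
print(round(mean_curve_distance(T, E), 4))            # 4.3951
print(round(mean_curve_distance(E, T), 4))            # 1.0
print(round(symmetric_mean_curve_distance(T, E), 4))  # 2.6976

# a 6-scan synthetic study, end to end
cohort = generate_cohort(6, seed=42, system_mode="curve")
result = run_pipeline(PipelineConfig(out_dir="results/demo"), cohort=cohort)
overall = result.strata["device"].iloc[0]
print(result.log["n_canals"], result.log["n_system_missing"])
print(round(overall["iv_median"], 3), round(overall["dv_median"], 3))
```

which prints

```
4.3951
1.0
2.6976
12 0
0.72 0.752
```

The first three numbers show the asymmetry of the MCD (a short estimator
curve is "far" from a long truth curve but not vice versa) and the SMCD
that averages the two directions. The study run reports 12 canals (6 scans
× 2 sides), none lost, with a median highest-interobserver SMCD of 0.72 mm
and a median system-to-expert SMCD of 0.752 mm; at 12 canals these two are
statistically indistinguishable (the 150-scan studies run by
`scripts/acceptance.py` are where the medians stabilise).

A command-line interface mirrors the library:

```bash
canalkit simulate --out cohort/ --n-scans 20 --seed 1
canalkit evaluate --cohort cohort/ --out results/ --by device
canalkit extract --volume scan.nii.gz --out curves/
canalkit report --results results/ --out figures/
```

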
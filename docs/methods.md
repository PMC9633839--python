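# Methods

This note records the models, conventions and numerical choices behind
`canalkit`, and what the synthetic validation does and does not show.

## Coordinate and curve conventions

World coordinates are right-handed millimetres with x = left–right,
y = posterior–anterior and z = inferior–superior. Voxel index (i, j, k)
maps to `origin + index * spacing` with an identity direction matrix;
curves are always stored in world mm, never voxel indices, so they are
independent of any grid. Curves are ordered polylines from the posterior
end (mandibular foramen, the superior end of the canal's course) to the
anterior end (mental foramen); wherever an orientation must be inferred
from geometry, the end with the greater superior coordinate is taken as
posterior.

## Distance metrics

All curve distances are computed over discrete point sets — d(x, S) is the
minimum Euclidean distance from x to the points of S, with no
point-to-segment interpolation. Curves are densified to a 0.5 mm step
before measurement, so the discretisation error (≤ 0.25 mm worst case for
a single point, far less after averaging) is small against the 0.4 mm
voxel size of the volumes the curves come from. The accelerated
implementation uses a KD-tree and is required by the test suite to agree
with an exhaustive O(|T|·|E|) evaluation to 1e-9 mm.

MCD(T, E) averages d(t, E) over t ∈ T and is deliberately asymmetric: it
measures how well E covers T, and is insensitive to E being too long.
SMCD averages the two directions and is the summary used when neither
curve is privileged (interobserver comparisons). The 2 mm within-margin
proportion is the fraction of T's points with d(t, E) ≤ 2 mm, matching the
clinical implant safety margin.

Annotations arrive as sparse control points (~3 mm apart). Densification
fits a natural cubic spline with chord-length parameterisation — an
interpolating spline, so every control point is reproduced exactly — and
resamples it at uniform arc length. The true spline family of clinical
annotation tools varies by vendor; a natural cubic is the standard neutral
choice, and at 3 mm control spacing the difference between reasonable
spline families is far below annotator noise.

Endpoint harmonization: annotators disagree most about how far to trace
the canal toward the mandibular foramen. The curve whose posterior
endpoint is most inferior (the shortest annotation in the superior
direction) is the reference; every other curve is truncated at its point
nearest that reference endpoint. Anterior ends are untouched. By default
the pipeline harmonizes the four expert curves and the system curve of a
canal together, which keeps IV and DV comparisons on the same support; it
can be restricted to experts only, or disabled.

Dice on two empty masks is defined as 1.0 (both graders agree there is
nothing).

## Centerline extraction

The extraction chain converts a binary segmentation into a left/right
canal pair: thinning → route segments → concatenation → anatomical
filtering → symmetric pair selection. Parameters live in
`ExtractionConfig`; defaults below.

- **Pre-smoothing** (on by default): one-voxel morphological closing then
  opening. Voxel-level boundary noise otherwise riddles the medial axis
  with junctions and fragments the canal into many short segments.
- **Thinning**: 3D medial-axis thinning (Lee-style, via scikit-image).
- **Route segments**: the 26-connectivity graph of skeleton voxels is
  split at branch voxels (degree > 2) and walked into branch-free paths.
  Twigs shorter than 3 mm hanging off a junction are pruned first (and a
  junction whose remaining neighbours stay mutually connected is dropped
  as a thick corner). Segments shorter than 2 mm are discarded.
- **Concatenation**: greedy merging of the closest pair of route endpoints
  satisfying: gap ≤ 12 mm, end-tangent agreement ≤ 60°, bridge direction
  not a U-turn, and no bridge across the midsagittal plane (a mandibular
  canal never crosses the midline). Gaps are bridged with a straight
  polyline at 0.4 mm steps. The 12 mm pipeline tolerance looks large
  against a ~3 mm physical gap, but thinning retracts the skeleton from
  every cut face by roughly one tube radius, so a 3 mm gap in a 2.5 mm
  radius tube measures 8–11 mm between skeleton endpoints. Before
  bridging, the retracted cone tip (≈ 1.5 × the local tube radius, read
  from the Euclidean distance transform ~3 mm inside the end) is trimmed
  from each joining end — the tips sit off-axis and would drag the bridge
  off the true centerline. End tangents are estimated over a 5 mm reach to
  be robust to voxel-scale hooks.
- **Anatomical filter**: arc length in [30, 120] mm (closed interval) and
  mean absolute discrete curvature (turning angle per arc length, after
  2 mm resampling) below 0.5 mm⁻¹. Adult canals run ~50–70 mm and are
  smooth at this scale.
- **Pair selection**: the midsagittal plane is the vertical plane through
  the foreground centroid, normal to the left–right axis. For each
  route pair on opposite sides, the symmetry score is the SMCD between one
  route mirrored across the plane and the other; the minimal-score pair
  wins. One-sided results are reported as `partial`, an empty skeleton as
  `failed` — extraction never raises on a valid binary volume, and the
  pipeline counts per-canal failures instead of dropping them.

Extraction is fully deterministic; greedy ties break on the lower route
index.

## Consensus reference

Grader curves are rasterized as tubes of fixed diameter (default 3.0 mm, a
typical canal calibre; the clinical annotation tools use a fixed but
unpublished diameter, so this is configurable and recorded in output
metadata). Voting is per voxel: canal where canal votes exceed background
votes, background where background wins, and exact ties (even grader
count) labelled canal. The vote mask is skeletonized; per side of the
midsagittal plane the largest 26-connected component (ties by the most
posterior centroid) is ordered along its longest path into the reference
curve. Gaps are intentionally not bridged here: where graders genuinely
disagree, the consensus legitimately has missing parts, and the reference
should show that rather than invent geometry.

## Variability statistics

Per canal, the highest interobserver variability (IV) selects, among the
six unordered expert pairs, the pair maximizing the larger of the two
directed MCDs (the MCD is asymmetric while the pair is unordered, so
"highest MCD" needs this resolution), and reports that pair's SMCD. The
highest system variability (DV) selects, among the four experts, the one
maximizing MCD(expert, system) — expert as ground truth, system as
estimator — and reports that SMCD. The selection statistic (directed MCD)
deliberately differs from the reported statistic (SMCD).

IV and DV are compared per canal with a two-tailed Wilcoxon signed-rank
test at α = 0.001. Zero differences are dropped (standard signed-rank
convention) and counted. For n ≤ 25 the p-value is exact: the distribution
of the positive-rank sum over all 2ⁿ equally likely sign assignments is
computed by dynamic programming (midranks handled by doubling, so tied
ranks are exact too); this is verified against full 2ⁿ enumeration in the
tests. Larger samples use the normal approximation with tie correction
(scipy). Summaries report median, IQR (Q3 − Q1 with linear-interpolation
quantiles — no quantile rule is canonical, so the rule is fixed and stated
in output metadata), mean, and SD with the n − 1 denominator. Stratified
comparisons (by device, clarity or condition flag) run the same paired
test per stratum, skip and flag strata with fewer than 5 complete pairs,
and always include the overall row. No multiplicity correction is applied
across strata; raw p-values are reported against α = 0.001.

### A structural caveat on the IV-vs-DV comparison

IV is the maximum over six expert pairs; DV the maximum over four
expert–system pairs. Even when the system is statistically exchangeable
with the experts (identical noise model), a maximum over six dependent
values stochastically dominates a maximum over four, so IV carries a
positive bias of roughly 0.05 mm at the default noise level. With 300
paired canals the signed-rank test detects this reliably (p ≪ 0.001 in
every replicate of the calibration experiment). The comparison design is
therefore *not* calibrated as a null test: a significant "system better
than interobserver" result partly reflects the selection asymmetry, not
only system quality. The package implements the comparison as designed and
documents the bias; the calibration experiment in the acceptance tests
makes it visible rather than hiding it.

## Synthetic cohort model

The phantom emulates the *structure* of a multigrader CBCT study — not
image physics. Per scan:

- **Geometry.** Each canal follows a parabolic arch in the axial plane
  (arch width 90 mm, depth 32 mm, each varied ±5% per scan), rises
  superiorly toward the posterior end (vertical dip 8 mm, minimum at 55%
  of the course) and ends 6 mm lateral of the midline anteriorly; arc
  length ≈ 54 mm (adult canals: 50–70 mm). The right canal is the mirrored
  left plus a smooth ≤ 1 mm asymmetry field. Volumes use 0.4 mm isotropic
  spacing, the standard resampling target for CBCT canal work.
- **Annotators.** Control points at ~3 mm arc spacing on the (posterior-
  truncated, half-normal SD 1.5 mm) truth, displaced by a smooth
  systematic offset (squared-exponential kernel, SD 0.22 mm, correlation
  12 mm — an annotator's personal idea of the canal centre), white
  perpendicular jitter (SD 0.15 mm), and, with probability 0.024 per
  control point, a gross error: a 3 mm displacement perpendicular to the
  canal, modelling a marking placed outside the actual canal. The four
  default experts scale the noise by 1.25/1.1/0.95/0.85 to emulate
  differing annotator habits; Unclear canals (15% of sides) get 1.5×
  noise. The jitter and offset SDs were set so the cohort's median
  highest-IV SMCD lands near 0.77 mm, inside the 0.5–0.9 mm range reported
  for expert canal annotation — this calibration is illustrative of
  realistic magnitudes, not a claim about any particular dataset.
- **System output.** Either a curve from the same annotator noise family
  (curve mode — used for statistical calibration studies, where volume
  rasterization would only add cost) or a defective label volume (volume
  mode): tubes of radius 1.5 mm with 10% boundary-voxel flips, a 3 mm
  axial gap with probability 0.3, a spurious off-canal component with
  probability 0.3 (placed ≥ 14 mm from the canals so it exercises the
  anatomical filter, not the gap bridging), and an outright missing canal
  with a configurable failure probability.
- **Metadata.** Device labels follow configured proportions over the five
  scanner names; condition flags (movement/metal artefacts, osteotomy,
  difficult bone/pathology) are Bernoulli draws at rates 0.08/0.15/0.02/
  0.10/0.05.

One global seed fans out to per-scan and per-component seeds via
`numpy.random.SeedSequence.spawn`, so any artefact can be regenerated
independently and bit-identically; the manifest records all generator
parameters.

**What passing tests show — and don't.** The phantoms validate the
geometry pipeline (metrics, extraction, voting, statistics) against known
truth, and the noise model reproduces the magnitudes of expert
disagreement. They do not contain real CBCT appearance, metal or motion
artefacts as image content, annotator biases correlated with anatomy, or a
real segmentation model's error structure; conclusions about any specific
clinical system require that system's own data.

## Problem sizes and numerical choices

The acceptance script runs a 20-phantom extraction study, a 150-scan
(300-canal) curve-mode variability study and a 40-scan consensus study —
sizes chosen so the whole reproduction completes in about a minute on one
CPU while keeping the medians stable to a few hundredths of a millimetre.
The null-calibration experiment uses 20 replicate 150-scan cohorts.
Degenerate inputs are handled explicitly: empty volumes give `failed`
status rather than exceptions; an absent system curve excludes that canal
from DV with a logged count; empty consensus sides are flagged absent; the
signed-rank test warns and returns p = 1 when every difference is zero and
refuses n < 5. Report CSVs are written with fixed float formatting and
sorted keys, making pipeline reruns byte-identical.

## Known limitations

- Distances are point-set based; for extremely sparse curves the MCD
  overestimates slightly versus a segment-based distance (densification
  makes this negligible at the defaults).
- The gap-bridging tolerance trades off bridging genuine interruptions
  against falsely joining nearby structures; the midline guard removes the
  worst failure mode, but heavily fragmented segmentations of short canals
  can still yield `partial` results.
- The consensus reference inherits voxel resolution: reference curves are
  accurate to about one voxel (0.4 mm), which bounds how finely
  assessor-vs-reference SMCDs can be interpreted.
- The IV-vs-DV comparison carries the selection bias described above; any
  use of this design on real data should report it.
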
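# Methods

## Margin geometry

All geometry is computed on binary voxel masks with per-axis physical
spacing (sx, sy, sz) in mm; a voxel is wholly foreground or background
(no sub-voxel weighting), and volumes are foreground counts times the
voxel volume sx·sy·sz. Distances are Euclidean distances **between
voxel centers**, computed with an exact Euclidean distance transform
that takes the anisotropic spacing into account. This voxel-center
convention is a declared choice: clinical margin software may use
surface meshes or slice-wise distances, and no single convention is
standard. The convention used here is reproducible and admits an exact
brute-force oracle (all-pairs voxel-center distances), against which
the transform and the dilation operator are tested for exact agreement
on small grids.

The m-mm expansion of the tumor is the set of voxels with distance
≤ m; the margin shell is the expansion minus the tumor, so shell
membership is 0 < d ≤ m — *closed* at m, i.e. a point exactly m mm from
the tumor belongs to the m-mm margin. A relative slack of 1e-9 is
applied when thresholding distances at m so that voxels at exactly m mm
are never lost to floating-point representation. Volume conservation
V(expansion) = V(tumor) + V(shell) holds exactly by construction.

If an expansion would reach any face of the array it raises an error
rather than silently clipping: a clipped shell is unobserved territory
and would bias the unablated percentage downward. Callers pad their
volumes instead.

The unablated safety-margin percentage at margin m is
U_m = 100 · V(shell \ ablation) / V(shell); the residual tumor
percentage is R = 100 · V(tumor \ ablation) / V(tumor). A margin so
small that the shell contains no voxel at the given resolution (e.g.
0.5 mm margins on 3-mm slices) is an error, not 0/0.

### Completeness classification

Per margin, a case is assigned one of five classes:
INCOMPLETE when R exceeds the residual tolerance (default 0 — any
uncovered tumor voxel); otherwise SM100 when U_m is exactly 0 (zero
uncovered shell voxels), SM95_100 when 0 < U_m < 5, SM90_95 when
5 ≤ U_m ≤ 10 (both bounds inclusive), SM_LT90 when U_m > 10. The
residual tolerance is configurable as an absolute volume (mm³) to
absorb sub-voxel segmentation noise; percentages are computed at full
precision and rounded to one decimal only in reports.

### Discretization behaviour

On sphere phantoms the voxelized U_m converges to the closed-form
shell fraction 100·((rt+m)³−ra³)/((rt+m)³−rt³) as the voxel size
shrinks (measured errors for rt=10, ra=12, m=5: 5.6 → 1.2 → 0.8
percentage points at 2 / 1 / 0.5 mm voxels). Dilation of a discretized
shape is biased slightly *inward* (up to about half a voxel diagonal),
so dilated volumes sit a few percent below their continuous
counterparts at 1-mm voxels; the tests assert the measured bounds.

## Synthetic data

**Sphere phantoms** voxelize two analytic spheres (tumor at the grid
center, ablation offset along one axis) by center inclusion on an
arbitrary anisotropic grid, with enough empty padding for the largest
margin. Offsetting the ablation center makes every completeness class
reachable. The exact coverage of any such configuration has a closed
form via sphere–sphere intersection (spherical-cap lens) volumes,
which serves as the independent oracle.

**Cohort simulation** works directly in percentage space (no masks),
so statistics tests can use hundreds of cases cheaply. Each case draws
a coverage-deficit depth c (mm, uniform on [0, 14] by default — cases
with c ≥ 10 are fully covered at every evaluated margin) and a
solid-angle fraction f (uniform on [0.05, 0.6]); the unablated
percentage follows the radial model

    U_m = 100 · f · max(0, ((rt+m)³ − (rt+c)³) / ((rt+m)³ − rt³))

on a nominal tumor radius rt = 12 mm (half the 24-mm mean tumor
diameter typical of such cohorts), which is non-decreasing in m by
construction, matching the shape of real margin profiles. A
`make_deficit_phantom` helper materializes the same model as an actual
mask pair (coverage shortfall over a cone of directions) for
end-to-end tests. Defaults: 76 cases, incomplete-ablation fraction
2/76 (those cases get c = 0 and a uniform residual percentage); LTP is
the threshold rule U at 6 mm > 10% flipped with Bernoulli noise
ε = 0.05. Times to LTP are log-normal with log-scale parameters
(2.731, 0.594), matching moments of 18.3 ± 11.9 months (positive and
right-skewed); follow-up/censoring is uniform on 12–72 months, and an
event time is truncated at the case's follow-up horizon. All
randomness flows from one seeded generator; identical spec + seed is
bit-for-bit reproducible.

The simulator emulates the *structure* of a margin-profile cohort
(monotone profiles, a threshold-driven outcome, censored follow-up),
not any real cohort's distributions: the per-case values of tumors
without progression are not published anywhere, so the deficit and
noise defaults are modelling choices. Passing statistics tests on
simulated cohorts demonstrates estimator correctness, not clinical
performance.

## Cohort statistics

The unit of analysis is the tumor, not the patient; no clustering
adjustment is applied. Completeness tables count the five classes per
margin with LTP tallies; cumulative tables report the nested 100% /
>95% / >90% / all groups (prefix sums of the class table). Association
uses the uncorrected chi-square test of independence (Yates correction
available by flag), falling back to the two-sided Fisher exact test
for 2×2 tables with any expected count below 5; Fisher is verified
against full hypergeometric enumeration. Continuous comparisons use
the pooled-variance two-sided t test (degenerate zero-variance inputs:
p = 1 for identical constants, p = 0 for distinct ones). LTP-free
survival is the Kaplan–Meier product-limit estimate (cases without LTP
are censored at last follow-up) compared by the log-rank test. No
multiple-testing adjustment is applied; p-values are reported raw.

ROC analysis sweeps thresholds at midpoints between distinct values of
U_m; ties contribute 1/2 (Mann–Whitney convention), so the trapezoidal
AUC equals the normalized concordant-pair count. The
**100%-sensitivity cut-off** is the largest threshold on a 0.1
percentage-point grid strictly below the minimum U among LTP cases
(floored at 0), with specificity the fraction of non-LTP cases at or
below it; the grid matches the one-decimal precision of the reference
data. The zone bands take green = [0, g) with g the 100%-sensitivity
cut-off, red = (r, 100] with r the largest U among non-LTP cases, and
gray = [g, r] when the classes overlap (empty otherwise).

## Reference cohort

The package ships the nine published LTP tumors of a 76-tumor
stereotactic-RFA cohort (per-tumor residual %, U_1..U_10, time to LTP,
covariates) as a CSV at the printed one-decimal precision, plus the
printed aggregates: per-margin class totals (which involve the 67
unpublished non-LTP tumors and are therefore embedded constants, not
recomputable) and headline rules. `verify_reference()` re-derives every
recomputable aggregate from the nine rows — class tallies at all ten
margins, fully-covered counts, the two margin rules (3 mm for full
coverage, 6 mm for ≥90% coverage), the 3.2%/11.2% cut-offs, and the
18.3 ± 11.9-month time-to-LTP summary. One source cell (tumor 77's
time/residual columns) is typographically ambiguous; the 7.5-month /
69.1% reading is used, and both readings give identical aggregates at
printed precision.

Published quantities that require the unpublished non-LTP values or
follow-up times — survival rates at 1/2/3 years, per-margin AUCs, the
specificities at the cut-offs, the upper gray-zone bound — are not
asserted against; the corresponding estimators are instead validated
by construction (empirical-survival identity, exhaustive pair-count
oracle, threshold recovery on noiseless simulated cohorts).

## Problem sizes in the test suite

Brute-force distance oracles run on grids up to 24³; convergence
checks use sphere phantoms at 2 / 1 / 0.5 mm voxels (up to 77³);
Fisher enumeration covers all 2×2 tables with N ≤ 40 up to row/column
symmetry; the chi-square/permutation comparison uses 10⁵ permutations
of a 500-case table; the t-test type-I-error check uses 2000 null
replicates at n = 30 + 30; threshold recovery uses noiseless simulated
cohorts of 500. These sizes were chosen to make each oracle exact or
its Monte-Carlo error negligible relative to the asserted tolerance.

## Known limitations

* Registration, segmentation and resampling are out of scope: inputs
  must already be co-registered binary masks on one grid (orientation
  equality is required, not corrected).
* Voxel-center distances understate margins relative to surface-based
  definitions by up to half a voxel; at 3-mm slice thickness this is
  material for sub-voxel margins and is why empty shells are an error.
* The classification treats any nonzero residual voxel as incomplete
  unless a tolerance is supplied; segmentation noise on real data will
  need a nonzero tolerance.
* Cumulative-table percentages for mixed published/recomputed groups
  rely on the embedded published denominators.
* No patient-level survival, no multivariable (Cox) modelling, no AUC
  confidence intervals.
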
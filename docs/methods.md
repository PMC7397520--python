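# Methods

## ROI quantification model

A site's mean uptake is measured in a sphere of fixed physical diameter
placed in world (mm) coordinates: 30 mm for the femoral head, 10 mm for
the acetabular dome. The protocol mirrors workstation practice: in each
of the three orthogonal planes the single central cross-section through
the sphere's centre is taken (the slice whose coordinate is nearest the
centre along the plane's normal), the mean of the counts over the closed
disc of in-plane voxel centres within the radius is computed, and the
three per-plane means are averaged with equal weight. Whether per-plane
samples should be single central slices or thicker slabs is genuinely
open; the single-slice reading was chosen and is recorded in each
measurement's `mode` field, and a full-3-D sphere mean is available as an
explicitly flagged alternative (`mode="sphere"`). The two generally
differ; they coincide on fields that are constant within the sphere.

Conventions applied identically everywhere: world coordinate of voxel
index *i* is *i*·spacing (0-based; x left-right, y anterior-posterior,
z inferior-superior); disc/sphere membership is voxel-centre within the
radius with ties at exactly the radius included; ROIs that reach past the
volume edge are clipped and the reduced voxel count reported, since dome
ROIs near the pelvic edge can clip. Zero eligible voxels raises a
measurement error (it signals ROI misplacement).

Cortical exclusion: the head ROI drops voxels labelled cortical in the
paired structure volume, so that the sample is cancellous bone only. On
real data with no label channel, thresholding the CT at a configurable
Hounsfield value (default 400 HU) produces the substitute mask
(`structure_from_ct`).

## Perfusion scores and classification

`R_hh` = affected-head mean / contralateral-head mean; `R_ha` =
affected-head mean / ipsilateral-dome mean. Both are invariant to global
count scaling, which is the rationale for relative quantification. The
reference rule is total over the four contralateral statuses: healthy →
contralateral head; implant, ONFH, or osteoarthritis → ipsilateral
acetabular dome. Classification calls ONFH when ratio ≤ cutoff; the tie
at exactly the cutoff is classified as ONFH, the conservative direction
for a screening decision (the convention is documented, not derivable).

## Diagnostic evaluation

Sensitivity, specificity and accuracy come from the 2×2 table of
predictions against outcomes. Likelihood-ratio CIs use the log method,
`exp(ln LR ± z₁₋α/₂·SE)` with the standard SE formulas on the table
cells; the method reproduces the reference intervals for the benchmark
reader table (5, 6, 1, 18) to two decimals (the LR+ lower bound computes
to 1.528). Zero cells make a CI undefined; an optional Haldane +0.5
correction (off by default, flagged in the output) is applied to the CI
computation only, never to the point estimates. An infinite LR+
(specificity 1) or zero LR− (sensitivity 1) is reported as such with the
CI omitted. Simulated coverage of the LR+ interval at n = 30 is near
nominal (97% over 2,000 replicates in the test suite).

## ROC and DeLong comparison

Perfusion ratios are negatively oriented, so the sweep calls a case
positive when score ≤ threshold, from a −∞ sentinel upward over the
distinct observed scores with ties grouped. The trapezoidal AUC equals
the Mann-Whitney pair-count AUC (ties ½) exactly on every input; both are
implemented and the identity is property-tested. The Youden-optimal
cutoff maximises J = sens + spec − 1, ties broken toward higher
specificity and then the lower threshold; the *reported* cutoff is the
midpoint between the optimal observed score and the next distinct score,
which yields clean values (0.5, 0.3) when the groups are separated.

DeLong's test uses placement values: per-positive and per-negative mean
concordances give sample covariance matrices (ddof 1) of the two
correlated AUC estimates; z = ΔAUC/√(var_a + var_b − 2cov) with a
two-sided normal p. Identical score vectors short-circuit to z = 0,
p = 1; a zero variance of the difference with unequal AUCs raises a
degenerate-variance error rather than dividing by zero. Single-case
placement vectors contribute zero variance. An unpaired variant (two
independent case sets, covariance 0) is provided because cohorts with
partially measurable scores may not pair cleanly. The implementation was
cross-checked against an independent reference implementation to 1e-10 on
a frozen fixture, and its variance against a 10,000-resample stratified
bootstrap.

## Synthetic phantom and cohort generator

The voxel phantom emulates *reconstructed* SPECT output, not acquisition:
two femoral heads (radius 22 mm, cortical shell 3 mm) with the affected
head's cancellous rate reduced, two acetabular domes (radius 10 mm),
uniform background, each voxel's expected value equal to its tissue
class's rate, and optional Poisson sampling — the natural noise model for
photon counting. Default rates (66.3 affected, 201.3 unaffected, 319.1
dome, counts/voxel) are the group means of the ratio analysis, so the
noiseless ratios are 0.329 and 0.208. Class assignment is
voxel-centre-inside-analytic-shape with no partial-volume blending, heads
taking precedence over domes. The grid is 96³ at isotropic 2.95 mm —
desk-scale rather than clinical matrix size, preserving mm geometry; all
geometry is configurable. Non-goals: gamma-camera acquisition, iterative
reconstruction, attenuation correction, metal artifacts, and any
biomechanical modelling of necrosis progression.

Cohort-level draws use truncated normal group distributions for each
ratio, parameterised by (mean, sd, lower, upper) with sd back-computed
from a normal-theory 95% CI half-width, sd = half·√n/1.96 (n = 6 ONFH
gives sd 0.0625; n = 24 union gives sd 0.675 for the head-to-head ratio).
The `mean` is the mean of the *truncated* distribution: the parent
normal's location is calibrated by root finding so that asymmetric bounds
do not bias the group mean (with the union group's bounds [0.55, 2.50] an
uncalibrated location of 1.30 would drift the realised mean to ≈1.41).
Head-to-head bounds ([0.18, 0.45] and [0.55, 2.50]) keep the groups on
opposite sides of the 0.5 cutoff, reflecting the perfect separation the
score shows at that operating point; the head-to-acetabulum bounds
([0.10, 0.29] and [0.35, 2.20]) follow the same logic around 0.3. The
two ratios of a patient are drawn comonotonically (one latent uniform
through both quantile functions), giving the within-patient coupling real
scores exhibit since both share the affected-head numerator. A fraction
of patients (default 6/30) is flagged contralateral-incomparable with
statuses implant/ONFH/OA in proportions 4:1:1. The drawn head-to-head
ratio is stored on every record as generator ground truth; reference
selection controls only which ratio feeds the primary classification.
Seeds are explicit fields and cohorts are pure functions of them.

What the generator does *not* emulate — and hence what passing tests do
not show about clinical data: measurement noise in ROI placement, partial
volume and reconstruction blur, inter-patient anatomical variation,
overlap between outcome groups (the truncation enforces separation), and
any relationship between ratios and covariates such as fracture
displacement. Results on the default cohort are a consistency check of
the pipeline under the stated distributional assumptions, not evidence of
clinical performance.

## Problem sizes and numerical choices

Defaults are chosen for desk-scale runs: 96³ phantoms (≈0.9 M voxels)
build in well under a second; the default cohort is 30 patients; the
bootstrap oracle in the tests uses 50 fixtures × 10,000 resamples; group
mean recovery is checked over 200 seeded cohorts. Exact assertions on ROI
means use a 1e-9 absolute tolerance (floating-point mean of identical
values); the AUC identity is asserted at 1e-12. Truncated-normal
calibration solves the location to 1e-12 by Brent's method. Group-mean
CIs in summaries use z = 1.96 rather than t, matching the convention used
to back-compute the generator's sds; with n = 6 a t interval would be
≈31% wider, so the two should not be mixed.

## Known limitations

- The three-plane mean is an interpretation of an under-specified manual
  protocol (single central slices; equal plane weights).
- The phantom's spherical, concentric geometry makes cortical exclusion
  trivially clean; real heads are neither spherical nor uniformly shelled.
- The acetabular dome is modelled as a 10 mm sphere of uniform uptake;
  real domes are aspherical and cortex-adjacent, and clinical pre-measured
  maximum ROI diameters vary from 10 to 24 mm.
- Likelihood-ratio CIs rely on the log-normal approximation, which is
  skewed at the small counts typical here (visible as over-coverage
  tendencies near cell boundaries).
- The DeLong normal approximation is asymptotic; at 6 positives it is
  indicative rather than exact, and degenerates entirely when both AUCs
  are 1 (the separated default cohort), where only the null result is
  meaningful.
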
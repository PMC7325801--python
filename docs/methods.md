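# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical choices, and the limits of what the
passing tests demonstrate.

## Statistical model of the task analysis

The unit of analysis is the parcel-averaged contrast effect size
("beta") per subject, area, and contrast, over a 360-area cortical atlas
(180 areas per hemisphere). Because MD activation is largely bilateral,
betas are averaged across hemispheres before testing, which halves the
residual variance and doubles effective power; a per-hemisphere mode is
kept for sensitivity checks.

**Significance of an area.** One-sample *t*-test of the group betas
against zero. We use a two-sided *p* with a positive-mean gate rather
than a one-sided test: "significantly positive" then means
*p* ≤ α/m **and** mean > 0, which is conservative relative to the
one-sided convention and never declares a negative effect positive.
Per contrast, m = 180 (Bonferroni over the areas tested); α = 0.05
throughout. Zero-variance samples are flagged degenerate and decided by
the sign of the constant mean instead of silently passing.

**Extended MD set.** The intersection of significant-positive areas
across the three contrasts. The familywise error of the conjunction is at
most that of a single contrast, because a null area must pass all three
gates; the all-zero calibration test confirms ≤ 5% of null cohorts
produce any extended-MD area.

**Core classification.** "Stronger than the mean of the extended set" is
operationalized per subject: for area *a*, contrast *c*, the statistic is
d_s = beta[s,a,c] − mean over the extended set of beta[s,·,c], tested
against zero with Bonferroni m = |extended set|. This paired-style form
cancels any per-subject global offset (scanner/responder effects), which
is why the generator's shared subject offset is irrelevant to core
membership — an invariance the suite tests directly. Areas above the mean
in all three contrasts are full core, in exactly two are partial core
(the threshold comparison is inclusive, p ≤ α/m); the rest of the
extended set is the penumbra. An alternative reading — comparing each
area's group mean to the grand mean across subjects — is not the default
because it retains between-subject variance in the contrast of interest.

**Segments.** The segment table (20 posterior→anterior segments, ten per
area, border fixed between segments 10 and 11) is the contract boundary;
geometric division of surface areas is upstream of this package. Each
segment is held to the *same* criterion as a full area (α/180 per
contrast, three-way conjunction), since the question is whether a segment
would survive as an extended-MD region on its own; m stays a flag for
other conventions. Significant segments merge by equal-weight mean into
one composite area.

**Task profiles.** Within each subject and contrast, betas across the MD
set are z-scored with the sample SD, then averaged over subjects. By
construction each subject's z-profile has mean 0 and SD 1, so the
subject-mean profile columns are centered — asserted to 1e-12. The
between-task SD per area is computed per subject across the three
contrasts' z-scores and then subject-averaged. Split-half replication
correlates group-mean profiles across areas between two disjoint subject
halves for every contrast pair; family structure does not exist in the
generator, so a plain random half-split stands in for the family-aware
split used with real cohorts.

## Functional connectivity

Per subject, FC is the Pearson correlation of parcel time series
(360×360). Averaging — across pairs within a connection group, across
subjects for the group-average matrix — always happens after the Fisher
r-to-z transform (arctanh), with back-transform for display only;
statistics stay in z-space. |r| is clamped at 1−1e-7 before arctanh with
a warning; the diagonal is excluded from every group mean.

Connection groups are the six unordered pairs of the classes
{core, penumbra, nonMD}; group means use within-hemisphere pairs only
(cross-hemisphere connectivity mixes homotopic effects into every group),
giving C(6,2) = 15 paired *t*-tests per hemisphere and a Bonferroni
m = 30 overall. In the FC analyses the 8BM/SCEF composite is unpacked:
8BM counts as core and SCEF as penumbra.

MDS uses classical (Torgerson) scaling of 1−r: double-center −½·J·D²·J,
eigendecompose, scale the top-k eigenvectors by √eigenvalue. 1−r is not
guaranteed Euclidean, so negative eigenvalues are truncated to zero with
a warning and their count reported. Coordinates are unique only up to
rotation/reflection; all tests compare reproduced distance matrices,
never raw coordinates.

## Subcortex

Task mapping: per structure and contrast, voxelwise one-sample *t*
(positive-gated), Benjamini–Hochberg FDR **within** each structure at
q = α/19 — FDR inside, Bonferroni across the 19 structures — then the
three-contrast conjunction. The composition order (FDR at a
Bonferroni-shrunk q) is one reading of a procedure that could also be
composed the other way; it is the stricter and simpler one.

FC mapping: each voxel's score is its mean z-connectivity to the cortical
core parcels. The null draws random parcel sets of the core's size from
all 360 parcels across both hemispheres — one shared draw per permutation
reused for every voxel (each voxel's null distribution is identical to
per-voxel draws; sharing only introduces weak dependence between voxels'
thresholds, and an independent-draw mode exists behind a flag). True core
parcels are not excluded from the draws by default (exclusion is a flag).
Significance requires the observed score to *strictly* exceed the
nearest-rank 97.5th percentile of the voxel's null, so a degenerate
all-zero null can never be significant. The default n_perm is 10 000,
with 100 000 available to match the original convention; with the
nearest-rank definition the flag decision is already stable at 10 000
(P(score > threshold) ≈ (n−rank)/(n+1) ≈ 0.025 for exchangeable nulls,
which the null-calibration test verifies within 3 Monte-Carlo SEs).
For ≤ 12 parcels the sampled null is checked against exhaustive subset
enumeration.

Replication between two maps: Pearson *r* over the continuous scores of
one structure's voxels, Dice = 2|A∩B|/(|A|+|B|) over the significant
sets (defined as 1 when both sets are empty).

## The synthetic cohort

The generator emulates the statistical structure the analyses assume,
with planted membership as ground truth.

**Task betas.** beta[s,a,c] = μ[a,c] + u_s + e, with u_s ~ N(0, 0.25²)
shared across areas and contrasts (a global responder effect — it
inflates per-area tests slightly and cancels exactly in the core
statistic) and e ~ N(0, 1²). Effects are in residual-SD units:
background 0; the 27 extended areas 0.4 in all three contrasts; the 7
full-core areas 0.8 in all three; the 3 partial-core areas 0.8 in exactly
two (IFJp: relational & math; 8C, PFm: WM & relational) and 0.4 in the
third, exercising the two-of-three rule. Penumbra areas additionally
carry ±0.1 zero-sum task-preference patterns so that profiles differ
between contrasts (driving the diagonal dominance of the split-half
profile correlations) without moving the extended-set means. A few
background areas are active in only one or two contrasts to exercise
conjunction rejection; SCEF as a whole area is planted positive but
sub-threshold in two contrasts and zero in the third, while its anterior
two segments carry the ramp. At n = 449, the weakest planted decision
(effect 0.3 after preference perturbation, hemisphere-averaged SD 0.75)
has noncentral-*t* power > 0.9999 at the Bonferroni threshold, so exact
recovery of all planted sets is near-certain — verified over seeded
replicates and by the closed-form power computation.

**Rest time series.** x_a(t) = Σ_k λ_ak f_k(t) + ε_a(t) with unit-variance
iid Gaussian factors and noise, T = 1200 timepoints. K = 4 factors is the
minimum producing the four FC tiers: core parcels load (0.8, 0.3) on the
core and penumbra factors, penumbra parcels (0.35, 0.45), background
parcels 0.4 on one of two background factors (alternating). Implied
population correlations: core–core 0.42 > core–penumbra 0.27 >
penumbra–penumbra 0.25 > within-background 0.14 > cross-group 0 — the
strict tier ordering the FC tests check in sample.

**Segments.** Population means 0 for SCEF segments 1–8, a ramp 0.45/0.9
over SCEF 9–10, 0.9 at the first 8BM segment and 0.7 across the rest:
build-up along anterior SCEF, peak at the border, sustained plateau
through 8BM. Same noise model as the task betas.

**Subcortex.** 19 structures × 30 voxels. Planted MD voxels (10 each in
left/right caudate and cerebellum, analogues of the caudate head and
cerebellar crus) carry task effect 0.8 in all contrasts and loading 0.6
on the core factor; null voxels are pure noise. The voxel rest session
shares its factor realizations with a matching cortical session, so
voxel-to-core FC is well defined.

**What the generator does not emulate.** No hemodynamics, autocorrelated
noise, head motion, family structure, spatial smoothness within
structures, hemispheric asymmetries, or heavy-tailed effect
distributions. Passing recovery tests therefore show that the
*procedures* are implemented correctly and are well calibrated under the
assumed model — not that real cohorts would reproduce any particular
area list. One known divergence: with correlated cortical parcels, the
random-set permutation null for voxel FC is anti-conservative for voxels
genuinely correlated with *any* cortical system (the null sets are less
internally correlated than the true core), which is a property of the
procedure itself; the calibration claim is made, and tested, under
independent series.

## Problem sizes and defaults

| parameter | default | note |
|---|---|---|
| n_subjects | 449 | full cohort size; recovery power calibrated here |
| sigma_subject / sigma_noise | 0.25 / 1.0 | between-subject offset, residual SD (beta units) |
| n_timepoints | 1200 | rest session length |
| α / m areas / m extended / m comparisons / structures | 0.05 / 180 / 27 / 30 / 19 | correction constants |
| n_perm / percentile | 10 000 / 97.5 | permutation null (100 000 available) |
| FC subjects in the orchestrated run | 24 | group means converge quickly; counts are structural |

Reduced cohorts in the fast tests (e.g. 120 subjects) scale the noise
down in proportion so the planted detection margins are preserved; the
full-cohort recovery tests and the acceptance script run at n = 449.

## Known limitations

- The area-name fixture carries the published MD labels, but a few
  penumbra labels beyond those named in the analysis narrative are
  best-effort placeholders from the same parcellation's vocabulary; the
  network assignment is a synthetic fixture shaped to the published
  core/penumbra-by-network counts, not the real partition.
- The CIFTI adapter reads parcellated files only and is exercised
  nowhere in the core pipeline.
- Subject-level (rather than group-average) observed statistics for the
  subcortical permutation test are provided but not validated against
  any external convention.
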
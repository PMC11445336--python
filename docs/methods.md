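# Methods

## Overview

`metaconn` computes three constructions of interregional brain
connectivity — group-level static-PET covariance (sPET), subject-level
constant-infusion fPET correlation, and subject-level fMRI correlation —
binarizes them by edge significance, intersects pairs of modalities into
common-edge ("tertiary") connectomes, and compares nodal degree between
groups and against disease severity. Because the imaging data such a study
rests on are not publicly deposited, the package ships a synthetic cohort
generator with a fully known ground truth; every empirical claim in the
test suite is a claim about recovery of that planted truth.

## Synthetic cohort: generative model

### Atlas

A toy label atlas partitions a voxel grid (default 12×12×12) into R
contiguous parcels (default 30, each ≥ 8 voxels), assigned to seven
functional units: cortical_motor, subcortical, cerebellar, frontal,
parietal, occipital, temporal. The construction is deterministic.

### Planted network structure

Connectivity is planted as *edge communities*: within-unit cliques that
share one latent factor each. The region-mean fluctuation signal is the
linear latent-factor model

    y_i(t) = Σ_k λ_ik f_k(t) + σ_i ε_i(t),      λ_ik = sqrt(s_k),

with independent standard-normal factors f_k and idiosyncratic terms
ε_i, and σ_i² = 1 − Σ_k λ_ik². Two regions sharing exactly one community
therefore correlate at exactly s_k, so target correlations are available
in closed form. Every unit carries a community in both groups; the
cortical-motor community is the planted *group effect*: controls keep a
reduced 3-region motor clique, patients the full motor unit, so the
patient truth has strictly more motor–motor edges. For motor communities
the strength is scaled by a per-subject coupling score c ∈ [0, 1]
(patients: c ~ U(0.3, 1.0); controls: c = 0.6).

The idiosyncratic term is split into two spatial channels with identical
region-mean statistics: a fraction `roi_coherent_frac` (default 0.5) of
its standard deviation is painted uniformly over the parcel, the rest is
spatially white voxel-level physiological noise. This mirrors real data —
a network's shared fluctuation dominates any parcel-aligned idiosyncrasy —
and is what lets group spatial ICA recover a community as one component:
a parcel-coherent idiosyncratic term at full strength would itself be an
independent sparse spatial source competing with the networks.

### Modalities

* **fPET** (90 one-minute frames): voxel value = accumulation ramp
  b_i·t + a_i·y_i(t)·1[t > 60] + N(0, noise_sd). Fluctuations are injected
  only into the last 30 frames, so the frame-retention rule is what
  exposes them; early frames are pure low-information ramp. The amplitude
  is a_i = `fluct_amp`·β_i (default 2.0, ≈ 3 % of late-frame signal).
* **sPET**: not simulated separately. The subject's accumulation rate is
  b_i = β_i (1 + `uptake_cv`·u_i) with a *subject-level* latent u_i using
  the same community loadings, so summed uptake covaries across subjects
  along the planted edges. β_i ~ U(0.8, 1.2) is fixed per atlas.
* **fMRI** (490 frames): voxel value = baseline + amp·AR1(y_i)(t) +
  N(0, noise_sd). Factor, coherent-idiosyncratic and voxel channels are all
  AR(1)-filtered with the same coefficient (default 0.4), which preserves
  contemporaneous correlations while giving each series the nominal lag-1
  autocorrelation.

Severity is the affine-monotone transform 15 + 30·c + N(0, 4.5), clipped
at 0 — strictly increasing in the coupling score before noise. The noise
s.d. was chosen a priori so the recovered Spearman correlation at n = 12
lands in the ρ ≈ 0.5–0.7 range typical of small motor-severity cohorts.

### Parameter defaults and rationale

| parameter | default | meaning / why |
|---|---|---|
| n_pd / n_hc | 12 / 13 | study-sized groups |
| n_rois, grid | 30, 12³ | smallest atlas with ≥ 3 regions per unit and ≥ 8-voxel parcels |
| edge_strength | 0.7 | planted community correlation; clears the across-subject significance threshold r ≈ 0.58 at n = 12 so sPET edges are recoverable |
| coupling (PD) | U(0.3, 1.0) | spans sub- and supra-threshold subject-level motor correlations at 30 frames, giving severity-graded degree |
| fpet_noise_sd | 0.5 | ≈ 10 % voxel-level noise on late frames |
| fluct_amp | 2.0 | fluctuation ≈ 3 % of late-frame signal |
| uptake_cv | 0.1 | ≈ 10 % across-subject uptake variation |
| ar_coefficient | 0.4 | BOLD-like temporal smoothness |
| roi_coherent_frac | 0.5 | see two-channel split above |
| severity_noise_sd | 4.5 | targets ρ ≈ 0.5–0.7 at n = 12 |

Randomness uses `numpy.random.default_rng([seed, subject_index, stream])`,
so any subject regenerates bit-identically from the master seed alone.

## Preprocessing

The last 30 of 90 fPET frames are retained (early constant-infusion frames
carry little signal), each retained frame is divided by its in-mask global
mean (making the per-frame mean exactly 1, hence idempotent), and region
series are unweighted voxel means over atlas parcels. The static (sPET)
image is the voxelwise sum over the *retained* window by default — the
same data window both PET constructions see; summing all 90 frames is
available by configuration. fMRI series pass through the same extraction
but are not globally normalized by default. Inputs must be pre-aligned;
no motion correction, smoothing or resampling is performed.

## Group spatial ICA

Subjects' normalized series are voxelwise temporally demeaned per subject
and concatenated in time. Without the demeaning step every subject's
static uptake map enters as a constant-in-time spatial direction whose
variance dwarfs the temporal networks; with it, the decomposition sees
only fluctuations. The concatenated matrix is PCA-whitened to exactly
`n_components` (default 10) spatial components in one reduction stage,
using an exact Gram-matrix eigendecomposition on the smaller side of the
matrix, then rotated by FastICA (deflation, logcosh contrast, tol 1e-6,
up to 5 seeded restarts on non-convergence, error afterwards). Maps are
z-scored over in-mask voxels and sign-fixed to non-negative spatial
skewness, which removes the ICA sign ambiguity deterministically.

A component is thresholded one-sided at z = 1.5 (z = 1.0 for the
sensorimotor component, so all cortical clusters survive) and parcellated:
regions with ≥ `min_fraction` (default 0.1) of their voxels inside the
mask form the network region set. The sensorimotor component is selected
by maximal absolute spatial correlation with a template (by default the
planted motor unit's indicator; with real data, a user-supplied region
list). Two-stage subject-level PCA reduction, ICASSO-style stability
analysis and back-reconstruction are deliberately not implemented.

## Connectivity and significance

Pearson correlations are Fisher-transformed with r clipped to
±(1 − 1e-7) so degenerate duplicates stay finite. Subject-level edge
p-values use the correlation t test (frames − 2 df); group-level
time-series results are mean Fisher-z with a per-edge two-sided one-sample
t test across subjects; sPET uses the correlation t test across subjects
(n − 2 df) since no subject dimension remains. Degenerate cases follow
documented conventions: a zero-variance region's edges are recorded as
r = 0, p = 1 and flagged (subject level) or raised as an error (group
static covariance, where silent flagging would distort the matrix); a
zero-variance one-sample t is p = 0 for a nonzero mean and p = 1
otherwise, flagged. Adjacency keeps the sign of each edge with p < alpha
(default 0.05, uncorrected — multiplicity is handled downstream at the
unit-degree level, not per edge).

## Connectomes, degree and statistics

Common edges require significance in both modalities *and* sign
agreement; Dice counts upper-triangle edges only, restricted to positive
edges by default (`reference="all"` is available), and the 0/0 case is
defined as 0 and flagged. Nodal degree counts nonzero off-diagonal
entries per row; per-unit aggregation is a sum by default (mean
available). Group comparisons of unit degree treat member regions'
degrees as the samples, use the Shapiro-gated two-sample test (Welch t if
both samples pass normality at 0.05, tie-corrected two-sided Mann-Whitney
U otherwise; constant samples fail the gate), and correct across the
units of one connectome with Bonferroni–Holm. The Welch default for the t
branch reflects that printed cohort-table t values match the
unequal-variance statistic; the pooled variant is available by flag.

The conditional-MLE odds ratio solves E[X | ψ] = x₁₁ under Fisher's
noncentral hypergeometric model by bisection on log ψ (tolerance 1e-10),
with Fisher's exact two-sided p; boundary tables yield 0/∞ with a flag.
Spearman severity correlations use tie-corrected ranks with an exact
permutation p for n ≤ 9 without ties (cohorts here are small) and the t
approximation otherwise. Cross-modal strength association is the Pearson
correlation and OLS fit between two modalities' upper-triangle Fisher-z
values.

## What passing tests do and do not show

The generator emulates the *statistical skeleton* of a multimodal cohort:
ramping uptake with network-structured fluctuations, across-subject uptake
covariance, autocorrelated BOLD-like series, a planted motor-unit excess
in patients, and severity coupled to motor connectivity. It does not
emulate pharmacokinetics, scanner physics, attenuation, motion, spatial
smoothing (irrelevant at parcel scale), physiological confounds
(cardiac/respiratory), or anatomically realistic parcel geometry. Passing
recovery tests therefore shows the *estimators and pipeline plumbing* are
correct and that effects of the planted size are detectable at study-sized
n — not that the pipeline would detect effects in any particular real
acquisition.

Problem sizes in tests and the acceptance script (30 regions, 12/13
subjects, 200 null replicates, 5 fixture seeds) are the package's default
study conditions; the acceptance run completes in well under a minute on
one CPU.

## Known limitations

- Global-mean normalization induces a common-mode anticorrelation among
  null pairs (visible as negative group-level fPET edges), as it does in
  real global-signal-normalized data; the sign-consistency rule of the
  multimodal intersection removes most of it.
- The sPET construction at n = 12 subjects has wide sampling variability
  (s.e. of r ≈ 0.2), so planted sPET edges are recovered stochastically,
  not deterministically.
- Unit-degree group tests treat member-region degrees as exchangeable
  samples; degrees within a planted community co-fluctuate, which the
  type-I simulation shows is conservative rather than anticonservative
  under these conditions.
- ICA component selection against a template presumes a labelled
  template/region set; fully unsupervised component labelling is out of
  scope.
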
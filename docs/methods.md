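# Methods

This note documents the models and procedures implemented in
`brainstemnm`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
make runs reproducible.

## Image conventions

All volumes are 3-D scalar arrays with voxel sizes in mm; the third axis
is the axial slice axis, ordered inferior → superior. ROI masks are sets
of 0-based `(i, j, k)` indices bound to a named grid; every operation
checks grid identity and bounds. NaN voxels are rejected at load time
because every downstream quantity is an intensity comparison or mean —
silently masking NaNs would move thresholds. Wherever a standard
deviation is computed (background ROIs, normative residuals, generator
checks) the unbiased (n − 1) estimator is used.

The neuromelanin slabs default to 13 slices with 2.8 mm effective slice
spacing (2.5 mm slice thickness + 0.3 mm interslice gap) and ≈0.43 mm
in-plane voxels (220 mm field of view / 512 matrix); both are
configuration values, not constants, since acquisition and analysis
grids can differ.

## SN neuromelanin signal volume

The background reference is the cerebral peduncle ROI, pooled across
hemispheres into a single mean/SD per subject: one threshold
`μ + k·σ` (default k = 3.25) serves all four SN subregions. Exceedance
is strict (`>`): a voxel exactly at the threshold does not count. This
choice is arbitrary at measure-zero events but is fixed for determinism.
Side-specific backgrounds were considered and not implemented: a single
pooled peduncle statistic is the simpler model and per-side referencing
would double the variance of the threshold estimate on half the voxels.

The module reports the four regional volumes, the anterior and posterior
left/right averages, the mean of all four regions (`avg_sn`, used for
cross-measure correlations) and `total_sn = avg_aSN + avg_pSN`, the
combined anterior+posterior volume whose control calibration value is
111.9 mm³ in the synthetic defaults.

The estimator is a pure per-voxel comparison, so it equals a brute-force
oracle on any input, is invariant to global intensity scaling (threshold
and intensities scale together), and is non-increasing in k.

## LC neuromelanin contrast

The slice-to-slice intensity correction is multiplicative: each slice
touched by the pons reference ROI is rescaled so its per-slice reference
mean equals the grand reference mean. A multiplicative correction is the
only choice that preserves within-slice intensity *ratios*, hence LC
contrast, by construction.

The search ROI is partitioned along its occupied slice range into three
contiguous blocks, rostral (superior) first; when the span is not
divisible by three the extra slices go to the rostral-most blocks
(e.g. 7 slices → 3/2/2). "Equal parts" is undefined for non-divisible
spans, so the remainder rule is fixed and documented rather than left to
chance.

Cluster extraction is greedy: seed at the ROI's brightest voxel, then
repeatedly add the brightest ROI voxel adjacent (26-neighbourhood by
default) to the current set until five voxels are collected. Ties break
toward the lowest `(i, j, k)` index, making the result deterministic.
Greedy growth is not globally optimal in general; the test suite
enumerates *all* connected 5-subsets on small fixtures and confirms that
greedy attains the global optimum whenever a dominant connected cluster
exists — the regime the measure is designed for. An ROI whose connected
components are all smaller than five voxels is an error, not a padded
estimate.

Contrast is `(Ī_cluster − Ī_pons)/Ī_pons` against a single pooled pons
background per subject; negative values are legitimate (the five
brightest voxels of a degenerated section can fall below the pons mean).
Left and right contrasts are averaged per section.

## NODDI ROI summaries

NODDI model fitting is upstream and out of scope; the module consumes
the three parameter maps (all fractions in [0, 1], enforced) and takes
arithmetic means over 8-voxel anterior/posterior SN ROIs per side, plus
side averages. A size mismatch against the configured 8 voxels fails by
default and can be downgraded to a warning.

## DAT-SPECT

SBR and the normative Z are exact formulas. The proprietary scanner
normative database is replaced by a declared linear-in-age,
sex-stratified model per ROI (intercept, age slope, residual SD),
configurable as JSON/YAML. The synthetic default uses intercepts
4.2/3.6/4.6 (striatum/putamen/caudate, male; +0.2 female), age slope
−0.02 SBR/year (−0.022 caudate) and residual SDs 0.30–0.35 — values in
the range of published normative DAT studies; only the *structure* of
the model carries weight, since Z is computed against whatever model is
supplied. Abnormality is strictly `Z < −2`; a subject at exactly −2 is
not flagged. "Most affected putamen" is the putamen with the lower Z,
ties to the left. Missing scans propagate as missing and correlation
routines drop incomplete pairs pairwise.

## Permutation ANCOVA

The design is intercept + age + sex (binary) + two group dummies against
a reference level; the omnibus statistic is the partial F of the nested
comparison (full vs covariates-only), df = (2, n − 5). The permutation
p-value uses the Freedman–Lane scheme: residuals of the reduced
(covariates-only) model are permuted, the reduced fit is added back, the
full and reduced models are refit to the reconstructed outcome, and the
p-value is the tail proportion with the +1 smoothing correction,
p = (1 + #{F* ≥ F}) / (n_perm + 1). Full-outcome permutation ("manly")
is available as a config alternative. Permutations are generated from a
mandatory integer seed via `numpy.random.default_rng`; results are
bit-reproducible given (seed, n_perm).

Post hoc inference runs all six ordered pairwise contrasts (A > B) as
one-tailed t-type contrasts on the adjusted group coefficients, with
one-tailed permutation p-values from the same permutation set and
Bonferroni ×6 correction capped at 1 (family corrected α = 0.00833 at
α = 0.05). Covariates are always retained in the post hoc model — the
alternative of pruning non-significant covariates introduces a
data-dependent model choice without changing the estimand, so the
deterministic option is the default.

Validity is tested directly: under a simulated global null with
covariate effects present, the omnibus rejection rate at α = 0.05 over
500 replicates must fall inside the 95% binomial band, and on
exchangeable Gaussian data the permutation p agrees with the parametric
F p to < 0.02 at 10 000 permutations.

Correlation families are Pearson r with BH step-up FDR over exactly the
listed family (pairwise deletion, df = n − 2). Multiple-testing
corrections are applied within an outcome's six contrasts, not across
outcomes.

## Normative w-scores

For each configured outcome an OLS model of outcome on age + sex is
fitted in controls only; w = (observed − predicted)/σ_resid with σ_resid
the (n − 1) SD of the control residuals. With this matched estimator the
control w-scores have mean exactly 0 (residuals with an intercept sum to
zero) and SD exactly 1, so w behaves as a standard normal deviate in the
normative population and the upper-tail percentile is 100·(1 − Φ(w)).
The denominator is the residual *SD*, not the residual variance: only
the SD denominator yields the mean-0/SD-1 property and the standard
normal percentile correspondences (1.96 → 2.5th, 1.65 → 5th,
1.04 → 15th).

Direction of abnormality is per-outcome configuration: for neuromelanin
volume and LC contrast, lower values are worse and the severity index is
−w; for free-water fraction, higher is worse and severity is +w. The
default w-score outcomes are posterior-SN FWF, posterior-SN neuromelanin
volume and middle-LC contrast.

## Synthetic data generator

The generator's job is to produce inputs with *known ground truth* under
the cohort conditions the analysis assumes, not to simulate MR physics.
Outcomes are drawn at the subject level and images are rendered to
match.

**Cohort.** Default group sizes 18/14/18 (HC/iRBD/PD) with fixed sex
counts 7M/11F, 10M/4F, 11M/7F and truncated-normal ages on 45–80 years
(means/SDs 63.1/11.0, 65.1/7.9, 63.1/9.0). Each of the eleven imaging
outcomes has group-specific means/SDs matching the published cohort
calibration. Cross-measure structure is placed on subject-level latent
factors — one factor per metric (neuromelanin, NDI, FWF, ODI, motor
score), shared by the anterior and posterior subregions of that metric,
plus independent factors per LC section — with default correlations
nm–NDI −0.610, NDI–FWF 0.417, NDI–ODI 0.494, nm–motor −0.404, FWF–motor
0.486. That target matrix is slightly indefinite and is repaired by
eigenvalue clipping (warned once); the repair moves the strongest entry
from −0.610 to ≈ −0.59. Draws violating physical bounds (volumes ≥ 0,
fractions in [0, 1], contrasts > −1) are redrawn whole-subject, which
preserves the correlation structure within the accepted region; the
induced mean shift is negligible for control calibrations and at most
~1 mm³ for the smallest patient volume distribution. One rostral-LC
control SD is printed inconsistently in the source material
(0.331, an order of magnitude above every neighbouring SD); the
generator uses 0.0331.

**Images.** The SN slab plants `round(V_true / v_voxel)` hyperintense
voxels per subregion at +10 background SDs over a Gaussian peduncle
background (default μ 100, σ 5) — quantization to whole voxels bounds
the planting error at half a voxel (≈0.26 mm³). The pons slab plants a
five-voxel plus-shaped cluster per section and side at
`μ_pons·(1 + c_true)`; the surrounding search-ROI tissue is rendered at
97% of the pons intensity so the planted cluster remains the brightest
connected set even for near-zero or mildly negative contrasts, and a
per-slice multiplicative gain perturbation (σ 2%) is applied for the
slice correction to remove. NODDI maps hold region-true values plus
voxel noise (σ 0.02), clipped to [0, 1]. Noise is Gaussian throughout;
Rician magnitude noise, motion, partial-volume effects and registration
error are *not* emulated — so passing recovery tests demonstrate
estimator correctness under the stated noise model, not robustness to
real-world acquisition artefacts.

**DAT.** Count densities are constructed backwards from planted
normative Z values (abnormal iRBD subjects drawn in (−3.3, −2.1),
normals clear of the boundary), so flag counts are exactly recoverable;
one iRBD subject is unscanned by default to exercise missingness.

Everything is driven by `numpy` `SeedSequence` children per subject:
equal seeds give byte-identical tables and voxel-identical images.

## Problem sizes used in the checks

The validity and calibration suites run at desk scale: 100 rendered
control subjects for the SN and LC calibration-recovery checks (3-SE
acceptance bands of the calibration SDs, 33.49 mm³ and 0.0273), 500
null replicates at 500 permutations for the type-I calibration, 10 000
permutations for the parametric-agreement check, and exhaustive
connected-subset enumeration on 18-voxel ROIs for the greedy-cluster
optimality check. The acceptance script uses 200 controls for the
w-score identities and 120 rendered controls for the LC calibration.

## Known limitations

- Registration, segmentation, ROI drawing and NODDI fitting are inputs,
  not algorithms; errors in those upstream steps are outside the model.
- The greedy cluster extractor is only provably optimal in the
  dominant-cluster regime; at contrast-to-noise near zero it inherits
  the upward max-statistic bias intrinsic to brightest-voxel measures.
- The permutation GLM assumes exchangeable errors under the reduced
  model; heteroscedastic groups are flagged by Levene's test but not
  modelled.
- The synthetic normative DAT model is declared, not estimated from a
  real normal database; Z-scores are only as meaningful as the supplied
  model.
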
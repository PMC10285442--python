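# Methods

This note documents the generative model, the analysis procedures, the
numerical choices, and what the synthetic design can and cannot show.

## Cohort generative model

Subjects carry three standardized latent traits — spider fear, snake fear,
disgust propensity — drawn per subject from a trivariate normal with unit
variances. The spider component's mean is shifted between groups
(`trait_means`, default phobic 3.0 vs control 0.0 SD); snake and disgust
traits correlate with the full spider trait (default r = 0.3 each), so the
phobic group is also mildly elevated on snake fear and disgust, as extreme
spider-fear groups are in practice.

**Recruitment truncation.** The emulated study *screened* its groups: an
interview plus questionnaire made the groups disjoint on spider fear. The
generator reproduces this with `trait_truncation = (1.8, 0.8)`: phobic
draws below 1.8 and control draws above 0.8 are redrawn. Under the item
model these bounds correspond to SPQ ≈ 13 (phobic floor) and SPQ ≈ 4–5
(control ceiling), the instruments' published group ranges. Set
`trait_truncation=None` for a continuous-trait (unscreened) cohort, which
is the right configuration for null designs with no group separation and
for studying how much of the observed correlations is induced by the
extreme-groups split.

**Observables.**

* *SPQ/SNAQ items*: logistic item-response model; the probability of the
  scored (fearful) response to item i is expit(a·(trait − b_i)) with slope
  a = 1.7 and difficulties b_i spread evenly (SPQ 0.9–3.1, SNAQ 1.4–3.8).
  Reverse-keyed items are stored in the raw (flipped) direction so scoring
  must undo them. Calibrated once by Monte Carlo so group mean SPQ lands in
  the low twenties (phobic) vs low single digits (control), and SNAQ means
  stay low (~1–4) in both groups. SNAQ vectors scoring above 17 are redrawn
  — the study's snake-fear inclusion cutoff.
* *DS-R*: each of the 25 elicitor items is round(clip(base_i + 0.6·disgust
  + N(0, 0.8))) on 0–4; the two catch items are answered with the keyed
  attention values. The item→factor map for subscales is a synthetic
  default (the instrument's real assignment is not encoded here).
* *BAT*: completed steps = #{k : trait + N(0, 0.8) < c_k} with cut-points
  c = (1.9, 2.7, 3.3, 3.8, 4.2, 4.6, 5.0), giving phobic means ≈ 4.3–4.7
  with the characteristic split between subjects who stop after uncovering
  the terrarium and those who touch the spider, and control means ≈ 6.9.
* *Interview*: six questions, each a steep logistic readout of the spider
  trait (slope 10, midpoint 1.5). Because group membership in the emulated
  study was *defined* by the interview (≥ 5 fearful answers for phobics,
  0 for controls), draws inconsistent with the recruited group are redrawn;
  a deep-tail subject whose rejection loop exhausts is set to the
  group-consistent extreme. This is truncation, not noise suppression.
* *Ratings*: per picture, round(clip(µ_c + w_c·spider + w'_c·snake + ε,
  1, 7)) with 40 pictures per category. Spider categories load on the
  spider trait (tarantula 1.5, daddy-long-legs 1.0), snake/lizard on the
  snake trait (1.2 / 0.5), beetles/leaves on essentially nothing; rating
  noise SD 0.8.

All randomness flows from `EffectConfig.seed`; a fixed config reproduces
the cohort bitwise.

## fMRI design and simulation

Each session holds 8 blocks per condition × 10 pictures × 1.5 s at
TR 1.5 s → 32 blocks, 480 s, 320 volumes. Block order is pseudorandom with
exact carryover balance *on the circular adjacency count*: a seeded
Eulerian circuit through the condition-transition multigraph makes every
ordered pair of conditions (including same-condition repeats when
blocks/condition is a multiple of 4; the 12 distinct pairs when a multiple
of 3) equally frequent. A strictly linear sequence of 32 blocks cannot
balance 12 ordered pairs over 31 adjacencies, so circular balance is the
exact property we construct and test; other block counts fall back to a
seeded permutation unless `require_balance=True`.

Regressors are condition boxcars convolved with a canonical double-gamma
HRF (response peak 6 s, undershoot 16 s at ratio 1/6, peak-normalized),
plus an intercept and Legendre drift terms (default order 1). The
simulated brain is a 12×12×12 grid of 3 mm voxels with a 3×3×3 planted
spider-responsive block; this desk scale keeps a full 61-subject,
two-session experiment under ~2 s while leaving > 1,700 voxels for the
multiple-comparison problem. Noise is temporally AR(1) (coefficient 0.3,
marginal SD 1.0 in arbitrary %-signal-change units), independent across
voxels; t-statistics are invariant to the overall signal scale. Motion,
slice-timing, and bias-field artifacts are out of scope; optional Gaussian
smoothing (FWHM in mm, σ = FWHM/(2√(2 ln 2))) is off by default so that
voxel noise stays independent, which the FWE calibration tests rely on.

## GLM and SFI

First-level fits are voxelwise OLS without pre-whitening; with AR(1) noise
the nominal residual df is slightly optimistic, a documented limitation
that cancels out of the rank-based downstream analyses. Zero-variance
voxels get t = 0 when the contrast effect is zero and a signed infinite
sentinel otherwise; sentinels are excluded from ROI candidacy.

The group map is a one-sample t-test across phobic subjects'
spider>beetle *contrast estimates* from the fear session (a first-level
t-value pathway is available via `group_pathway="tvalue"`). The ROI is
defined at FWE α = 0.05, one-sided, Bonferroni over the finite-t voxels by
default (exactly reproducible); sign-flipping max-t permutation is the
closer analogue of common neuroimaging practice and is provided as an
option. The ROI uses phobic subjects only (`phobics_only_roi=False` pools
everyone). The SFI is the arithmetic mean of the subject's spider-session
first-level t-values inside the ROI; averaging betas instead is exposed
for sensitivity analysis through the contrast-estimate maps. An empty ROI
raises rather than silently returning zero, since the SFI is undefined
without a mask. Because the ROI comes from the fear session and the SFI
from the spider session, selection bias does not leak into the index:
under a null spider session the SFI distribution is centered at zero
(tested).

SFI magnitudes here are mean t-statistics and scale with the planted gain
and session length; they are not comparable to any particular scanner's
units.

## Statistical analyses

* **RDA** (authored here, not wrapped): center Y and X, regress Y on X,
  take the SVD of the fitted values. Eigenvalue k is the fitted variance
  along axis k (divisor n − 1); explained proportion is the fitted-to-total
  variance ratio. Scaling 1 site scores are Ŷ·V; scaling 2 multiplies
  response loadings by √λ. Predictors are standardized by default (affects
  biplot arrows only — explained variance is invariant to affine predictor
  rescaling, which is tested). Collinear predictors are dropped with a
  warning.
* **Sequential permutation tests**: terms enter in the stated order; each
  term's pseudo-F is its added constrained sum of squares over the
  full-model residual mean square (df_res = n − 1 − m). The null permutes
  the *reduced-model residuals* (free row permutation available);
  p = (1 + #{F* ≥ F})/(1 + n_perm). For the first term this is exact
  permutation; for later terms it is the standard residual-permutation
  approximation. Type-I error is calibrated in the test suite (500 null
  simulations at 199 permutations).
* **Linear-model reduction**: AIC = n·ln(RSS/n) + 2(k + 1); backward
  stepwise by default, exhaustive subsets for ≤ 12 candidates. RSS is
  floored at 10⁻¹² of the total SS so exact fits are compared by parsimony
  rather than by the logarithm of rounding error. Reported per-term F
  statistics are partial (drop-one) F tests of the selected model.
* **Discriminant analysis**: two-class LDA with pooled within-group
  covariance (scikit-learn's implementation behind the package surface),
  reported as a resubstitution confusion matrix — the apparent-accuracy
  convention of the emulated analyses — with leave-one-out as an option,
  plus per-variable one-way ANOVA F statistics ranking univariate
  discriminating power. A shrinkage fallback handles singular pooled
  covariances.
* **Spearman correlation**: scipy's midrank implementation; p from the
  t-approximation, or the exact n! permutation distribution for n ≤ 10.

The package is a library, not a shell tool: `run_study` plus the
importable estimators are the intended entry points, and
`scripts/acceptance.py` is the reproducible end-to-end run.

## What the synthetic design does and does not show

Passing tests demonstrate that the pipeline recovers planted structure
under its own generative assumptions: monotone item responses, linear BOLD
superposition, AR(1) voxel noise, and an extreme-groups recruitment. They
do not validate the instruments on humans, nor the SFI against real
scanner data with motion, physiological noise, spatially correlated
fields, or preprocessing interactions. The perfect discriminant separation
reported by the acceptance run is a property of screened extreme groups
with strong rating effects — with `trait_truncation=None` the groups
overlap and accuracy drops below 100%, which is the realistic behavior for
unscreened samples.

## Degenerate inputs and tie-breaks

Rank-deficient design matrices, all-zero contrasts, empty ROIs, constant
vectors in Spearman, non-prefix BAT step patterns, and out-of-range DS-R
responses all raise `ValueError` rather than propagating NaNs. Likert
ratings round half to even (numpy `rint`) before clipping to 1–7. BAT
score 0 (refusing to enter) is permitted even though the emulated scale
starts at 1; the interview classifier requires exactly six answers.
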
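# Methods

## The model

Activity-flow mapping treats a region's task-evoked activation as the
propagation of other regions' activations over the brain's intrinsic
functional network. For a held-out target parcel *j* and task condition
*c*,

    FlowAct_j,c = Σ_{i ∈ sources(j)} Act_i,c · FC_ij

where `Act_i,c` is the source parcel's GLM amplitude and `FC_ij` is the
resting-state functional connectivity between source and target. The model
is linear and one-step: no recurrence, no nonlinearity. Its substantive
claim is that if distributed propagation shapes local responses, the
generated activations should reproduce both the magnitude pattern and the
*selectivity* of the actual responses — here, the selectivity of the
cortical convergence circuit (CCC: bilateral V1, frontal eye field,
supplementary/cingulate eye field, anterior intraparietal area) for
convergence motor demands (VM task) over matched sensory stimulation (VS
task).

Two derived statistics carry the inference:

* **Vergence specificity** `VM̄ / VS̄` — the ratio of mean VM-condition to
  mean VS-condition activation after per-parcel min–max normalization
  (each parcel's 8-condition profile is rescaled by the *actual* profile's
  min/max; generated profiles use the same constants and are not clamped).
  Null value 1.
* **Distributed contribution** `100 · spec_generated / spec_actual` — the
  share of actual specificity reproduced by the generated (purely
  distributed) activations. Null reference 50%.

## Source policies

All headline analyses hold out the entire 8-parcel circuit: when any
parcel's activation is generated, *all* CCC parcels are removed from the
source set, so functionally related regions cannot leak information into
each other's generation. Variants implemented: target-only holdout, an
additional 10-mm spatial exclusion radius (strict `<` on the supplied
distance matrix; surface geometry is out of scope), network-restricted
submodels (VIS-CON-DAN, VIS-CON, VIS-DAN, VIS-Only, DAN-Only), a
network-partitioned decomposition whose 12 components sum exactly to the
full model, a second within-circuit flow step applied to the generated
activations (only the target held out, since a full-circuit holdout is
impossible inside the circuit), a V1-initiated model (mean-centered V1
activations as the only sources; each V1 is generated from the
contralateral V1), and matched-size random subnetworks.

## Estimation

**Denoising** is per-run OLS residualization: drop the first 5 resting
frames, then remove intercept, linear trend, 24 motion regressors (6
parameters, derivatives, quadratics of both), 20 physiological regressors
(5 components, derivatives, quadratics), and — for rest only — one spike
regressor per frame with frame-wise displacement > 0.25 mm (strict;
displacement is the RMS frame-to-frame change of the six parameters, frame
0 set to 0). Task runs rely on the 44 confounds without spike regressors.
Detrending is first-order; no prewhitening — betas are used as point
amplitude estimates only.

**GLM**: condition regressors are boxcars convolved with the canonical
double-gamma HRF (response peak 6 s, undershoot 16 s, unit dispersions,
undershoot ratio 1/6, 32 s support, peak-normalized), built on a 16×
oversampled grid and sampled at TR = 2 s. The two VM runs are concatenated
after denoising with per-run intercepts. The two-step procedure
(denoise, then fit the task GLM on residuals) is statistically less
efficient than a joint model but keeps the denoised series reusable for
connectivity estimation and keeps each stage independently testable.

**Functional connectivity** is regularized partial correlation by graphical
lasso. Series are standardized first (the penalty is then scale-free); the
L1 penalty is selected by held-out Gaussian log-likelihood over a 20-value
log-spaced grid spanning two decades below the empirical maximum absolute
off-diagonal correlation, with 5 contiguous-block (unshuffled) folds over
timepoints to respect temporal autocorrelation. The precision matrix is
converted to partial correlation `-P_ij/√(P_ii·P_jj)` with a zeroed
diagonal. Pearson correlation is retained as the field-standard comparison
estimator.

**Inference** uses sign-flip max-T permutation tests (one-sample and
paired, upper-tailed). The corrected p-value is `(b+1)/(n_perm+1)`; the
`b/n_perm` convention (floor 0.00001 at 100,000 permutations) is reported
alongside. A variable is significant iff its observed t exceeds the
(1−α) quantile of the max-null. Families are explicit per analysis:
2 hemispheres for specificity/contribution, 12 networks for contribution
contrasts, all 132 ordered network pairs for ranking, and the non-circuit
parcels for parcel-level contrasts. Constant-zero data (e.g., a paired
test of identical inputs) gives t = 0 rather than an error; constant
nonzero data raises a zero-variance error. Outliers in specificity are
flagged by `|x − median| > 5 · 1.4826 · MAD`, unioned over actual and
generated indices, per hemisphere independently; when MAD is 0 nothing is
flagged and a warning is issued. Degenerate normalizations and
non-positive VS means are excluded, not imputed.

**Dominance analysis** decomposes the regression of the actual circuit
response profile (4 parcels × 8 conditions = 32 observations per subject
and hemisphere) on the 12 network-partitioned generated components.
General dominance is used — each predictor's incremental R² is averaged
within subset sizes and then across sizes — because this size-conditional
weighting is the Shapley value of the R² game and therefore sums *exactly*
to the full-model R²; a plain average over all subsets would not. All
2¹² − 1 = 4,095 nonempty subsets are enumerated (including the full set;
enumerating only sizes 1–11 would break the sum identity). Intercepts are
included in every subset fit; rank-deficient subsets fall back to
least-norm fits with a warning, which leaves the sum identity intact.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the physiology of BOLD:

* **Parcellation**: P parcels (default 360; reduced test scale 60) split
  evenly over the 12 networks, parcels alternating hemispheres; 8 CCC
  parcels placed per hemisphere as (VIS1, CON, CON, DAN). Distances come
  from a uniform 3-D embedding per hemisphere with a 140-mm
  cross-hemisphere offset.
* **Ground-truth connectivity**: a sparse precision matrix with dense,
  strong within-network blocks (default density 0.6, partial-correlation
  strengths 0.4–0.8 before diagonal loading), sparse weak between-network
  edges (density 0.02), 90% positive edges, and planted strong edges from
  each CCC parcel to same-hemisphere VIS2 (and, weaker, DAN) parcels —
  the routing whose recovery the network-ranking analysis checks. SPD is
  enforced by diagonal-dominance loading; the covariance is rescaled to
  correlation form (which leaves partial correlations unchanged).
* **Rest**: a stationary AR(1) process (coefficient 0.3) whose innovation
  covariance is scaled so the latent stationary covariance equals the
  ground truth, plus white observation noise (sd 0.1). Default length 150
  TRs at TR = 2 s, matching the acquisition protocol the analysis
  targets; the connectivity-quality and parameter-recovery suites use 600
  frames at P = 60, the regime in which the graphical-lasso estimand is
  well conditioned at desk scale.
* **Designs**: VM 5×19 s + 5×18 s blocks over 208 TRs (two runs), VS
  5×22 + 5×18 over 208, SM 5×24 + 5×24 over 208, FT 3×20 + 3×20 over 92;
  block types alternate and rest gaps are spaced evenly to fill the
  printed run lengths (exact gap placement is a free choice; even spacing
  was chosen for reproducibility).
* **Task runs**: HRF-convolved design times planted betas, plus loadings
  on the 44 standardized confounds, plus AR(1) observation noise. Motion
  is a random walk with occasional jumps (rate 0.03/frame) calibrated to
  exceed the 0.25-mm spike threshold, so spike handling is exercised.

### Planting distributed structure

Condition profiles are anchored so that the weakest condition (FT-slow)
sits at zero; min–max normalization, which subtracts the profile minimum,
then preserves VM/VS ratios in expectation. Non-CCC parcels share a
profile shape with VM/VS ratio λρ, scaled by network amplitudes (VIS2 3.0,
DAN 2.0, VIS1 1.5, others 0.8). Each CCC parcel mixes

    β_ccc = λ · flow + (1−λ) · local + noise

where `flow` is the true-connectivity-weighted sum of the non-CCC betas
(carrying specificity λρ) and `local` is a structured profile with ratio
ρ(1+λ) plus an i.i.d. component orthogonalized against the flow. The
λ-weighted mixture then has actual specificity exactly ρ and
generated/actual ratio exactly λ in expectation, so the distributed
contribution estimand equals 100·λ by construction. A purely unstructured
(zero-mean, flow-orthogonal) local component cannot plant a contribution
below 100%: the actual specificity would converge to the flow's and the
contribution to 100% for every λ. The structured local term is therefore
what makes λ identifiable from the contribution statistic.

Defaults plant λ = 0.75 and ρ = 1.5, i.e. a distributed contribution of
75% and a clearly super-null specificity — the qualitative regime the
analysis is designed to detect (contribution above 50%, specificity above
1, VIS2-then-DAN routing).

### What the generator does not emulate

Voxel-level structure, hemodynamic nonlinearity, scanner drift beyond a
linear trend, spatially correlated noise (so the 10-mm exclusion control
changes little on synthetic data), physiological rhythms (confounds are
generic AR series), and between-subject variation in connectivity (all
subjects share one ground-truth precision; only activations and noise vary
by subject). Passing tests therefore demonstrate correctness of the
estimation machinery and identifiability of the planted parameters under
the stated assumptions — not robustness to real-fMRI artifact structure.

## Study scales and numerical choices

Network rankings are computed per hemisphere (as the analysis reports
them) and additionally at cohort level, with each subject's contributions
averaged over hemispheres before ranking. The cohort-level ranking is the
statistic used for planted-routing recovery checks: both hemispheres share
the planted routing, and pooling resolves the occasional within-hemisphere
10–10 pairwise-win ties that the mean-t tie-break would otherwise decide.

Parameter-recovery and reliability checks run 20 independent cohorts at
P = 60, n = 24 subjects, T_rest = 600, n_perm = 1,000, with a reduced
3-fold / 6-penalty connectivity cross-validation; the repeated-session
comparison uses the first 5 cohorts. These sizes were chosen so a full
study completes in minutes on one CPU while every estimator stays in its
well-conditioned regime; the permutation default of 100,000 used for
headline inference is configurable everywhere.

Tolerances: flow-term and network-partition conservation are exact linear
identities (tested at 1e−10); dominance sum-to-full at 1e−8; generative
identity (λ = 1, zero noise, truth connectivity) at 1e−8. Ties in network
ranking are broken by mean pairwise t. The minimum attainable corrected
p-value is 1/(n_perm+1).

## Known limitations

* The two-step GLM (denoise, then fit) discards the efficiency of a joint
  model and can bias betas when task regressors correlate with confounds.
* One ground-truth network per cohort means between-subject FC variability
  is not modeled; session-reliability results are accordingly optimistic
  relative to real repeated scans.
* The contribution statistic is a ratio of ratios and degenerates when the
  normalized VS mean approaches zero; such records are excluded rather
  than stabilized, which can shrink the effective sample in
  weak-signal submodels.
* Whole-cortex accuracy benchmarks use condition-level (8-column) betas;
  run-level variants are not implemented.
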
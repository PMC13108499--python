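# vergeflow

Activity-flow mapping of binocular convergence fMRI: does the convergence
circuit's task response arise from local computation, or from activity
propagating over the brain's resting-state network?

`vergeflow` is for researchers who want a tested, reusable implementation
of the distributed activity-flow analysis of convergent eye movements —
functional connectivity estimation, task GLM, held-out generation of
circuit activations, vergence-specificity statistics, and network-level
contribution analysis — together with a synthetic-cohort generator whose
ground truth is known, so every stage can be validated without access to
raw scans.

## The model

A held-out target parcel *j*'s activation in condition *c* is generated as
the connectivity-weighted sum of all source parcels' actual activations:

    FlowAct_j,c = Σ_{i ∈ sources(j)} Act_i,c · FC_ij

with `Act` the GLM betas (8 task conditions: VM-many/few, VS-many/few,
SM-fast/slow, FT-fast/slow) and `FC` the regularized partial correlation
estimated per subject by cross-validated graphical lasso on denoised
resting series. All 8 parcels of the cortical convergence circuit (CCC —
bilateral V1, frontal eye field, supplementary/cingulate eye field,
anterior intraparietal area) are held out of every generation.

Two statistics quantify convergence selectivity:

* vergence specificity = VM̄ / VS̄ after per-parcel min–max normalization
  (null 1), and
* distributed contribution = 100 · generated specificity / actual
  specificity (null reference 50%): the share of the circuit's motor
  selectivity explained by distributed propagation alone.

Network-level machinery decomposes each generated activation into 12
network components (summing exactly to the full model), ranks networks by
pairwise max-T permutation tests, and apportions response-profile variance
by general dominance analysis over all 4,095 predictor subsets.

See `docs/methods.md` for the full model account, estimation choices and
the synthetic-cohort design.

## Worked example

Run the full pipeline on a simulated cohort (60 parcels, 8 subjects, two
resting sessions, planted distributed share λ = 0.75 and specificity
ρ = 1.5):

```bash
vergeflow run-all --seed 42 --subjects 8 --parcels 60 --out scratch/example
vergeflow report --report scratch/example/report.json
```

which prints (abridged):

```
Whole-model accuracy (n=8): r = 0.737, R^2 = 0.316, MAE = 0.149
CCC response profile (L): r = 0.951, R^2 = 0.788, MAE = 0.108
Vergence specificity (L, df = 7 after outlier removal): actual = 1.563 (t = 6.85***), generated = 1.151 (t = 2.50***)
Distributed contribution (L): 73.66% vs 50% reference (t = 77.89***)
Network ranking (L): VIS2, DAN, VIS1 lead (wins: {'VIS2': 11, 'DAN': 10, ...})
Dominance (L): full R^2 = 0.969 over 4095 subset models; top partial R^2: VIS2, DAN, VIS1
- DAN-Only: R^2 L = -1.042, R = -0.971
- V1-initiated: R^2 L = -2.187, R = -2.074
```

Reading the numbers: the generated activations correlate with the actual
ones across the whole cortex (r = 0.74) and reproduce the circuit's
8-condition response profile closely (r = 0.95). The actual specificity
recovers the planted ρ ≈ 1.5; the distributed contribution recovers the
planted λ ≈ 75% and is significantly above the 50% null, i.e. most of the
circuit's convergence selectivity is carried by distributed propagation.
The planted VIS2-then-DAN routing is recovered by both the pairwise
ranking and the dominance decomposition, and condensed submodels degrade
in the expected ladder, with the V1-initiated model explaining no variance
at all (negative R²). The second resting session reproduces the
session-1 results (same report, `Session 2` block).

The same stages are available piecewise (`simulate`, `glm`, `fc`,
`actflow`, `evaluate`, `networks`, `dominance`, `report`) over an on-disk
cohort directory, and as library functions (`vergeflow.actflow_generate`,
`vergeflow.fc_glasso`, ...).

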
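"""Reproducible simulation studies at reduced desk scale.

These runners execute the full estimation pipeline (simulate -> denoise ->
GLM -> graphical-lasso FC -> activity flow -> statistics) on cohorts whose
ground truth is known, so that the headline quantities of the analysis --
distributed contribution, planted specificity, network ranking, the
condensed-submodel ladder and repeated-session reliability -- can be
checked against what was planted.

The default study scale is P = 60 parcels, 24 subjects, 600 resting frames
and 1,000 permutations, with a 3-fold / 6-penalty connectivity
cross-validation; these sizes keep a 20-seed study within minutes on one
CPU while leaving every estimator in its well-conditioned regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actflow import SourcePolicy, actflow_generate
from .connectivity import fc_glasso
from .core import CONDITIONS, HEMISPHERES, ActivationMatrix, FCMatrix
from .evaluate import accuracy, apply_outlier_union, specificity_records
from .netstats import compare_submodels, network_flow_contributions, rank_networks
from .permtest import maxt_one_sample
from .preprocess import denoise, subject_activations
from .synth import SimConfig, simulate_cohort

__all__ = ["RecoverySeedResult", "run_recovery_seed", "recovery_study",
           "fwer_study", "subject_fc", "cohort_fcs"]


def subject_fc(ds, session: int = 1, folds: int = 3, alphas: int = 6) -> FCMatrix:
    """Denoise one rest session (drop 5 frames, spikes) and fit glasso FC."""
    conf = ds.rest_confounds[session]
    spikes = conf.fd > 0.25 if conf.fd is not None else None
    clean = denoise(ds.rest[session], conf, spikes=spikes, drop_initial=5)
    return fc_glasso(clean, folds=folds, alphas=alphas,
                     subject_id=ds.subject_id, session_id=str(session))


def cohort_fcs(cohort, session: int = 1, folds: int = 3,
               alphas: int = 6) -> dict[str, FCMatrix]:
    return {ds.subject_id: subject_fc(ds, session, folds, alphas)
            for ds in cohort.subjects}


@dataclass
class RecoverySeedResult:
    """Pipeline outputs for one seeded cohort."""

    seed: int
    contribution_mean: float                 # pooled over hemispheres
    spec_actual_mean: float
    sig_contribution: dict[str, bool]        # per hemisphere
    ranking: dict[str, list[str]]            # per hemisphere network order
    submodel_r2: dict[str, dict[str, float]]  # model -> hemisphere -> R^2
    whole_r_session1: float
    whole_r_session2: float | None = None


def run_recovery_seed(seed: int,
                      n_subjects: int = 24,
                      p: int = 60,
                      t_rest: int = 600,
                      lambda_distributed: float = 0.75,
                      specificity_ratio: float = 1.5,
                      n_perm: int = 1000,
                      alpha: float = 0.05,
                      fc_folds: int = 3,
                      fc_alphas: int = 6,
                      with_session2: bool = False,
                      with_submodels: bool = True) -> RecoverySeedResult:
    """Simulate one cohort and run the full estimation pipeline on it."""
    cfg = SimConfig(p=p, n_subjects=n_subjects, t_rest=t_rest,
                    lambda_distributed=lambda_distributed,
                    specificity_ratio=specificity_ratio,
                    n_rest_sessions=2 if with_session2 else 1,
                    seed=seed)
    cohort = simulate_cohort(cfg)
    parcels = cohort.parcels
    acts: dict[str, ActivationMatrix] = {
        ds.subject_id: subject_activations(ds, CONDITIONS)
        for ds in cohort.subjects}
    fcs = cohort_fcs(cohort, 1, fc_folds, fc_alphas)

    policy = SourcePolicy(mode="exclude_ccc")
    all_targets = np.arange(parcels.n_parcels)
    flows = {sid: actflow_generate(acts[sid], fcs[sid], all_targets, policy,
                                   parcels)
             for sid in acts}

    whole = accuracy([acts[s].betas for s in acts],
                     [flows[s].generated for s in acts])
    whole_r2 = None
    if with_session2:
        fcs2 = cohort_fcs(cohort, 2, fc_folds, fc_alphas)
        flows2 = {sid: actflow_generate(acts[sid], fcs2[sid], all_targets,
                                        policy, parcels)
                  for sid in acts}
        whole_r2 = accuracy([acts[s].betas for s in acts],
                            [flows2[s].generated for s in acts]).mean_r

    records = specificity_records(acts, flows, parcels)
    apply_outlier_union(records)
    kept = [r for r in records if r.valid and not r.outlier]
    contribution_mean = float(np.mean([r.contribution_pct for r in kept]))
    spec_actual_mean = float(np.mean([r.spec_actual for r in kept]))
    sig = {}
    for hemi in HEMISPHERES:
        vals = np.array([r.contribution_pct for r in kept
                         if r.hemisphere == hemi])
        res = maxt_one_sample(vals[:, None], mu0=50.0, n_perm=n_perm,
                              seed=seed + 7, alpha=alpha)
        sig[hemi] = bool(res.significant[0])

    contrib = network_flow_contributions(flows, parcels, scope="vm")
    ranking = {
        hemi: rank_networks(contrib.array(hemi), n_perm=n_perm,
                            seed=seed + 11, alpha=alpha).order
        for hemi in HEMISPHERES}
    # cohort-level ordering: subject contributions pooled over hemispheres
    pooled = 0.5 * (contrib.array("L") + contrib.array("R"))
    ranking["pooled"] = rank_networks(pooled, n_perm=n_perm, seed=seed + 11,
                                      alpha=alpha).order

    submodel_r2: dict[str, dict[str, float]] = {}
    if with_submodels:
        entries = compare_submodels(acts, fcs, parcels, n_perm=200,
                                    seed=seed + 13)
        submodel_r2 = {e.name: e.r2 for e in entries}

    return RecoverySeedResult(
        seed=seed,
        contribution_mean=contribution_mean,
        spec_actual_mean=spec_actual_mean,
        sig_contribution=sig,
        ranking=ranking,
        submodel_r2=submodel_r2,
        whole_r_session1=whole.mean_r,
        whole_r_session2=whole_r2,
    )


def recovery_study(master_seed: int = 0, n_seeds: int = 20,
                   n_session2_seeds: int = 5,
                   **kwargs) -> list[RecoverySeedResult]:
    """Run the recovery pipeline over independent seeded cohorts.

    Session-2 FC (the repeated-scan workflow) is evaluated on the first
    ``n_session2_seeds`` cohorts; every cohort yields contribution,
    specificity, ranking and submodel results.
    """
    seeds = [int(master_seed * 10_000 + 101 * k) % (2 ** 31 - 1)
             for k in range(n_seeds)]
    return [run_recovery_seed(s, with_session2=(k < n_session2_seeds),
                              **kwargs)
            for k, s in enumerate(seeds)]


def fwer_study(seed: int = 0, n_replicates: int = 500, n_subjects: int = 24,
               n_vars: int = 12, n_perm: int = 1000,
               alpha: float = 0.05) -> float:
    """Family-wise error rate of the max-T test under a global null.

    Each replicate draws standard-normal data and counts whether any
    variable's observed t exceeds the max-T threshold.
    """
    rng = np.random.default_rng(seed)
    fp = 0
    for rep in range(n_replicates):
        data = rng.standard_normal((n_subjects, n_vars))
        res = maxt_one_sample(data, mu0=0.0, n_perm=n_perm,
                              seed=int(rng.integers(2 ** 31)), alpha=alpha)
        if res.significant.any():
            fp += 1
    return fp / n_replicates
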
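"""Generator properties: parcellation, ground truth, rest, designs, planting."""

import numpy as np
import pytest

from vergeflow.core import CONDITIONS, FCMatrix, ValidationError
from vergeflow.actflow import SourcePolicy, actflow_generate
from vergeflow.evaluate import vergence_specificity
from vergeflow.preprocess import build_design_matrix, estimate_betas
from vergeflow.synth import (
    SimConfig,
    condition_profile,
    make_designs,
    make_ground_truth_fc,
    make_parcellation,
    make_task_activations,
    simulate_cohort,
    simulate_rest,
    simulate_task_runs,
)


class TestParcellation:
    def test_full_scale_layout(self):
        parcels, dist = make_parcellation(360, seed=0)
        assert parcels.n_parcels == 360
        assert parcels.ccc_indices.size == 8
        for hemi in "LR":
            nets = sorted(parcels.networks[parcels.ccc_indices_hemi(hemi)])
            assert nets == ["CON", "CON", "DAN", "VIS1"]
        # network sizes sum to P
        assert sum((parcels.networks == n).sum() for n in set(parcels.networks)) == 360

    def test_determinism(self):
        a, da = make_parcellation(60, seed=1)
        b, db = make_parcellation(60, seed=1)
        assert a.frame.equals(b.frame)
        assert np.array_equal(da.values, db.values)

    def test_distances_positive_off_diagonal(self):
        _, dist = make_parcellation(60, seed=1)
        off = dist.values[~np.eye(60, dtype=bool)]
        assert np.all(off > 0)

    def test_cross_hemisphere_distances_large(self):
        parcels, dist = make_parcellation(60, seed=2)
        cross = dist.values[np.ix_(parcels.hemispheres == "L",
                                   parcels.hemispheres == "R")]
        within = dist.values[np.ix_(parcels.hemispheres == "L",
                                    parcels.hemispheres == "L")]
        assert cross.min() > np.median(within)

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError):
            make_parcellation(20, seed=0)


class TestGroundTruth:
    def test_spd(self):
        parcels, _ = make_parcellation(60, seed=0)
        gt = make_ground_truth_fc(parcels, SimConfig(p=60, seed=0))
        assert np.linalg.eigvalsh(gt.precision).min() > 0

    def test_zero_density_gives_independence(self):
        parcels, _ = make_parcellation(60, seed=0)
        cfg = SimConfig(p=60, within_density=0.0, between_density=0.0,
                        ccc_boost_edges=0, seed=0)
        gt = make_ground_truth_fc(parcels, cfg)
        off = gt.true_partial_corr[~np.eye(60, dtype=bool)]
        assert np.abs(off).max() < 1e-12

    def test_chain_precision_partial_vs_marginal(self):
        # 3-parcel chain: edges (1,2) and (2,3) only. Analytically the
        # partial correlation of (1,3) is zero while the marginal
        # correlation of (1,3), the product of the chain links, is not.
        K = np.array([[1.0, -0.4, 0.0],
                      [-0.4, 1.0, -0.4],
                      [0.0, -0.4, 1.0]])
        d = np.sqrt(np.diag(K))
        pc = -K / np.outer(d, d)
        assert pc[0, 2] == 0.0
        cov = np.linalg.inv(K)
        dd = np.sqrt(np.diag(cov))
        marginal = cov / np.outer(dd, dd)
        assert abs(marginal[0, 2]) > 0.1


class TestRest:
    def test_defaults_match_protocol(self):
        cfg = SimConfig(p=60, seed=0)
        assert cfg.t_rest == 150
        assert cfg.tr == 2.0
        parcels, _ = make_parcellation(60, seed=0)
        gt = make_ground_truth_fc(parcels, cfg)
        ts = simulate_rest(gt, cfg, session=1, seed=5)
        assert ts.values.shape == (60, 150)
        assert ts.tr == 2.0

    def test_zero_ar_gives_uncorrelated_frames(self):
        parcels, _ = make_parcellation(60, seed=0)
        cfg = SimConfig(p=60, t_rest=4000, ar_coef=0.0, obs_noise_sd=0.0,
                        seed=0)
        gt = make_ground_truth_fc(parcels, cfg)
        ts = simulate_rest(gt, cfg, session=1, seed=1)
        x = ts.values[0]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(lag1) < 0.05

    def test_long_run_covariance_matches_truth(self):
        parcels, _ = make_parcellation(60, seed=0)
        cfg = SimConfig(p=60, t_rest=50_000, ar_coef=0.0, obs_noise_sd=0.1,
                        seed=0)
        gt = make_ground_truth_fc(parcels, cfg)
        ts = simulate_rest(gt, cfg, session=1, seed=2)
        emp = np.cov(ts.values)
        target = gt.covariance + cfg.obs_noise_sd ** 2 * np.eye(60)
        assert np.max(np.abs(emp - target)) < 0.02

    def test_sessions_differ_but_share_truth(self):
        parcels, _ = make_parcellation(60, seed=0)
        cfg = SimConfig(p=60, seed=0)
        gt = make_ground_truth_fc(parcels, cfg)
        s1 = simulate_rest(gt, cfg, session=1, seed=9)
        s2 = simulate_rest(gt, cfg, session=2, seed=9)
        assert not np.allclose(s1.values, s2.values)


class TestDesigns:
    def test_vm_block_seconds(self):
        vm = make_designs()["VM"][0]
        total = sum(b.duration_s for b in vm.blocks)
        assert total == 5 * 19 + 5 * 18
        assert vm.n_timepoints == 208

    def test_ft_run_length(self):
        ft = make_designs()["FT"][0]
        assert ft.n_timepoints == 92

    def test_eight_conditions_total(self):
        designs = make_designs()
        labels = [c for runs in designs.values() for c in runs[0].condition_set]
        assert sorted(set(labels)) == sorted(CONDITIONS)
        assert len(set(labels)) == 8

    def test_two_vm_runs(self):
        assert len(make_designs()["VM"]) == 2


class TestPlantedActivations:
    def _setup(self, **kw):
        cfg = SimConfig(p=60, seed=4, **kw)
        parcels, _ = make_parcellation(60, seed=4)
        gt = make_ground_truth_fc(parcels, cfg)
        return cfg, parcels, gt

    def test_pure_distributed_limit(self):
        cfg, parcels, gt = self._setup(
            lambda_distributed=1.0, source_noise_sd=0.0, ccc_noise_sd=0.0,
            local_noise_sd=0.0)
        act = make_task_activations(gt, parcels, cfg, 11)
        pc = gt.true_partial_corr
        non_ccc = np.setdiff1d(np.arange(60), parcels.ccc_indices)
        for j in parcels.ccc_indices:
            flow = act.betas[non_ccc].T @ pc[non_ccc, j]
            assert np.allclose(act.betas[j], flow, atol=1e-12)

    def test_pure_local_limit(self):
        cfg, parcels, gt = self._setup(
            lambda_distributed=0.0, source_noise_sd=0.0, ccc_noise_sd=0.0,
            local_noise_sd=0.0)
        act = make_task_activations(gt, parcels, cfg, 11)
        # local component is the scaled structured profile at ratio rho
        prof = condition_profile(cfg.specificity_ratio)
        for j in parcels.ccc_indices:
            b = act.betas[j]
            scale = b[0] / prof[0]
            assert np.allclose(b, scale * prof, atol=1e-10)

    def test_null_specificity_planting(self):
        cfg, parcels, gt = self._setup(
            specificity_ratio=1.0, source_noise_sd=0.0, ccc_noise_sd=0.0,
            local_noise_sd=0.0)
        act = make_task_activations(gt, parcels, cfg, 11)
        vm = act.betas[parcels.ccc_indices][:, :2].mean()
        vs = act.betas[parcels.ccc_indices][:, 2:4].mean()
        assert vm == pytest.approx(vs, rel=1e-9)

    def test_planted_specificity_recoverable(self):
        cfg, parcels, gt = self._setup()  # rho = 1.5 default
        specs = []
        for s in range(120):
            act = make_task_activations(gt, parcels, cfg, 5000 + s)
            for hemi in "LR":
                idx = parcels.ccc_indices_hemi(hemi)
                rec = vergence_specificity(act.betas[idx], act.betas[idx],
                                           subject=str(s), hemisphere=hemi)
                if rec.valid:
                    specs.append(rec.spec_actual)
        assert np.mean(specs) == pytest.approx(1.5, rel=0.05)


class TestTaskRuns:
    def test_noiseless_glm_recovery(self):
        cfg = SimConfig(p=60, task_noise_sd=0.0, confound_strength=0.0, seed=6)
        parcels, _ = make_parcellation(60, seed=6)
        gt = make_ground_truth_fc(parcels, cfg)
        act = make_task_activations(gt, parcels, cfg, 21)
        design = make_designs()["VM"][0]
        ts, _ = simulate_task_runs(design, act, cfg, seed=33)
        dm = build_design_matrix(design)
        est = estimate_betas(ts, dm)
        planted = np.column_stack([act.column(c) for c in est.conditions])
        assert np.max(np.abs(est.betas - planted)) < 1e-8

    def test_same_seed_identical(self):
        cfg = SimConfig(p=60, seed=6)
        parcels, _ = make_parcellation(60, seed=6)
        gt = make_ground_truth_fc(parcels, cfg)
        act = make_task_activations(gt, parcels, cfg, 21)
        design = make_designs()["FT"][0]
        a, ca = simulate_task_runs(design, act, cfg, seed=5, run_id="x")
        b, cb = simulate_task_runs(design, act, cfg, seed=5, run_id="x")
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(ca.motion, cb.motion)

    def test_spike_rate_matches_configuration(self):
        cfg = SimConfig(p=60, spike_rate=0.05, seed=6)
        parcels, _ = make_parcellation(60, seed=6)
        gt = make_ground_truth_fc(parcels, cfg)
        act = make_task_activations(gt, parcels, cfg, 21)
        design = make_designs()["VM"][0]
        from vergeflow.preprocess import compute_fd

        frac = []
        for s in range(30):
            _, conf = simulate_task_runs(design, act, cfg, seed=s)
            _, spikes = compute_fd(conf.motion)
            frac.append(spikes.mean())
        assert np.mean(frac) == pytest.approx(0.05, abs=0.02)


class TestCohort:
    def test_determinism_byte_identical(self):
        cfg = SimConfig(p=60, n_subjects=2, t_rest=60, seed=12)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for ds_a, ds_b in zip(a.subjects, b.subjects):
            assert np.array_equal(ds_a.rest[1].values, ds_b.rest[1].values)
            for task in ds_a.tasks:
                for (ta, _, ca), (tb, _, cb) in zip(ds_a.tasks[task],
                                                    ds_b.tasks[task]):
                    assert np.array_equal(ta.values, tb.values)
                    assert np.array_equal(ca.nuisance, cb.nuisance)
        for sid in a.ground_truth.true_betas:
            assert np.array_equal(a.ground_truth.true_betas[sid].betas,
                                  b.ground_truth.true_betas[sid].betas)

    def test_manifest_lists_two_vm_runs(self, tmp_path):
        cfg = SimConfig(p=60, n_subjects=2, t_rest=60, seed=12)
        simulate_cohort(cfg, out_dir=tmp_path / "cohort")
        import json

        manifest = json.loads((tmp_path / "cohort" / "manifest.json").read_text())
        for entry in manifest["subjects"].values():
            assert len(entry["tasks"]["VM"]) == 2

    def test_generative_identity_downstream(self, noiseless_cohort):
        cohort = noiseless_cohort
        parcels = cohort.parcels
        fc = FCMatrix(cohort.ground_truth.true_partial_corr, method="glasso")
        for sid, act in cohort.ground_truth.true_betas.items():
            flow = actflow_generate(act, fc, parcels.ccc_indices,
                                    SourcePolicy(mode="exclude_ccc"), parcels)
            assert np.max(np.abs(flow.generated
                                 - act.betas[parcels.ccc_indices])) < 1e-10
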
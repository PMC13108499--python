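"""Synthetic BOLD cohorts with known ground truth.

Because the study's raw scans are not deposited, every pipeline stage is
exercised on simulated cohorts that reproduce the statistical structure the
analysis assumes:

* a 12-network parcellation with 8 convergence-circuit (CCC) parcels, four
  per hemisphere (one VIS1, two CON, one DAN);
* resting series drawn from a sparse ground-truth precision matrix with
  denser/stronger within-network blocks, AR(1) temporal structure and
  observation noise;
* block-design task runs for the four tasks (VM x2, VS, SM, FT; TR = 2 s)
  whose condition amplitudes are planted;
* CCC activations that are a mixture of distributed flow (the
  connectivity-weighted sum of non-CCC activations) and a local component,
  mixed by ``lambda_distributed`` with a planted VM/VS specificity ratio.

Planting scheme
---------------
Condition profiles are anchored so that the weakest condition (FT-slow) sits
at zero; min-max normalization then preserves VM/VS ratios. Non-CCC parcels
share the profile shape ``prof(lambda * rho)`` scaled by network amplitudes,
so the flow arriving at a CCC parcel carries specificity ``lambda * rho``.
The local component carries ``rho * (1 + lambda)``; the lambda-weighted
mixture then has actual specificity ``rho`` and generated/actual ratio
``lambda`` in expectation, making the distributed-contribution estimand
equal ``100 * lambda`` by construction.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import (
    CONDITIONS,
    NETWORKS,
    TimeSeriesMatrix,
    VM_CONDITIONS,
    VS_CONDITIONS,
    ActivationMatrix,
    Block,
    ConfoundTable,
    DistanceMatrix,
    ParcelTable,
    SubjectDataset,
    TaskDesign,
    ValidationError,
    write_design,
    write_matrix,
    write_parcel_table,
)
from .preprocess import build_design_matrix, compute_fd

import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Cohort",
    "make_parcellation",
    "make_ground_truth_fc",
    "simulate_rest",
    "make_designs",
    "make_task_activations",
    "simulate_task_runs",
    "simulate_cohort",
]

#: Names of the 8 CCC regions, per hemisphere, in (VIS1, CON, CON, DAN) order.
CCC_REGIONS = ("V1", "FEF", "SCEF", "AIP")
CCC_NETWORKS = ("VIS1", "CON", "CON", "DAN")


@dataclass
class SimConfig:
    """Cohort generation parameters.

    Defaults follow the acquisition the analysis targets: TR = 2 s, 150
    resting TRs, 48 subjects, and network amplitudes that route convergence
    flows predominantly through VIS2 then DAN sources.
    """

    p: int = 360
    n_networks: int = 12
    n_subjects: int = 48
    n_rest_sessions: int = 2
    t_rest: int = 150
    tr: float = 2.0
    # ground-truth precision structure
    within_density: float = 0.6
    within_strength: tuple[float, float] = (0.4, 0.8)
    between_density: float = 0.02
    between_strength: tuple[float, float] = (0.15, 0.35)
    positive_fraction: float = 0.9
    ccc_boost_edges: int = 4          # extra edges from each CCC parcel ...
    ccc_boost_strength: float = 0.6   # ... into each boosted source network
    ccc_boost_networks: tuple[str, ...] = ("VIS2", "DAN")
    # temporal structure
    ar_coef: float = 0.3
    obs_noise_sd: float = 0.1
    # planted activation structure
    lambda_distributed: float = 0.75
    specificity_ratio: float = 1.5
    source_noise_sd: float = 0.05
    ccc_noise_sd: float = 0.03
    local_noise_sd: float = 0.05
    network_amplitudes: dict[str, float] = field(default_factory=lambda: {
        "VIS1": 1.5, "VIS2": 3.0, "DAN": 2.0,
    })
    default_amplitude: float = 0.8
    vm_boost: dict[str, float] = field(default_factory=dict)
    # task-run noise
    task_noise_sd: float = 0.2
    confound_strength: float = 0.1
    spike_rate: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_networks != len(NETWORKS):
            raise ValidationError("n_networks is fixed to the 12 labels")
        if not (0.0 <= self.lambda_distributed <= 1.0):
            raise ValidationError("lambda_distributed must lie in [0, 1]")
        if self.specificity_ratio <= 0:
            raise ValidationError("specificity_ratio must be positive")
        for name, dens in (("within_density", self.within_density),
                           ("between_density", self.between_density)):
            if not (0.0 <= dens <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.t_rest < 50:
            raise ValidationError("t_rest must be at least 50 frames")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")

    def amplitude(self, network: str) -> float:
        return self.network_amplitudes.get(network, self.default_amplitude)


@dataclass
class GroundTruth:
    """Generative truth record: precision, mixing weight, planted ratio."""

    precision: np.ndarray
    true_partial_corr: np.ndarray
    covariance: np.ndarray
    lambda_distributed: float
    specificity_ratio: float
    seed: int
    true_betas: dict[str, ActivationMatrix] = field(default_factory=dict)

    def __post_init__(self):
        eigs = np.linalg.eigvalsh(self.precision)
        if eigs.min() <= 0:
            raise ValidationError("precision matrix is not positive definite")


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def make_parcellation(p: int, seed: int = 0) -> tuple[ParcelTable, DistanceMatrix]:
    """Build a P-parcel, 12-network, two-hemisphere parcellation.

    Parcels within each network alternate hemispheres; the 8 CCC parcels are
    placed per hemisphere as (VIS1, CON, CON, DAN). Distances come from a
    random 3-D embedding per hemisphere with a large cross-hemisphere offset.
    """
    if p < 24:
        raise ValidationError("need p >= 24 for 12 networks across 2 hemispheres")
    rng = np.random.default_rng(seed)
    K = len(NETWORKS)
    sizes = np.full(K, p // K)
    sizes[: p % K] += 1
    # CCC needs: VIS1 >= 1/hemi, CON >= 2/hemi, DAN >= 1/hemi
    minimum = {"VIS1": 2, "CON": 4, "DAN": 2}
    for net, m in minimum.items():
        if sizes[NETWORKS.index(net)] < m:
            raise ValidationError(f"p={p} leaves network {net} with < {m} parcels")

    rows = []
    pid = 1
    for net, size in zip(NETWORKS, sizes):
        for i in range(size):
            hemi = "LR"[i % 2]
            rows.append((pid, f"{net}_{hemi}{i // 2 + 1:02d}", hemi, net, False))
            pid += 1
    frame = pd.DataFrame(
        rows, columns=["parcel_id", "name", "hemisphere", "network", "is_ccc"]
    )

    # flag CCC parcels: per hemisphere one VIS1, two CON, one DAN
    for hemi in ("L", "R"):
        picks = []
        for region, net in zip(CCC_REGIONS, CCC_NETWORKS):
            pool = frame.index[
                (frame.network == net) & (frame.hemisphere == hemi)
                & ~frame.index.isin(picks)
            ]
            picks.append(int(pool[0]))
            frame.loc[picks[-1], "name"] = f"{region}_{hemi}"
        frame.loc[picks, "is_ccc"] = True

    coords = rng.uniform(0.0, 70.0, size=(p, 3))
    coords[frame.hemisphere.to_numpy() == "R", 0] += 140.0
    frame["mni_x"], frame["mni_y"], frame["mni_z"] = coords.T
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(dist, 0.0)
    return ParcelTable(frame), DistanceMatrix(dist)


# ---------------------------------------------------------------------------
# Ground-truth connectivity
# ---------------------------------------------------------------------------

def _partial_corr_from_precision(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def make_ground_truth_fc(parcels: ParcelTable, cfg: SimConfig) -> GroundTruth:
    """Sample a sparse SPD precision with network-block structure.

    Edge weights are drawn as target partial-correlation strengths (mostly
    positive, i.e. negative precision off-diagonals); extra edges connect
    each CCC parcel to same-hemisphere parcels of the boosted source
    networks. SPD is enforced by diagonal-dominance loading, after which the
    true partial correlation is ``-P_ij / sqrt(P_ii P_jj)``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    P = parcels.n_parcels
    nets = parcels.networks
    hemis = parcels.hemispheres
    W = np.zeros((P, P))

    iu = np.triu_indices(P, 1)
    same_net = nets[iu[0]] == nets[iu[1]]
    dens = np.where(same_net, cfg.within_density, cfg.between_density)
    lo = np.where(same_net, cfg.within_strength[0], cfg.between_strength[0])
    hi = np.where(same_net, cfg.within_strength[1], cfg.between_strength[1])
    on = rng.random(len(iu[0])) < dens
    mag = rng.uniform(lo, hi)
    sign = np.where(rng.random(len(iu[0])) < cfg.positive_fraction, 1.0, -1.0)
    vals = np.where(on, mag * sign, 0.0)
    W[iu] = vals
    W.T[iu] = vals

    # planted CCC source edges (strong positive connectivity to VIS2/DAN)
    for j in parcels.ccc_indices:
        for net in cfg.ccc_boost_networks:
            pool = np.flatnonzero(
                (nets == net) & (hemis == hemis[j]) & ~parcels.is_ccc
            )
            if pool.size == 0:
                continue
            picks = rng.choice(pool, size=min(cfg.ccc_boost_edges, pool.size),
                               replace=False)
            for i in picks:
                W[i, j] = W[j, i] = cfg.ccc_boost_strength

    precision = -W
    rowsum = np.abs(W).sum(axis=1)
    np.fill_diagonal(precision, np.maximum(1.0, 1.1 * rowsum))
    cov = np.linalg.inv(precision)
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)           # correlation scale; partial corr unchanged
    precision = np.linalg.inv(cov)
    precision = 0.5 * (precision + precision.T)
    return GroundTruth(
        precision=precision,
        true_partial_corr=_partial_corr_from_precision(precision),
        covariance=cov,
        lambda_distributed=cfg.lambda_distributed,
        specificity_ratio=cfg.specificity_ratio,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# Resting-state simulation
# ---------------------------------------------------------------------------

def simulate_rest(gt: GroundTruth, cfg: SimConfig, session: int,
                  seed: int) -> TimeSeriesMatrix:
    """Draw one resting run: AR(1) latent process + observation noise.

    The innovation covariance is scaled so the latent stationary covariance
    equals the ground-truth covariance regardless of the AR coefficient;
    distinct sessions use independent noise streams of the same truth.
    """
    if cfg.t_rest < 50:
        raise ValidationError("t_rest must be at least 50")
    rng = np.random.default_rng((seed, session))
    P = gt.covariance.shape[0]
    L = np.linalg.cholesky(gt.covariance)
    phi = cfg.ar_coef
    x = np.empty((cfg.t_rest, P))
    x[0] = L @ rng.standard_normal(P)
    innov_scale = np.sqrt(1.0 - phi ** 2)
    for t in range(1, cfg.t_rest):
        x[t] = phi * x[t - 1] + innov_scale * (L @ rng.standard_normal(P))
    x += cfg.obs_noise_sd * rng.standard_normal(x.shape)
    return TimeSeriesMatrix(x.T, tr=cfg.tr, run_id=f"rest{session}",
                            state="rest")


# ---------------------------------------------------------------------------
# Task designs
# ---------------------------------------------------------------------------

def _block_run(task: str, conds: tuple[str, str], counts: tuple[int, int],
               durations: tuple[float, float], n_timepoints: int,
               tr: float) -> TaskDesign:
    """Alternate the two block types with evenly spaced rest gaps."""
    n_blocks = sum(counts)
    order = []
    for i in range(max(counts)):
        if i < counts[0]:
            order.append(0)
        if i < counts[1]:
            order.append(1)
    task_s = counts[0] * durations[0] + counts[1] * durations[1]
    gap = (n_timepoints * tr - task_s) / (n_blocks + 1)
    if gap < 0:
        raise ValidationError(f"{task} blocks exceed run length")
    blocks, t = [], gap
    for which in order:
        blocks.append(Block(conds[which], round(t, 6), durations[which]))
        t += durations[which] + gap
    return TaskDesign(tuple(blocks), n_timepoints, tr, conds)


def make_designs(tr: float = 2.0) -> dict[str, list[TaskDesign]]:
    """The four task designs: VM (two runs), VS, SM, FT.

    VM: 5 x 19 s many + 5 x 18 s few over 208 TRs; VS: 5 x 22 + 5 x 18 over
    208 TRs; SM: 5 x 24 + 5 x 24 over 208 TRs; FT: 3 x 20 + 3 x 20 over
    92 TRs. Rest gaps are spaced evenly to fill the printed run lengths.
    """
    vm = _block_run("VM", ("VM-many", "VM-few"), (5, 5), (19.0, 18.0), 208, tr)
    vs = _block_run("VS", ("VS-many", "VS-few"), (5, 5), (22.0, 18.0), 208, tr)
    sm = _block_run("SM", ("SM-fast", "SM-slow"), (5, 5), (24.0, 24.0), 208, tr)
    ft = _block_run("FT", ("FT-fast", "FT-slow"), (3, 3), (20.0, 20.0), 92, tr)
    return {"VM": [vm, vm], "VS": [vs], "SM": [sm], "FT": [ft]}


# ---------------------------------------------------------------------------
# Planted activations
# ---------------------------------------------------------------------------

def condition_profile(ratio: float) -> np.ndarray:
    """Base 8-condition profile with VM-mean/VS-mean equal to ``ratio``.

    VS conditions sit at 0.6, the VM pair at (1.1, 0.9) * 0.6 * ratio, the
    control conditions below, and FT-slow at exactly 0 so that min-max
    normalization (which anchors at the profile minimum) preserves the
    planted VM/VS ratio.
    """
    base_vs = 0.6
    prof = np.array([
        1.1 * base_vs * ratio,   # VM-many
        0.9 * base_vs * ratio,   # VM-few
        base_vs,                 # VS-many
        base_vs,                 # VS-few
        0.45, 0.3,               # SM-fast, SM-slow
        0.2, 0.0,                # FT-fast, FT-slow
    ])
    return prof


def make_task_activations(gt: GroundTruth, parcels: ParcelTable,
                          cfg: SimConfig, subject_seed: int
                          ) -> ActivationMatrix:
    """Plant one subject's true P x 8 activation matrix.

    Non-CCC parcels: ``beta_i = a_i * prof(lambda * rho) + noise`` with
    network amplitudes ``a_i`` (optionally VM-boosted per network). Each CCC
    parcel mixes the distributed flow (connectivity-weighted non-CCC sum)
    with a structured local component plus i.i.d. noise orthogonalized
    against the flow.
    """
    rng = np.random.default_rng((subject_seed, 17))
    P = parcels.n_parcels
    lam = gt.lambda_distributed
    rho = gt.specificity_ratio
    pc = gt.true_partial_corr
    ccc = parcels.ccc_indices
    non_ccc = np.setdiff1d(np.arange(P), ccc)

    flow_prof = condition_profile(lam * rho)
    betas = np.zeros((P, len(CONDITIONS)))
    amps = np.array([cfg.amplitude(n) for n in parcels.networks])
    vm_mask = np.isin(np.array(CONDITIONS), np.array(VM_CONDITIONS))
    for i in non_ccc:
        boost = cfg.vm_boost.get(parcels.networks[i], 0.0)
        prof_i = flow_prof * np.where(vm_mask, 1.0 + boost, 1.0)
        betas[i] = amps[i] * prof_i + cfg.source_noise_sd * rng.standard_normal(
            len(CONDITIONS))

    local_prof = (condition_profile(rho * (1.0 + lam)) if lam < 1.0
                  else np.zeros(len(CONDITIONS)))
    for j in ccc:
        flow_j = betas[non_ccc].T @ pc[non_ccc, j]      # 8-vector
        s_j = float(amps[non_ccc] @ pc[non_ccc, j])     # expected flow scale
        eps = cfg.local_noise_sd * rng.standard_normal(len(CONDITIONS))
        denom = float(flow_j @ flow_j)
        if denom > 0:
            eps -= (eps @ flow_j) / denom * flow_j      # orthogonal to flow
        local_j = s_j * local_prof + eps
        noise = cfg.ccc_noise_sd * rng.standard_normal(len(CONDITIONS))
        betas[j] = lam * flow_j + (1.0 - lam) * local_j + noise
    return ActivationMatrix(betas, CONDITIONS)


# ---------------------------------------------------------------------------
# Task-run simulation
# ---------------------------------------------------------------------------

def _simulate_confounds(n_frames: int, cfg: SimConfig,
                        rng: np.random.Generator) -> ConfoundTable:
    """Motion random walk with occasional spikes + AR physiological series."""
    steps = 0.01 * rng.standard_normal((n_frames, 6))
    jumps = rng.random(n_frames) < cfg.spike_rate
    steps[jumps] += rng.uniform(0.4, 1.2, size=(int(jumps.sum()), 1)) \
        * rng.choice([-1.0, 1.0], size=(int(jumps.sum()), 6))
    motion = np.cumsum(steps, axis=0)

    physio = np.zeros((n_frames, 5))
    physio[0] = rng.standard_normal(5)
    for t in range(1, n_frames):
        physio[t] = 0.5 * physio[t - 1] + rng.standard_normal(5)

    def expand(base: np.ndarray) -> np.ndarray:
        deriv = np.vstack([np.zeros((1, base.shape[1])), np.diff(base, axis=0)])
        return np.hstack([base, deriv, base ** 2, deriv ** 2])

    nuisance = np.hstack([expand(motion), expand(physio)])
    fd, _ = compute_fd(motion)
    return ConfoundTable(motion=motion, nuisance=nuisance, fd=fd)


def simulate_task_runs(design: TaskDesign, true_betas: ActivationMatrix,
                       cfg: SimConfig, seed: int, run_id: str = "task"
                       ) -> tuple[TimeSeriesMatrix, ConfoundTable]:
    """One task run: HRF-convolved design times beta + confounds + AR noise."""
    rng = np.random.default_rng((seed, zlib.crc32(run_id.encode())))
    dm = build_design_matrix(design)
    X = dm.conditions                                   # T x C_task
    cond_idx = [true_betas.conditions.index(c) for c in dm.condition_labels]
    B = true_betas.betas[:, cond_idx]                   # P x C_task
    y = X @ B.T                                         # T x P

    conf = _simulate_confounds(design.n_timepoints, cfg, rng)
    if cfg.confound_strength > 0:
        loadings = cfg.confound_strength * rng.standard_normal(
            (conf.nuisance.shape[1], B.shape[0]))
        # standardized confounds so loading scale is interpretable
        z = conf.nuisance - conf.nuisance.mean(0)
        sd = z.std(0)
        z = z / np.where(sd > 0, sd, 1.0)
        y = y + z @ loadings

    if cfg.task_noise_sd > 0:
        noise = np.empty_like(y)
        noise[0] = rng.standard_normal(y.shape[1])
        for t in range(1, y.shape[0]):
            noise[t] = cfg.ar_coef * noise[t - 1] + np.sqrt(
                1 - cfg.ar_coef ** 2) * rng.standard_normal(y.shape[1])
        y = y + cfg.task_noise_sd * noise

    ts = TimeSeriesMatrix(y.T, tr=design.tr, run_id=run_id, state="task")
    return ts, conf


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A simulated cohort plus its generative truth."""

    config: SimConfig
    parcels: ParcelTable
    distances: DistanceMatrix
    ground_truth: GroundTruth
    subjects: list[SubjectDataset]
    designs: dict[str, list[TaskDesign]]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def simulate_cohort(cfg: SimConfig, out_dir: str | Path | None = None) -> Cohort:
    """Simulate a full cohort; optionally write it to disk with a manifest."""
    if cfg.n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    parcels, distances = make_parcellation(cfg.p, seed=cfg.seed)
    gt = make_ground_truth_fc(parcels, cfg)
    designs = make_designs(cfg.tr)

    ss = np.random.SeedSequence(cfg.seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(cfg.n_subjects)]

    subjects = []
    for si, sseed in enumerate(subject_seeds):
        sid = f"sub-{si + 1:03d}"
        true_act = make_task_activations(gt, parcels, cfg, sseed)
        gt.true_betas[sid] = true_act

        rest, rest_conf = {}, {}
        for session in range(1, cfg.n_rest_sessions + 1):
            ts = simulate_rest(gt, cfg, session, sseed)
            ts.subject_id = sid
            rest[session] = ts
            rng = np.random.default_rng((sseed, 900 + session))
            rest_conf[session] = _simulate_confounds(cfg.t_rest, cfg, rng)

        tasks: dict[str, list] = {}
        for task, runs in designs.items():
            tasks[task] = []
            for ri, design in enumerate(runs):
                run_id = f"{task}_run{ri + 1}"
                ts, conf = simulate_task_runs(design, true_act, cfg, sseed,
                                              run_id=run_id)
                ts.subject_id = sid
                tasks[task].append((ts, design, conf))
        subjects.append(SubjectDataset(
            subject_id=sid, rest=rest, rest_confounds=rest_conf,
            tasks=tasks, parcels=parcels,
        ))

    cohort = Cohort(cfg, parcels, distances, gt, subjects, designs)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the cohort as TSV/HDF5 files with a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_parcel_table(cohort.parcels, out / "parcels.tsv")
    write_matrix(cohort.distances.values, out / "distances.tsv")
    write_matrix(cohort.ground_truth.true_partial_corr,
                 out / "truth_partial_corr.h5")
    write_matrix(cohort.ground_truth.precision, out / "truth_precision.h5")
    for task, runs in cohort.designs.items():
        for ri, d in enumerate(runs):
            write_design(d, out / f"design_{task}_run{ri + 1}.tsv")

    manifest: dict[str, object] = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cohort.config).items()},
        "n_subjects": len(cohort.subjects),
        "subjects": {},
    }
    for ds in cohort.subjects:
        sdir = out / ds.subject_id
        sdir.mkdir(exist_ok=True)
        entry: dict[str, object] = {"rest": [], "tasks": {}}
        for session, ts in ds.rest.items():
            name = f"rest_ses{session}.h5"
            write_matrix(ts.values, sdir / name,
                         {"tr": ts.tr, "subject_id": ds.subject_id,
                          "state": "rest"})
            _write_confounds(ds.rest_confounds[session],
                             sdir / f"confounds_rest_ses{session}.h5")
            entry["rest"].append(name)
        for task, runs in ds.tasks.items():
            entry["tasks"][task] = []
            for ri, (ts, design, conf) in enumerate(runs):
                name = f"{task}_run{ri + 1}.h5"
                write_matrix(ts.values, sdir / name,
                             {"tr": ts.tr, "subject_id": ds.subject_id,
                              "state": task})
                _write_confounds(conf, sdir / f"confounds_{task}_run{ri + 1}.h5")
                entry["tasks"][task].append(name)
        true_act = cohort.ground_truth.true_betas[ds.subject_id]
        write_matrix(true_act.betas, sdir / "true_betas.h5",
                     {"conditions": list(true_act.conditions)})
        manifest["subjects"][ds.subject_id] = entry
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _write_confounds(conf: ConfoundTable, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("motion", data=conf.motion)
        h5.create_dataset("nuisance", data=conf.nuisance)
        if conf.fd is not None:
            h5.create_dataset("fd", data=conf.fd)


def read_cohort(path: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    import h5py

    from .core import read_design, read_matrix, read_parcel_table

    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    raw_cfg = dict(manifest["config"])
    for key in ("within_strength", "between_strength", "ccc_boost_networks"):
        if key in raw_cfg and isinstance(raw_cfg[key], list):
            raw_cfg[key] = tuple(raw_cfg[key])
    cfg = SimConfig(**raw_cfg)
    parcels = read_parcel_table(root / "parcels.tsv")
    distances = read_matrix(root / "distances.tsv", "distance", parcels)
    designs = make_designs(cfg.tr)
    pc = read_matrix(root / "truth_partial_corr.h5", "fc").values

    with h5py.File(root / "truth_precision.h5", "r") as h5:
        precision = h5["values"][()]
    cov = np.linalg.inv(precision)
    d = np.sqrt(np.diag(cov))
    gt = GroundTruth(precision=precision,
                     true_partial_corr=pc,
                     covariance=cov / np.outer(d, d),
                     lambda_distributed=cfg.lambda_distributed,
                     specificity_ratio=cfg.specificity_ratio,
                     seed=cfg.seed)

    subjects = []
    for sid, entry in manifest["subjects"].items():
        sdir = root / sid
        rest, rest_conf = {}, {}
        for session, name in enumerate(entry["rest"], start=1):
            rest[session] = read_matrix(sdir / name, "timeseries", parcels,
                                        tr=cfg.tr, subject_id=sid)
            rest_conf[session] = _read_confounds(
                sdir / f"confounds_rest_ses{session}.h5")
        tasks: dict[str, list] = {}
        for task, names in entry["tasks"].items():
            tasks[task] = []
            for ri, name in enumerate(names):
                ts = read_matrix(sdir / name, "timeseries", parcels,
                                 tr=cfg.tr, subject_id=sid, state=task)
                conf = _read_confounds(sdir / f"confounds_{task}_run{ri + 1}.h5")
                tasks[task].append((ts, designs[task][ri], conf))
        gt.true_betas[sid] = read_matrix(sdir / "true_betas.h5", "activation",
                                         parcels)
        subjects.append(SubjectDataset(subject_id=sid, rest=rest,
                                       rest_confounds=rest_conf, tasks=tasks,
                                       parcels=parcels))
    return Cohort(cfg, parcels, distances, gt, subjects, designs)


def _read_confounds(path: Path) -> ConfoundTable:
    import h5py

    with h5py.File(path, "r") as h5:
        return ConfoundTable(motion=h5["motion"][()],
                             nuisance=h5["nuisance"][()],
                             fd=h5["fd"][()] if "fd" in h5 else None)
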
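"""Parcel-level denoising and GLM activation estimation.

The procedure is two-step: (1) per-run nuisance regression removes the mean,
a linear trend, the 44 motion/physiological regressors and (for rest) one
spike regressor per high-motion frame; (2) condition amplitudes are then
estimated by ordinary least squares against HRF-convolved block regressors,
with the two VM runs concatenated between the steps. The two-step form is
less efficient than a joint model but keeps the denoised series reusable
for connectivity estimation.

Spike regressors are applied to resting-state runs only; task runs rely on
the 44 confound regressors. Detrending is first-order (demean + linear).
No prewhitening is applied: betas are used as point amplitude estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .core import (
    FD_SPIKE_THRESHOLD_MM,
    ActivationMatrix,
    ConfoundTable,
    SubjectDataset,
    TaskDesign,
    TimeSeriesMatrix,
    ValidationError,
)

__all__ = [
    "compute_fd",
    "canonical_hrf",
    "build_design_matrix",
    "denoise",
    "estimate_betas",
    "subject_activations",
    "DesignMatrix",
]


def compute_fd(motion: np.ndarray,
               threshold: float = FD_SPIKE_THRESHOLD_MM
               ) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise displacement and spike mask from 6 rigid-body parameters.

    Displacement is the relative root-mean-square frame-to-frame change of
    the six parameters (assumed already expressed in mm). Frame 0 has zero
    displacement by convention; the mask is True strictly above ``threshold``.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValidationError(
            f"motion must be T x 6, got shape {motion.shape}"
        )
    if motion.shape[0] < 2:
        raise ValidationError("need at least 2 frames to compute displacement")
    diffs = np.diff(motion, axis=0)
    fd = np.zeros(motion.shape[0])
    fd[1:] = np.sqrt(np.mean(diffs ** 2, axis=1))
    return fd, fd > threshold


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every ``tr`` s.

    Response peak at 6 s, undershoot peak at 16 s, unit dispersions,
    undershoot ratio 1/6, 32 s support; peak-normalized to a maximum of 1.
    """
    if tr <= 0:
        raise ValidationError("tr must be positive")
    t = np.arange(0.0, duration + 1e-9, tr)
    peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """T x R design with labeled columns; condition columns come first."""

    values: np.ndarray
    labels: tuple[str, ...]
    condition_labels: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.labels):
            raise ValidationError("design labels do not match columns")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValidationError("design matrix is rank deficient")

    @property
    def conditions(self) -> np.ndarray:
        idx = [self.labels.index(c) for c in self.condition_labels]
        return self.values[:, idx]


def _convolved_regressors(design: TaskDesign, tr: float,
                          oversample: int = 16) -> np.ndarray:
    """HRF-convolved boxcars for each condition, sampled at frame times."""
    if not design.condition_set:
        raise ValidationError("design has no conditions")
    dt = tr / oversample
    n_fine = design.n_timepoints * oversample
    hrf = canonical_hrf(dt)
    cols = np.zeros((design.n_timepoints, len(design.condition_set)))
    for ci, cond in enumerate(design.condition_set):
        box = np.zeros(n_fine)
        for b in design.blocks:
            if b.condition != cond:
                continue
            i0 = int(round(b.onset_s / dt))
            i1 = int(round((b.onset_s + b.duration_s) / dt))
            box[i0:min(i1, n_fine)] = 1.0
        conv = np.convolve(box, hrf)[:n_fine]
        cols[:, ci] = conv[::oversample]
    return cols


def build_design_matrix(designs: TaskDesign | Sequence[TaskDesign],
                        tr: float | None = None) -> DesignMatrix:
    """Assemble the GLM design for one run or a concatenation of runs.

    Condition regressors are HRF-convolved boxcars stacked across runs; one
    intercept column is added per run. All runs must share a condition set.
    """
    if isinstance(designs, TaskDesign):
        designs = [designs]
    designs = list(designs)
    if tr is None:
        tr = designs[0].tr
    cond_set = designs[0].condition_set
    for d in designs:
        if d.condition_set != cond_set:
            raise ValidationError("concatenated runs must share a condition set")
    blocks = [_convolved_regressors(d, tr) for d in designs]
    n_total = sum(d.n_timepoints for d in designs)
    cond_cols = np.vstack(blocks)
    intercepts = np.zeros((n_total, len(designs)))
    offset = 0
    for ri, d in enumerate(designs):
        intercepts[offset:offset + d.n_timepoints, ri] = 1.0
        offset += d.n_timepoints
    values = np.hstack([cond_cols, intercepts])
    labels = tuple(cond_set) + tuple(f"intercept_run{r + 1}"
                                     for r in range(len(designs)))
    return DesignMatrix(values, labels, tuple(cond_set))


def _nuisance_matrix(n_frames: int, confounds: np.ndarray | None,
                     spikes: np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(n_frames), np.linspace(-1.0, 1.0, n_frames)]
    labels = ["intercept", "trend"]
    if confounds is not None:
        for i in range(confounds.shape[1]):
            cols.append(confounds[:, i])
            labels.append(f"confound_{i}")
    if spikes is not None:
        for frame in np.flatnonzero(spikes):
            one_hot = np.zeros(n_frames)
            one_hot[frame] = 1.0
            cols.append(one_hot)
            labels.append(f"spike_{frame}")
    return np.column_stack(cols), labels


def denoise(ts: TimeSeriesMatrix,
            confounds: ConfoundTable | np.ndarray | None = None,
            spikes: np.ndarray | None = None,
            drop_initial: int = 0) -> TimeSeriesMatrix:
    """Remove initial frames, mean, linear trend, confounds and spikes.

    Returns the per-parcel OLS residual series. Raises on a rank-deficient
    nuisance matrix, naming the collinear columns.
    """
    values = ts.values
    conf = confounds.nuisance if isinstance(confounds, ConfoundTable) else confounds
    if conf is not None and conf.shape[0] != ts.n_timepoints:
        raise ValidationError("confound rows do not match time series frames")
    if spikes is not None and len(spikes) != ts.n_timepoints:
        raise ValidationError("spike mask length does not match time series")
    if drop_initial:
        values = values[:, drop_initial:]
        conf = None if conf is None else conf[drop_initial:]
        spikes = None if spikes is None else spikes[drop_initial:]
    T = values.shape[1]
    nuisance, labels = _nuisance_matrix(T, conf, spikes)
    rank = np.linalg.matrix_rank(nuisance)
    if rank < nuisance.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = np.empty((T, 0))
        for j in range(nuisance.shape[1]):
            cand = np.hstack([kept, nuisance[:, j:j + 1]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(labels[j])
        raise ValidationError(
            f"nuisance matrix rank deficient; collinear columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(nuisance, values.T, rcond=None)
    resid = values.T - nuisance @ beta
    return TimeSeriesMatrix(resid.T, tr=ts.tr, subject_id=ts.subject_id,
                            run_id=ts.run_id, state=ts.state)


def estimate_betas(ts: TimeSeriesMatrix | Sequence[TimeSeriesMatrix],
                   dm: DesignMatrix) -> ActivationMatrix:
    """OLS condition amplitudes per parcel; returns condition columns only."""
    if isinstance(ts, TimeSeriesMatrix):
        data = ts.values
    else:
        data = np.hstack([t.values for t in ts])
    if dm.values.shape[0] != data.shape[1]:
        raise ValidationError(
            f"design has {dm.values.shape[0]} rows but series has "
            f"{data.shape[1]} frames"
        )
    beta, *_ = np.linalg.lstsq(dm.values, data.T, rcond=None)
    cond_idx = [dm.labels.index(c) for c in dm.condition_labels]
    return ActivationMatrix(beta[cond_idx].T, dm.condition_labels)


def subject_activations(ds: SubjectDataset,
                        conditions: Sequence[str] | None = None
                        ) -> ActivationMatrix:
    """Denoise every task run and assemble the P x 8 activation matrix.

    VM's two runs are concatenated after denoising and fit jointly; every
    other task is fit from its single run. Columns follow ``conditions``
    (default: the union in task order).
    """
    betas_by_cond: dict[str, np.ndarray] = {}
    cond_order: list[str] = []
    for task, runs in ds.tasks.items():
        cleaned, designs = [], []
        for ts, design, conf in runs:
            cleaned.append(denoise(ts, conf))
            designs.append(design)
        dm = build_design_matrix(designs)
        act = estimate_betas(cleaned, dm)
        for cond in act.conditions:
            betas_by_cond[cond] = act.column(cond)
            cond_order.append(cond)
    if conditions is None:
        conditions = cond_order
    betas = np.column_stack([betas_by_cond[c] for c in conditions])
    return ActivationMatrix(betas, tuple(conditions))
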
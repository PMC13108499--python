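"""Domain types, file I/O and dataset validation shared by every pipeline stage.

The analysis space is parcels x time (BOLD series) and parcels x conditions
(GLM activation amplitudes). All containers validate their invariants on
construction so downstream stages can assume well-formed inputs.

On-disk dialects
----------------
* Parcel tables and small matrices: tab-delimited text (diff-able fixtures).
* Cohorts: HDF5, one dataset per matrix under ``/values`` with shape/metadata
  attributes.
* Task designs: TSV with columns ``condition``, ``onset_s``, ``duration_s``.

Parcel ids are 1-based in files (atlas-index convention) and contiguous
0-based internally. MNI coordinates are carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

#: The 12 cortical network labels (CAB-NP abbreviations).
NETWORKS: tuple[str, ...] = (
    "VIS1", "VIS2", "SMN", "CON", "DAN", "LAN",
    "FPN", "AUD", "DMN", "PMM", "VMM", "ORA",
)

#: The 8 task conditions, ordered: two conditions per task (VM, VS, SM, FT).
CONDITIONS: tuple[str, ...] = (
    "VM-many", "VM-few", "VS-many", "VS-few",
    "SM-fast", "SM-slow", "FT-fast", "FT-slow",
)

#: Conditions belonging to the convergence motor (VM) and sensory (VS) tasks.
VM_CONDITIONS: tuple[str, ...] = ("VM-many", "VM-few")
VS_CONDITIONS: tuple[str, ...] = ("VS-many", "VS-few")

#: Frame-wise displacement threshold (mm) above which a frame is a spike.
FD_SPIKE_THRESHOLD_MM: float = 0.25

#: Number of nuisance regressors before spike columns (24 motion + 20 physio).
N_NUISANCE_COLUMNS: int = 44

HEMISPHERES: tuple[str, ...] = ("L", "R")


class ValidationError(ValueError):
    """An input violated a structural invariant."""


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

class ParcelTable:
    """Parcel identities, hemisphere, 12-network assignment and CCC membership.

    Wraps a :class:`pandas.DataFrame` with columns ``parcel_id`` (1-based,
    contiguous), ``name``, ``hemisphere`` (L/R), ``network`` (one of the 12
    labels), ``is_ccc`` (bool) and optional ``mni_x/y/z``.
    """

    REQUIRED = ("parcel_id", "name", "hemisphere", "network", "is_ccc")

    def __init__(self, frame: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValidationError(f"parcel table missing column {col!r}")
        frame = frame.reset_index(drop=True)
        ids = frame["parcel_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            dup = int(ids[pd.Series(ids).duplicated()][0])
            raise ValidationError(f"duplicate parcel_id {dup}")
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValidationError("parcel_id must be contiguous 1..P")
        frame = frame.sort_values("parcel_id").reset_index(drop=True)
        bad = set(frame["network"]) - set(NETWORKS)
        if bad:
            raise ValidationError(f"unknown network label(s): {sorted(bad)}")
        bad_hemi = set(frame["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere label(s): {sorted(bad_hemi)}")
        frame["is_ccc"] = frame["is_ccc"].astype(bool)
        self.frame = frame

    # -- basic accessors ----------------------------------------------------

    @property
    def n_parcels(self) -> int:
        return len(self.frame)

    @property
    def networks(self) -> np.ndarray:
        """Per-parcel network label (length P)."""
        return self.frame["network"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.frame["hemisphere"].to_numpy()

    @property
    def is_ccc(self) -> np.ndarray:
        return self.frame["is_ccc"].to_numpy()

    @property
    def ccc_indices(self) -> np.ndarray:
        """0-based indices of the CCC parcels."""
        return np.flatnonzero(self.is_ccc)

    def ccc_indices_hemi(self, hemisphere: str) -> np.ndarray:
        return np.flatnonzero(self.is_ccc & (self.hemispheres == hemisphere))

    def network_indices(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.networks == network)

    def v1_indices(self) -> np.ndarray:
        """The two primary-visual CCC parcels (one per hemisphere), L then R."""
        out = []
        for hemi in HEMISPHERES:
            idx = np.flatnonzero(
                self.is_ccc & (self.networks == "VIS1") & (self.hemispheres == hemi)
            )
            if idx.size != 1:
                raise ValidationError(
                    f"expected exactly one VIS1 CCC parcel in hemisphere {hemi}"
                )
            out.append(int(idx[0]))
        return np.asarray(out)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParcelTable) and self.frame.equals(other.frame)

    def __repr__(self) -> str:
        return f"ParcelTable(P={self.n_parcels}, ccc={int(self.is_ccc.sum())})"


def read_parcel_table(path: str | Path) -> ParcelTable:
    """Read a validated :class:`ParcelTable` from a TSV file."""
    frame = pd.read_csv(path, sep="\t")
    return ParcelTable(frame)


def write_parcel_table(parcels: ParcelTable, path: str | Path) -> None:
    parcels.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"{what} contains non-finite value at index {tuple(int(i) for i in bad)}"
        )


def _check_symmetric(values: np.ndarray, what: str, tol: float = 1e-8) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"{what} must be square, got shape {values.shape}")
    if not np.allclose(values, values.T, atol=tol):
        raise ValidationError(f"{what} must be symmetric")


@dataclass
class DistanceMatrix:
    """Symmetric inter-parcel distances in mm with a zero diagonal."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_finite(self.values, "distance matrix")
        _check_symmetric(self.values, "distance matrix")
        if np.any(self.values < 0):
            raise ValidationError("distances must be non-negative")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValidationError("distance matrix diagonal must be zero")


@dataclass
class TimeSeriesMatrix:
    """Parcels x timepoints BOLD matrix with acquisition metadata."""

    values: np.ndarray
    tr: float
    subject_id: str = ""
    run_id: str = ""
    state: str = "rest"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("time series must be 2-D (parcels x timepoints)")
        if self.values.shape[1] < 2:
            raise ValidationError("time series needs T >= 2 frames")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if not np.all(np.isfinite(self.values)):
            frame = int(np.argwhere(~np.isfinite(self.values))[0][1])
            raise ValidationError(f"non-finite time-series value at frame {frame}")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float


@dataclass
class TaskDesign:
    """Block timing for one task run."""

    blocks: tuple[Block, ...]
    n_timepoints: int
    tr: float
    condition_set: tuple[str, ...]

    def __post_init__(self):
        self.blocks = tuple(
            b if isinstance(b, Block) else Block(*b) for b in self.blocks
        )
        run_s = self.n_timepoints * self.tr
        labels = {b.condition for b in self.blocks}
        missing = labels - set(self.condition_set)
        if missing:
            raise ValidationError(f"block condition(s) not in condition_set: {missing}")
        for b in self.blocks:
            if b.onset_s < 0 or b.onset_s + b.duration_s > run_s + 1e-9:
                raise ValidationError(
                    f"block {b.condition} at {b.onset_s}s (+{b.duration_s}s) "
                    f"outside run of {run_s}s"
                )
        ordered = sorted(self.blocks, key=lambda b: b.onset_s)
        for a, b in zip(ordered, ordered[1:]):
            if a.onset_s + a.duration_s > b.onset_s + 1e-9:
                raise ValidationError(
                    f"blocks overlap: {a.condition}@{a.onset_s}s and "
                    f"{b.condition}@{b.onset_s}s"
                )

    @property
    def run_seconds(self) -> float:
        return self.n_timepoints * self.tr


def read_design(path: str | Path, n_timepoints: int, tr: float,
                condition_set: Sequence[str] | None = None) -> TaskDesign:
    frame = pd.read_csv(path, sep="\t")
    blocks = tuple(
        Block(str(r.condition), float(r.onset_s), float(r.duration_s))
        for r in frame.itertuples()
    )
    if condition_set is None:
        condition_set = tuple(dict.fromkeys(b.condition for b in blocks))
    return TaskDesign(blocks, n_timepoints, tr, tuple(condition_set))


def write_design(design: TaskDesign, path: str | Path) -> None:
    pd.DataFrame(
        [(b.condition, b.onset_s, b.duration_s) for b in design.blocks],
        columns=["condition", "onset_s", "duration_s"],
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ConfoundTable:
    """Per-frame nuisance regressors: 24 motion + 20 physiological columns.

    ``motion`` holds the raw 6 rigid-body parameters (mm) used for FD;
    ``nuisance`` holds the 44 regressor columns (24 motion-derived +
    20 physiological-component-derived).
    """

    motion: np.ndarray          # T x 6 raw parameters (mm)
    nuisance: np.ndarray        # T x 44 regressors
    fd: np.ndarray | None = None  # frame-wise displacement (mm)

    def __post_init__(self):
        self.motion = np.asarray(self.motion, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValidationError("motion must have 6 columns")
        if self.nuisance.shape[1] != N_NUISANCE_COLUMNS:
            raise ValidationError(
                f"expected {N_NUISANCE_COLUMNS} nuisance columns, "
                f"got {self.nuisance.shape[1]}"
            )
        if self.nuisance.shape[0] != self.motion.shape[0]:
            raise ValidationError("motion and nuisance row counts differ")
        _check_finite(self.motion, "motion parameters")
        _check_finite(self.nuisance, "nuisance regressors")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.nuisance.shape[0]


@dataclass
class ActivationMatrix:
    """Parcels x conditions GLM amplitudes (the Act_i of the flow model)."""

    betas: np.ndarray
    conditions: tuple[str, ...]

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 2:
            raise ValidationError("betas must be 2-D (parcels x conditions)")
        if self.betas.shape[1] != len(self.conditions):
            raise ValidationError("condition labels do not match beta columns")
        _check_finite(self.betas, "activation matrix")
        self.conditions = tuple(self.conditions)

    def column(self, condition: str) -> np.ndarray:
        return self.betas[:, self.conditions.index(condition)]


@dataclass
class FCMatrix:
    """Parcels x parcels functional connectivity (zero diagonal, symmetric)."""

    values: np.ndarray
    method: str = "glasso"
    subject_id: str = ""
    session_id: str = "1"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_finite(self.values, "FC matrix")
        _check_symmetric(self.values, "FC matrix")
        if np.any(np.abs(np.diag(self.values)) > 1e-10):
            raise ValidationError("FC diagonal must be zero")
        if self.method == "glasso" and np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValidationError("glasso partial correlations must lie in [-1, 1]")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectDataset:
    """All runs for one subject: rest sessions, task runs with designs."""

    subject_id: str
    rest: dict[int, TimeSeriesMatrix]                     # session -> run
    rest_confounds: dict[int, ConfoundTable]
    tasks: dict[str, list[tuple[TimeSeriesMatrix, TaskDesign, ConfoundTable]]]
    parcels: ParcelTable

    @property
    def n_parcels(self) -> int:
        return self.parcels.n_parcels


# ---------------------------------------------------------------------------
# Generic matrix I/O
# ---------------------------------------------------------------------------

_MATRIX_KINDS = ("timeseries", "fc", "distance", "activation")


def write_matrix(values: np.ndarray, path: str | Path,
                 attrs: Mapping[str, object] | None = None) -> None:
    """Write a matrix as TSV (``.tsv``) or HDF5 (anything else)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if path.suffix == ".tsv":
        np.savetxt(path, values, delimiter="\t", fmt="%.17g")
    else:
        with h5py.File(path, "w") as h5:
            ds = h5.create_dataset("values", data=values)
            for key, val in (attrs or {}).items():
                ds.attrs[key] = val


def read_matrix(path: str | Path, kind: str,
                parcels: ParcelTable | None = None, **meta):
    """Read and validate a matrix of the given kind.

    ``kind`` is one of ``timeseries``, ``fc``, ``distance`` or ``activation``;
    the corresponding typed container is returned. Metadata not stored in the
    file (``tr`` for TSV time series, condition labels for activations) is
    supplied through ``meta``.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    path = Path(path)
    attrs: dict[str, object] = {}
    if path.suffix == ".tsv":
        values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    else:
        with h5py.File(path, "r") as h5:
            ds = h5["values"]
            values = ds[()]
            attrs = {k: v for k, v in ds.attrs.items()}
    if parcels is not None and values.shape[0] != parcels.n_parcels:
        raise ValidationError(
            f"matrix has {values.shape[0]} rows but parcel table has "
            f"{parcels.n_parcels} parcels"
        )
    if kind == "timeseries":
        tr = float(meta.get("tr", attrs.get("tr", 0.0)))
        return TimeSeriesMatrix(
            values, tr=tr,
            subject_id=str(meta.get("subject_id", attrs.get("subject_id", ""))),
            run_id=str(meta.get("run_id", attrs.get("run_id", ""))),
            state=str(meta.get("state", attrs.get("state", "rest"))),
        )
    if kind == "fc":
        return FCMatrix(
            values,
            method=str(meta.get("method", attrs.get("method", "glasso"))),
            subject_id=str(meta.get("subject_id", attrs.get("subject_id", ""))),
            session_id=str(meta.get("session_id", attrs.get("session_id", "1"))),
        )
    if kind == "distance":
        return DistanceMatrix(values)
    conditions = meta.get("conditions", attrs.get("conditions"))
    if conditions is None:
        conditions = CONDITIONS[: values.shape[1]]
    conditions = tuple(str(c) for c in np.asarray(conditions).tolist())
    return ActivationMatrix(values, conditions)


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Pass/fail record per dataset invariant."""

    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, passed: bool, message: str = "") -> None:
        self.checks.append((name, passed, message))

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.checks)

    @property
    def failures(self) -> list[tuple[str, str]]:
        return [(n, m) for n, p, m in self.checks if not p]

    def raise_if_failed(self) -> None:
        if not self.ok:
            msgs = "; ".join(f"{n}: {m}" for n, m in self.failures)
            raise ValidationError(f"dataset validation failed: {msgs}")


def validate_dataset(ds: SubjectDataset, min_rest_frames: int = 10) -> ValidationReport:
    """Check cross-container invariants of one subject's dataset."""
    report = ValidationReport()
    P = ds.n_parcels

    for session, ts in ds.rest.items():
        report.add(
            f"rest[{session}] parcels", ts.n_parcels == P,
            f"rest run has {ts.n_parcels} parcels, expected {P}",
        )
        report.add(
            f"rest[{session}] length", ts.n_timepoints >= min_rest_frames,
            f"rest run shorter than {min_rest_frames} frames",
        )
        conf = ds.rest_confounds.get(session)
        report.add(
            f"rest[{session}] confounds",
            conf is not None and conf.n_frames == ts.n_timepoints,
            "confound rows do not match rest frames",
        )

    vm_runs = ds.tasks.get("VM", [])
    report.add("VM runs", len(vm_runs) == 2, "VM requires two runs")
    for task, runs in ds.tasks.items():
        for i, (ts, design, conf) in enumerate(runs):
            report.add(
                f"{task}[{i}] parcels", ts.n_parcels == P,
                f"{task} run has {ts.n_parcels} parcels, expected {P}",
            )
            report.add(
                f"{task}[{i}] frames",
                design.n_timepoints == ts.n_timepoints
                and conf.n_frames == ts.n_timepoints,
                "design/confound frames do not match run",
            )
    return report
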
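"""Shared fixtures: tiny hand-built parcellations and small simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from vergeflow.core import ParcelTable, DistanceMatrix
from vergeflow.synth import SimConfig, simulate_cohort


def tiny_parcel_table(p: int = 10, n_ccc: int = 3, seed: int = 0) -> ParcelTable:
    """Hand-built small parcel table (a few networks, a few CCC parcels)."""
    rng = np.random.default_rng(seed)
    nets = ["VIS1", "VIS2", "CON", "DAN"]
    rows = []
    for i in range(p):
        rows.append((i + 1, f"p{i + 1}", "LR"[i % 2], nets[i % len(nets)],
                     i < n_ccc))
    return ParcelTable(pd.DataFrame(
        rows, columns=["parcel_id", "name", "hemisphere", "network", "is_ccc"]))


def tiny_distances(p: int, seed: int = 0) -> DistanceMatrix:
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 50, size=(p, 3))
    diff = coords[:, None] - coords[None, :]
    d = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d)


def loop_actflow(act: np.ndarray, fc: np.ndarray, target: int,
                 sources) -> np.ndarray:
    """Brute-force reference: explicit loop over sources and conditions."""
    out = np.zeros(act.shape[1])
    for c in range(act.shape[1]):
        s = 0.0
        for i in sources:
            s += act[i, c] * fc[i, target]
        out[c] = s
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-scale cohort (P=60, n=4) with two rest sessions."""
    cfg = SimConfig(p=60, n_subjects=4, t_rest=600, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Pure-distributed, zero-noise cohort for exact generative checks."""
    cfg = SimConfig(p=60, n_subjects=2, t_rest=150,
                    lambda_distributed=1.0, source_noise_sd=0.0,
                    ccc_noise_sd=0.0, local_noise_sd=0.0,
                    task_noise_sd=0.0, confound_strength=0.0, seed=3)
    return simulate_cohort(cfg)
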
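"""Resting-state functional connectivity estimation.

The primary estimator is regularized partial correlation via the graphical
lasso, with the L1 penalty chosen by cross-validated held-out Gaussian
log-likelihood over a log-spaced grid. Folds are contiguous blocks of
timepoints (no shuffling) to respect temporal autocorrelation, and series
are standardized first so the penalty is scale-free. Pairwise Pearson
correlation is retained as the field-standard comparison method.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.covariance import GraphicalLassoCV
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold

from .core import FCMatrix, TimeSeriesMatrix, ValidationError

__all__ = ["fc_glasso", "fc_pearson", "seed_fc_map", "default_alpha_grid"]


def default_alpha_grid(X: np.ndarray, n_alphas: int = 20) -> np.ndarray:
    """Log-spaced L1 penalty grid for standardized series.

    Spans two decades below the empirical maximum absolute off-diagonal
    correlation (the penalty at which the estimate is fully sparse), so the
    grid adapts to the data scale.
    """
    emp = X.T @ X / X.shape[0]
    amax = float(np.max(np.abs(emp - np.diag(np.diag(emp)))))
    amax = max(amax, 1e-3)
    return np.logspace(np.log10(0.01 * amax), np.log10(amax), n_alphas)


def _series(rest: TimeSeriesMatrix | np.ndarray) -> np.ndarray:
    values = rest.values if isinstance(rest, TimeSeriesMatrix) else np.asarray(rest)
    return values.astype(float)


def fc_glasso(rest: TimeSeriesMatrix | np.ndarray,
              folds: int = 5,
              alphas: Sequence[float] | int = 20,
              max_iter: int = 200,
              subject_id: str = "",
              session_id: str = "1") -> FCMatrix:
    """Graphical-lasso partial correlation with cross-validated penalty.

    Parameters
    ----------
    rest : parcels x timepoints series (denoised).
    folds : contiguous-block CV folds over timepoints (2 <= folds <= T-1).
    alphas : penalty grid, or a count for :func:`default_alpha_grid`.

    Returns the symmetric partial-correlation matrix
    ``-P_ij / sqrt(P_ii P_jj)`` with zero diagonal.
    """
    X = _series(rest).T                    # T x P
    T, P = X.shape
    if not (2 <= folds <= T - 1):
        raise ValidationError(f"folds must satisfy 2 <= folds <= T-1, got {folds}")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        parcel = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"constant series for parcel {parcel}")
    X = (X - X.mean(axis=0)) / sd

    if isinstance(alphas, int):
        alphas = default_alpha_grid(X, alphas)
    alphas = np.asarray(list(alphas), dtype=float)

    import warnings

    model = GraphicalLassoCV(
        alphas=alphas, cv=KFold(n_splits=folds, shuffle=False),
        max_iter=max_iter, n_refinements=1, assume_centered=True,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X)
    except FloatingPointError as exc:  # pragma: no cover - rare numerics
        raise ValidationError(
            f"graphical lasso failed to converge over penalty grid "
            f"{alphas.min():.4g}..{alphas.max():.4g}: {exc}"
        ) from exc

    prec = model.precision_
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    pc = 0.5 * (pc + pc.T)
    np.fill_diagonal(pc, 0.0)
    pc = np.clip(pc, -1.0, 1.0)
    return FCMatrix(pc, method="glasso", subject_id=subject_id,
                    session_id=session_id)


def fc_pearson(rest: TimeSeriesMatrix | np.ndarray,
               subject_id: str = "", session_id: str = "1") -> FCMatrix:
    """Pairwise Pearson correlation with zero diagonal."""
    X = _series(rest)
    if X.shape[1] < 3:
        raise ValidationError("need T >= 3 for Pearson FC")
    if np.any(X.std(axis=1) == 0):
        parcel = int(np.flatnonzero(X.std(axis=1) == 0)[0])
        raise ValidationError(f"constant series for parcel {parcel}")
    corr = np.corrcoef(X)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 0.0)
    return FCMatrix(corr, method="pearson", subject_id=subject_id,
                    session_id=session_id)


def seed_fc_map(fc: FCMatrix, seeds: Sequence[int]) -> np.ndarray:
    """Mean FC of every parcel to a seed set, self-connections excluded.

    At a seed parcel the value is its mean FC to the *other* seeds.
    """
    seeds = np.asarray(seeds, dtype=int)
    if seeds.size == 0:
        raise ValidationError("seed set must be non-empty")
    P = fc.n_parcels
    values = fc.values
    out = np.empty(P)
    seed_set = set(int(s) for s in seeds)
    for p in range(P):
        others = [s for s in seeds if s != p]
        # a lone seed has no other seeds; its value is 0 (the zero diagonal)
        out[p] = values[p, others].mean() if others else 0.0
    return out
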
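"""Nonparametric max-T permutation inference.

One-sample (sign-flip) and paired upper-tailed t tests with family-wise
error control by the maximum-statistic method: each permutation randomly
flips the sign of every subject's (centered) data row, the maximum t over
the variable family is recorded, and each variable's corrected p-value is
the fraction of max-null values at or above its observed t.

The p-value uses the valid (b+1)/(n_perm+1) convention; the b/n_perm form
(whose floor at 100,000 permutations is 0.00001) is reported alongside as
``p_basic``. A variable is significant iff its observed t exceeds the
(1-alpha) quantile of the max-null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError

__all__ = ["PermutationResult", "maxt_one_sample", "maxt_paired"]


@dataclass
class PermutationResult:
    """Observed statistics, max-T null summary and corrected p-values."""

    t_obs: np.ndarray            # per variable
    p: np.ndarray                # corrected, (b+1)/(n_perm+1)
    p_basic: np.ndarray          # corrected, b/n_perm (floored convention)
    threshold: float             # (1-alpha) quantile of the max-null
    alpha: float
    n_perm: int
    seed: int
    tail: str
    df: int                      # subjects - 1
    max_null: np.ndarray | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.t_obs > self.threshold

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (self.n_perm + 1)


def _t_stats(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd == 0
    if np.any(degenerate & (mean != 0)):
        var = int(np.flatnonzero(degenerate & (mean != 0))[0])
        raise ValidationError(f"zero variance in variable {var}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate] = 0.0   # constant-zero data carries no evidence
    return t


def maxt_one_sample(data: np.ndarray, mu0: float = 0.0,
                    n_perm: int = 1000, seed: int = 0,
                    alpha: float = 0.05, tail: str = "upper",
                    keep_null: bool = False) -> PermutationResult:
    """One-sample upper-tailed max-T test of subjects x variables data.

    The null is built by random sign flips of the rows of ``data - mu0``;
    the max over variables is recorded per permutation. Requires >= 3
    subjects and finite data.
    """
    if tail != "upper":
        raise ValidationError("only upper-tailed tests are implemented")
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.ndim != 2:
        raise ValidationError("data must be subjects x variables")
    n, V = x.shape
    if n < 3:
        raise ValidationError("need at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValidationError("data contains non-finite values")
    x = x - mu0
    t_obs = _t_stats(x)

    rng = np.random.default_rng(seed)
    sq_sum = (x ** 2).sum(axis=0)          # invariant under sign flips
    max_null = np.empty(n_perm)
    # chunked permutations keep memory bounded at large n_perm
    chunk = max(1, min(n_perm, 20_000_000 // max(1, n * V)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n))
        means = signs @ x / n                              # m x V
        var = (sq_sum[None, :] - n * means ** 2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = means / np.sqrt(var / n)
        t = np.where(np.isfinite(t), t,
                     np.where(means > 0, np.inf,
                              np.where(means < 0, -np.inf, 0.0)))
        max_null[done:done + m] = t.max(axis=1)
        done += m

    b = (max_null[None, :] >= t_obs[:, None]).sum(axis=1)
    p = (b + 1) / (n_perm + 1)
    p_basic = np.maximum(b / n_perm, 0.0)
    threshold = float(np.quantile(max_null, 1.0 - alpha, method="higher"))
    return PermutationResult(
        t_obs=t_obs, p=p, p_basic=p_basic, threshold=threshold, alpha=alpha,
        n_perm=n_perm, seed=seed, tail=tail, df=n - 1,
        max_null=max_null if keep_null else None,
    )


def maxt_paired(a: np.ndarray, b: np.ndarray, n_perm: int = 1000,
                seed: int = 0, alpha: float = 0.05,
                keep_null: bool = False) -> PermutationResult:
    """Paired upper-tailed max-T test: one-sample test on a - b vs 0."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValidationError("paired samples must share a shape")
    return maxt_one_sample(a - b, mu0=0.0, n_perm=n_perm, seed=seed,
                           alpha=alpha, keep_null=keep_null)
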
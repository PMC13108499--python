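"""Accuracy metrics, vergence specificity, and distributed contribution.

Mapping accuracy between generated and actual activations is summarized by
Pearson r, the coefficient of determination R^2 = 1 - SSE/SST (which may be
negative when the generated pattern is worse than the mean predictor), and
mean absolute error; each is computed per participant and then averaged for
a random-effects group estimate.

Vergence specificity is the ratio of mean VM-condition to mean VS-condition
activation after per-parcel min-max normalization, computed per hemisphere
over the circuit's four parcels; its null value is 1. The distributed
contribution is 100 * (generated specificity / actual specificity), tested
against a 50% null downstream. Outliers are flagged by the median-absolute-
deviation rule with a conservative +/-5 threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from .core import (
    CONDITIONS,
    HEMISPHERES,
    VM_CONDITIONS,
    VS_CONDITIONS,
    ActivationMatrix,
    ParcelTable,
    ValidationError,
)
from .actflow import FlowResult

__all__ = [
    "AccuracyReport",
    "SpecificityRecord",
    "accuracy",
    "minmax_normalize",
    "vergence_specificity",
    "distributed_contribution",
    "mad_outliers",
    "specificity_records",
    "apply_outlier_union",
]

MAD_SCALE = 1.4826  # consistency constant for normal data


@dataclass
class AccuracyReport:
    """Per-subject and group-mean mapping accuracy."""

    level: str
    pearson_r: list[float] = field(default_factory=list)
    r_squared: list[float] = field(default_factory=list)
    mae: list[float] = field(default_factory=list)
    degenerate: list[bool] = field(default_factory=list)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.pearson_r))

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r_squared))

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.mae))

    def summary(self) -> dict[str, float]:
        return {"r": self.mean_r, "r2": self.mean_r2, "mae": self.mean_mae,
                "n": len(self.pearson_r)}


def _metrics(actual: np.ndarray, generated: np.ndarray
             ) -> tuple[float, float, float, bool]:
    a = np.asarray(actual, dtype=float).ravel(order="C")
    g = np.asarray(generated, dtype=float).ravel(order="C")
    if a.shape != g.shape:
        raise ValidationError("actual and generated shapes differ")
    sst = float(np.sum((a - a.mean()) ** 2))
    degenerate = sst == 0.0
    if degenerate:
        r = 1.0 if np.allclose(a, g) else 0.0
        r2 = 1.0 if np.allclose(a, g) else -np.inf
    else:
        sse = float(np.sum((a - g) ** 2))
        r2 = 1.0 - sse / sst
        r = 0.0 if g.std() == 0 else float(np.corrcoef(a, g)[0, 1])
    mae = float(np.mean(np.abs(a - g)))
    return r, r2, mae, degenerate


def accuracy(actual, generated, level: str = "whole_model") -> AccuracyReport:
    """Compare actual and generated activations, per subject then averaged.

    ``actual``/``generated`` are either single matrices (one subject) or
    equal-length sequences of matrices. Flattening is parcels-major,
    conditions-minor. Zero-variance actual data is flagged degenerate.
    """
    if isinstance(actual, (np.ndarray, ActivationMatrix)):
        actual, generated = [actual], [generated]
    report = AccuracyReport(level=level)
    for a, g in zip(actual, generated, strict=True):
        a = a.betas if isinstance(a, ActivationMatrix) else a
        g = g.betas if isinstance(g, ActivationMatrix) else g
        r, r2, mae, degen = _metrics(a, g)
        report.pearson_r.append(r)
        report.r_squared.append(r2)
        report.mae.append(mae)
        report.degenerate.append(degen)
    return report


def minmax_normalize(actual_profile: np.ndarray, generated_profile: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Rescale a parcel's condition profiles by the actual profile's range.

    The actual profile maps onto [0, 1] by its own min/max; the generated
    profile is rescaled with the *same* min/max (values outside [0, 1] are
    retained, not clamped). A constant actual profile is flagged degenerate
    and must be excluded from specificity.
    """
    a = np.asarray(actual_profile, dtype=float)
    g = np.asarray(generated_profile, dtype=float)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return a, g, True
    return (a - lo) / (hi - lo), (g - lo) / (hi - lo), False


@dataclass
class SpecificityRecord:
    """Per subject and hemisphere: specificity indices and contribution."""

    subject: str
    hemisphere: str
    spec_actual: float
    spec_generated: float
    contribution_pct: float
    valid: bool = True
    outlier: bool = False
    note: str = ""


def _mean_over(profiles: np.ndarray, conditions: tuple[str, ...],
               which: tuple[str, ...]) -> float:
    idx = [conditions.index(c) for c in which]
    return float(profiles[:, idx].mean())


def vergence_specificity(actual_profiles: np.ndarray,
                         generated_profiles: np.ndarray,
                         conditions: tuple[str, ...] = CONDITIONS,
                         subject: str = "", hemisphere: str = ""
                         ) -> SpecificityRecord:
    """Specificity indices for one hemisphere's four circuit parcels.

    ``actual_profiles``/``generated_profiles`` are parcels x conditions.
    Each parcel is min-max normalized by its actual range; VM-bar and VS-bar
    then average the VM / VS conditions over the surviving parcels, and the
    index is VM-bar / VS-bar for actual and generated separately.
    """
    a_norm, g_norm = [], []
    for ap, gp in zip(actual_profiles, generated_profiles, strict=True):
        an, gn, degen = minmax_normalize(ap, gp)
        if degen:
            continue
        a_norm.append(an)
        g_norm.append(gn)
    if not a_norm:
        return SpecificityRecord(subject, hemisphere, np.nan, np.nan, np.nan,
                                 valid=False, note="all parcels degenerate")
    a_norm = np.asarray(a_norm)
    g_norm = np.asarray(g_norm)
    vm_a = _mean_over(a_norm, conditions, VM_CONDITIONS)
    vs_a = _mean_over(a_norm, conditions, VS_CONDITIONS)
    vm_g = _mean_over(g_norm, conditions, VM_CONDITIONS)
    vs_g = _mean_over(g_norm, conditions, VS_CONDITIONS)
    if vs_a <= 0 or vs_g <= 0:
        logger.warning(
            "non-positive VS mean for %s/%s; record excluded",
            subject, hemisphere)
        return SpecificityRecord(subject, hemisphere, np.nan, np.nan, np.nan,
                                 valid=False, note="non-positive VS mean")
    spec_a = vm_a / vs_a
    spec_g = vm_g / vs_g
    contribution = distributed_contribution(spec_a, spec_g)
    return SpecificityRecord(subject, hemisphere, spec_a, spec_g, contribution)


def distributed_contribution(spec_actual: float, spec_generated: float) -> float:
    """Percentage of actual specificity explained by generated specificity."""
    if not np.isfinite(spec_actual) or not np.isfinite(spec_generated):
        raise ValidationError("specificity indices must be finite")
    if spec_actual <= 0:
        raise ValidationError("actual specificity must be positive")
    return 100.0 * spec_generated / spec_actual


def mad_outliers(values: np.ndarray, k: float = 5.0
                 ) -> tuple[np.ndarray, int]:
    """Median-absolute-deviation outlier mask and surviving count.

    Flags ``|x - median| > k * 1.4826 * MAD``. When MAD is zero the rule is
    degenerate; nothing is flagged and a warning is issued.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValidationError("need at least 3 values for outlier detection")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged", stacklevel=2)
        mask = np.zeros(values.size, dtype=bool)
    else:
        mask = np.abs(values - med) > k * MAD_SCALE * mad
    return mask, int((~mask).sum())


# ---------------------------------------------------------------------------
# Cohort-level helpers
# ---------------------------------------------------------------------------

def specificity_records(actuals: dict[str, ActivationMatrix],
                        flows: dict[str, FlowResult],
                        parcels: ParcelTable) -> list[SpecificityRecord]:
    """Per-subject, per-hemisphere specificity over the circuit parcels."""
    records = []
    for sid, act in actuals.items():
        flow = flows[sid]
        for hemi in HEMISPHERES:
            idx = parcels.ccc_indices_hemi(hemi)
            a = act.betas[idx]
            g = np.stack([flow.row(int(j)) for j in idx])
            records.append(vergence_specificity(a, g, act.conditions,
                                                subject=sid, hemisphere=hemi))
    return records


def apply_outlier_union(records: list[SpecificityRecord], k: float = 5.0
                        ) -> list[SpecificityRecord]:
    """Flag MAD outliers per hemisphere, unioned over actual and generated.

    A subject flagged in either its actual or generated specificity is
    marked an outlier for that hemisphere (hemispheres are independent,
    matching the per-hemisphere degrees of freedom of the analysis).
    """
    for hemi in HEMISPHERES:
        recs = [r for r in records if r.hemisphere == hemi and r.valid]
        if len(recs) < 3:
            continue
        mask_a, _ = mad_outliers(np.array([r.spec_actual for r in recs]), k)
        mask_g, _ = mad_outliers(np.array([r.spec_generated for r in recs]), k)
        for r, oa, og in zip(recs, mask_a, mask_g):
            r.outlier = bool(oa or og)
    return records
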
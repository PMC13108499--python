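"""The activity-flow engine.

A held-out region's task activation is generated as the connectivity-weighted
sum of source-region activations::

    FlowAct_j,c = sum_{i in sources(j)} Act_i,c * FC_ij

Source-selection policies cover every variant of the analysis: hold out the
target only, hold out the full 8-parcel convergence circuit (the default for
all headline results), additionally exclude parcels within a spatial radius
of the target, restrict sources to chosen networks (condensed submodels),
partition sources by network (the 12 components summing exactly to the full
model), circulate a second flow step inside the circuit, initiate flow from
V1 alone, or draw matched-size random subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    NETWORKS,
    ActivationMatrix,
    DistanceMatrix,
    FCMatrix,
    ParcelTable,
    ValidationError,
)

__all__ = [
    "SourcePolicy",
    "FlowResult",
    "resolve_sources",
    "actflow_generate",
    "network_partitioned_generate",
    "secondary_circulation",
    "v1_initiated",
    "random_subnetwork_draws",
]

_MODES = ("target_only", "exclude_ccc", "exclude_ccc_radius")


@dataclass(frozen=True)
class SourcePolicy:
    """Which parcels may serve as flow sources for a given target."""

    mode: str = "exclude_ccc"
    radius_mm: float | None = None
    allowed_networks: frozenset[str] | None = None
    explicit_sources: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValidationError(f"unknown policy mode {self.mode!r}")
        if (self.mode == "exclude_ccc_radius") != (self.radius_mm is not None):
            raise ValidationError(
                "radius_mm is required exactly when mode='exclude_ccc_radius'"
            )
        if self.allowed_networks is not None:
            object.__setattr__(self, "allowed_networks",
                               frozenset(self.allowed_networks))
            bad = self.allowed_networks - set(NETWORKS)
            if bad:
                raise ValidationError(f"unknown network(s) in policy: {sorted(bad)}")
        if self.explicit_sources is not None:
            object.__setattr__(self, "explicit_sources",
                               tuple(int(i) for i in self.explicit_sources))


def resolve_sources(target: int, policy: SourcePolicy, parcels: ParcelTable,
                    dist: DistanceMatrix | None = None) -> np.ndarray:
    """Source parcel indices for one target under a policy.

    The target itself is always excluded; ``exclude_ccc`` removes all CCC
    parcels; the radius mode additionally removes parcels strictly within
    ``radius_mm`` of the target; ``allowed_networks`` then intersects the
    remainder. Raises on an empty source set.
    """
    P = parcels.n_parcels
    if not (0 <= target < P):
        raise ValidationError(f"target {target} outside parcel range")
    if policy.explicit_sources is not None:
        keep = np.zeros(P, dtype=bool)
        keep[list(policy.explicit_sources)] = True
    else:
        keep = np.ones(P, dtype=bool)
    keep[target] = False
    if policy.mode in ("exclude_ccc", "exclude_ccc_radius"):
        keep[parcels.ccc_indices] = False
    if policy.mode == "exclude_ccc_radius":
        if dist is None:
            raise ValidationError("radius policy requires a distance matrix")
        keep[dist.values[target] < policy.radius_mm] = False
        keep[target] = False
    if policy.allowed_networks is not None:
        keep &= np.isin(parcels.networks, list(policy.allowed_networks))
    sources = np.flatnonzero(keep)
    if sources.size == 0:
        raise ValidationError(f"empty source set for target {target}")
    return sources


@dataclass
class FlowResult:
    """Generated activations plus the per-source flow terms behind them."""

    targets: np.ndarray                    # target parcel indices
    conditions: tuple[str, ...]
    generated: np.ndarray                  # targets x conditions
    source_indices: list[np.ndarray]       # per target
    flow_terms: list[np.ndarray]           # per target: sources x conditions
    policy: SourcePolicy | None = None

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=int)
        self.generated = np.asarray(self.generated, dtype=float)

    def row(self, target: int) -> np.ndarray:
        """Generated condition vector for one target parcel."""
        pos = int(np.flatnonzero(self.targets == target)[0])
        return self.generated[pos]

    def check_conservation(self, tol: float = 1e-10) -> None:
        for pos in range(len(self.targets)):
            total = self.flow_terms[pos].sum(axis=0)
            if np.max(np.abs(total - self.generated[pos])) > tol:
                raise ValidationError("flow terms do not sum to generated value")


def actflow_generate(act: ActivationMatrix, fc: FCMatrix,
                     targets: Sequence[int], policy: SourcePolicy,
                     parcels: ParcelTable,
                     dist: DistanceMatrix | None = None) -> FlowResult:
    """Generate target activations by summing FC-weighted source activations."""
    if act.betas.shape[0] != fc.n_parcels:
        raise ValidationError("activation and FC parcel counts differ")
    targets = np.asarray(targets, dtype=int)
    generated = np.zeros((targets.size, act.betas.shape[1]))
    src_list, term_list = [], []
    for pos, j in enumerate(targets):
        sources = resolve_sources(int(j), policy, parcels, dist)
        terms = act.betas[sources] * fc.values[sources, j][:, None]
        generated[pos] = terms.sum(axis=0)
        src_list.append(sources)
        term_list.append(terms)
    return FlowResult(targets, act.conditions, generated, src_list,
                      term_list, policy)


def network_partitioned_generate(act: ActivationMatrix, fc: FCMatrix,
                                 targets: Sequence[int], policy: SourcePolicy,
                                 parcels: ParcelTable,
                                 dist: DistanceMatrix | None = None
                                 ) -> dict[str, FlowResult]:
    """One FlowResult per network, sources restricted to that network.

    The element-wise sum of the 12 components equals the unrestricted model
    (a network emptied by the policy contributes zeros).
    """
    targets = np.asarray(targets, dtype=int)
    out: dict[str, FlowResult] = {}
    for net in NETWORKS:
        if policy.allowed_networks is not None:
            allowed = policy.allowed_networks & {net}
        else:
            allowed = frozenset({net})
        generated = np.zeros((targets.size, act.betas.shape[1]))
        srcs, terms_l = [], []
        for pos, j in enumerate(targets):
            if allowed:
                net_policy = SourcePolicy(
                    mode=policy.mode, radius_mm=policy.radius_mm,
                    allowed_networks=allowed,
                    explicit_sources=policy.explicit_sources)
                try:
                    sources = resolve_sources(int(j), net_policy, parcels, dist)
                except ValidationError:
                    sources = np.empty(0, dtype=int)
            else:
                sources = np.empty(0, dtype=int)
            t = act.betas[sources] * fc.values[sources, j][:, None]
            generated[pos] = t.sum(axis=0)
            srcs.append(sources)
            terms_l.append(t)
        out[net] = FlowResult(targets, act.conditions, generated, srcs,
                              terms_l, policy)
    return out


def secondary_circulation(gen1: FlowResult, fc: FCMatrix,
                          parcels: ParcelTable) -> FlowResult:
    """One round of within-circuit flow applied to generated activations.

    Each CCC target is regenerated from the other seven CCC parcels'
    first-round generated activations, weighted by FC; only the target is
    held out (full-circuit holdout is impossible inside the circuit).
    """
    ccc = parcels.ccc_indices
    missing = np.setdiff1d(ccc, gen1.targets)
    if missing.size:
        raise ValidationError("first-round result must cover all CCC parcels")
    gen1_by_parcel = {int(t): gen1.row(int(t)) for t in ccc}
    generated = np.zeros((ccc.size, len(gen1.conditions)))
    srcs, terms_l = [], []
    for pos, j in enumerate(ccc):
        sources = np.array([i for i in ccc if i != j], dtype=int)
        terms = np.stack([gen1_by_parcel[int(i)] * fc.values[i, j]
                          for i in sources])
        generated[pos] = terms.sum(axis=0)
        srcs.append(sources)
        terms_l.append(terms)
    return FlowResult(ccc, gen1.conditions, generated, srcs, terms_l, None)


def v1_initiated(act: ActivationMatrix, fc: FCMatrix,
                 parcels: ParcelTable) -> FlowResult:
    """Flow initiated from mean-centered V1 activations only.

    Each V1's condition vector is centered to mean zero across conditions.
    The six non-V1 circuit targets receive flow from both V1s; each V1
    target receives flow from the contralateral V1 alone.
    """
    v1 = parcels.v1_indices()            # [left, right]
    ccc = parcels.ccc_indices
    centered = {int(v): act.betas[v] - act.betas[v].mean() for v in v1}
    generated = np.zeros((ccc.size, len(act.conditions)))
    srcs, terms_l = [], []
    for pos, j in enumerate(ccc):
        if j in v1:
            sources = np.array([int(v) for v in v1 if v != j], dtype=int)
        else:
            sources = np.asarray(v1, dtype=int)
        terms = np.stack([centered[int(i)] * fc.values[i, j] for i in sources])
        generated[pos] = terms.sum(axis=0)
        srcs.append(sources)
        terms_l.append(terms)
    return FlowResult(ccc, act.conditions, generated, srcs, terms_l, None)


def random_subnetwork_draws(size: int, excluded_networks: Iterable[str],
                            n_draws: int, seed: int,
                            parcels: ParcelTable) -> list[np.ndarray]:
    """Matched-size random source sets excluding given networks and the CCC."""
    excluded = set(excluded_networks)
    bad = excluded - set(NETWORKS)
    if bad:
        raise ValidationError(f"unknown excluded network(s): {sorted(bad)}")
    eligible = np.flatnonzero(
        ~np.isin(parcels.networks, list(excluded)) & ~parcels.is_ccc
    )
    if size > eligible.size:
        raise ValidationError(
            f"requested {size} parcels but only {eligible.size} eligible"
        )
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(eligible, size=size, replace=False))
            for _ in range(n_draws)]
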
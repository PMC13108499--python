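"""Network-level contribution statistics.

Flow terms arriving at the convergence circuit are aggregated by the source
parcel's network (mean over the network's parcels, avoiding network-size
bias), ranked by pairwise max-T comparisons, decomposed by general dominance
analysis over all 2^12 - 1 subset regressions, contrasted between VM and VS
conditions, and compared against condensed submodels and matched-size random
subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .actflow import (
    FlowResult,
    SourcePolicy,
    actflow_generate,
    network_partitioned_generate,
    random_subnetwork_draws,
    v1_initiated,
)
from .core import (
    CONDITIONS,
    HEMISPHERES,
    NETWORKS,
    VM_CONDITIONS,
    VS_CONDITIONS,
    ActivationMatrix,
    FCMatrix,
    ParcelTable,
    ValidationError,
)
from .evaluate import _metrics, vergence_specificity
from .permtest import PermutationResult, maxt_one_sample, maxt_paired

__all__ = [
    "NetworkContribution",
    "DominanceResult",
    "network_flow_contributions",
    "rank_networks",
    "contrast_flows",
    "parcel_flow_matrix",
    "dominance",
    "SUBMODELS",
    "compare_submodels",
]

#: Condensed submodels: allowed source networks per model name.
SUBMODELS: dict[str, tuple[str, ...]] = {
    "VIS-CON-DAN": ("VIS1", "VIS2", "CON", "DAN"),
    "VIS-CON": ("VIS1", "VIS2", "CON"),
    "VIS-DAN": ("VIS1", "VIS2", "DAN"),
    "VIS-Only": ("VIS1", "VIS2"),
    "DAN-Only": ("DAN",),
}

_SCOPES = {"vm": VM_CONDITIONS, "vs": VS_CONDITIONS, "all": CONDITIONS}


@dataclass
class NetworkContribution:
    """Mean network-level flow into the circuit per subject and hemisphere."""

    subjects: list[str]
    scope: str
    values: dict[str, np.ndarray]   # hemisphere -> subjects x 12 networks

    def array(self, hemisphere: str) -> np.ndarray:
        return self.values[hemisphere]


def _flow_contribution_one(flow: FlowResult, parcels: ParcelTable,
                           hemisphere: str, scope: str) -> np.ndarray:
    """12-vector of mean flows into one hemisphere's circuit parcels."""
    conds = _SCOPES[scope]
    cond_idx = [flow.conditions.index(c) for c in conds]
    targets = parcels.ccc_indices_hemi(hemisphere)
    nets = parcels.networks
    out = np.zeros(len(NETWORKS))
    for ni, net in enumerate(NETWORKS):
        per_target = []
        for j in targets:
            pos = int(np.flatnonzero(flow.targets == j)[0])
            sources = flow.source_indices[pos]
            terms = flow.flow_terms[pos]
            mask = nets[sources] == net
            if mask.any():
                per_target.append(terms[mask][:, cond_idx].mean())
            else:
                per_target.append(0.0)
        out[ni] = float(np.mean(per_target))
    return out


def network_flow_contributions(flows: dict[str, FlowResult],
                               parcels: ParcelTable,
                               scope: str = "vm") -> NetworkContribution:
    """Aggregate flow terms by source network, per subject and hemisphere.

    For each circuit target, flow terms are averaged over the source parcels
    of each network; values are then averaged over the hemisphere's targets
    and over the scoped conditions (``vm``, ``vs`` or ``all``).
    """
    if scope not in _SCOPES:
        raise ValidationError(f"unknown condition scope {scope!r}")
    subjects = list(flows)
    values = {
        hemi: np.stack([
            _flow_contribution_one(flows[s], parcels, hemi, scope)
            for s in subjects
        ])
        for hemi in HEMISPHERES
    }
    return NetworkContribution(subjects, scope, values)


@dataclass
class NetworkRanking:
    """Pairwise max-T wins per network and the implied ordering."""

    networks: tuple[str, ...]
    wins: np.ndarray                 # significant comparisons out of 11
    mean_t: np.ndarray               # mean pairwise t per network
    order: list[str]                 # descending by wins then mean t
    pairwise: PermutationResult


def rank_networks(contrib: np.ndarray, n_perm: int = 1000,
                  seed: int = 0, alpha: float = 0.05) -> NetworkRanking:
    """Rank 12 networks by significant pairwise comparisons out of 11.

    ``contrib`` is subjects x 12. All ordered pairs form one max-T family
    (upper-tailed paired tests); each network's rank statistic is its count
    of significant wins, tie-broken by its mean pairwise t.
    """
    contrib = np.asarray(contrib, dtype=float)
    if contrib.shape[1] != len(NETWORKS):
        raise ValidationError("contribution matrix must have 12 columns")
    pairs = [(i, j) for i in range(len(NETWORKS))
             for j in range(len(NETWORKS)) if i != j]
    diffs = np.stack([contrib[:, i] - contrib[:, j] for i, j in pairs], axis=1)
    result = maxt_one_sample(diffs, mu0=0.0, n_perm=n_perm, seed=seed,
                             alpha=alpha)
    wins = np.zeros(len(NETWORKS), dtype=int)
    t_sums = np.zeros(len(NETWORKS))
    for (i, j), t, sig in zip(pairs, result.t_obs, result.significant):
        t_sums[i] += t
        if sig:
            wins[i] += 1
    mean_t = t_sums / (len(NETWORKS) - 1)
    order_idx = sorted(range(len(NETWORKS)),
                       key=lambda k: (wins[k], mean_t[k]), reverse=True)
    return NetworkRanking(NETWORKS, wins, mean_t,
                          [NETWORKS[k] for k in order_idx], result)


def parcel_flow_matrix(flows: dict[str, "FlowResult"], parcels: ParcelTable,
                       scope: str = "vm") -> tuple[np.ndarray, list[int]]:
    """Subjects x source-parcels mean flow into the circuit.

    The family is the non-circuit parcels (circuit parcels carry no flow
    terms into themselves); each entry is the mean of a source parcel's
    flow terms over the circuit targets and the scoped conditions.
    """
    if scope not in _SCOPES:
        raise ValidationError(f"unknown condition scope {scope!r}")
    conds = _SCOPES[scope]
    ccc = set(int(j) for j in parcels.ccc_indices)
    source_parcels = [p for p in range(parcels.n_parcels) if p not in ccc]
    col = {p: k for k, p in enumerate(source_parcels)}
    subjects = list(flows)
    out = np.zeros((len(subjects), len(source_parcels)))
    counts = np.zeros((len(subjects), len(source_parcels)))
    for si, sid in enumerate(subjects):
        flow = flows[sid]
        cond_idx = [flow.conditions.index(c) for c in conds]
        for pos in range(len(flow.targets)):
            if int(flow.targets[pos]) not in ccc:
                continue
            for k, src in enumerate(flow.source_indices[pos]):
                if int(src) in ccc:
                    continue
                j = col[int(src)]
                out[si, j] += flow.flow_terms[pos][k, cond_idx].mean()
                counts[si, j] += 1
    out = np.divide(out, counts, out=np.zeros_like(out), where=counts > 0)
    return out, source_parcels


def contrast_flows(flows_vm: np.ndarray, flows_vs: np.ndarray,
                   level: str = "network", n_perm: int = 1000,
                   seed: int = 0, alpha: float = 0.05,
                   labels: list[str] | None = None) -> PermutationResult:
    """Paired upper-tailed max-T contrast of VM vs VS flows.

    ``flows_vm``/``flows_vs`` are subjects x variables (12 networks, or the
    non-circuit source parcels for the parcel level).
    """
    if level not in ("network", "parcel"):
        raise ValidationError("level must be 'network' or 'parcel'")
    return maxt_paired(flows_vm, flows_vs, n_perm=n_perm, seed=seed,
                       alpha=alpha)


# ---------------------------------------------------------------------------
# Dominance analysis
# ---------------------------------------------------------------------------

@dataclass
class DominanceResult:
    """General-dominance R^2 decomposition over all predictor subsets."""

    predictors: tuple[str, ...]
    partial_r2: np.ndarray
    full_r2: float
    n_subsets: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.predictors, self.partial_r2.tolist()))


def _subset_r2(y: np.ndarray, X: np.ndarray) -> dict[int, float]:
    """R^2 (with intercept) for every nonempty predictor subset, by bitmask."""
    n, K = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sst = float(yc @ yc)
    G = Xc.T @ Xc
    c = Xc.T @ yc
    r2: dict[int, float] = {}
    for size in range(1, K + 1):
        for subset in combinations(range(K), size):
            idx = list(subset)
            Gs = G[np.ix_(idx, idx)]
            cs = c[idx]
            try:
                beta = np.linalg.solve(Gs, cs)
            except np.linalg.LinAlgError:
                beta, *_ = np.linalg.lstsq(Gs, cs, rcond=None)
            ess = float(cs @ beta)
            mask = 0
            for k in idx:
                mask |= 1 << k
            r2[mask] = ess / sst if sst > 0 else 0.0
    return r2


def dominance(y: np.ndarray, X: np.ndarray,
              predictors: tuple[str, ...] = NETWORKS) -> DominanceResult:
    """General dominance: size-conditional average incremental R^2.

    For each predictor k, the incremental R^2 of adding k is averaged over
    all subsets lacking k within each subset size, then averaged over sizes
    (the empty model contributes R^2 = 0). With this size-conditional
    weighting the partial values sum exactly to the full-model R^2.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, K = X.shape
    if len(predictors) != K:
        raise ValidationError("predictor names do not match columns")
    if y.shape[0] != n:
        raise ValidationError("response length does not match predictors")
    import warnings as _warnings

    if np.linalg.matrix_rank(X - X.mean(0)) < K:
        _warnings.warn("rank-deficient predictor matrix; least-norm fits used",
                       stacklevel=2)
    r2 = _subset_r2(y, X)
    full_mask = (1 << K) - 1
    full_r2 = r2[full_mask]

    partial = np.zeros(K)
    for k in range(K):
        bit = 1 << k
        by_size: dict[int, list[float]] = {s: [] for s in range(K)}
        by_size[0].append(r2[bit])               # increment over empty model
        for mask, val in r2.items():
            if mask & bit:
                continue
            size = bin(mask).count("1")
            by_size[size].append(r2[mask | bit] - val)
        partial[k] = np.mean([np.mean(v) for v in by_size.values() if v])
    return DominanceResult(tuple(predictors), partial, full_r2, len(r2))


# ---------------------------------------------------------------------------
# Submodel comparison
# ---------------------------------------------------------------------------

@dataclass
class SubmodelEntry:
    name: str
    r2: dict[str, float]                      # hemisphere -> pooled R^2
    specificity_t: dict[str, float]           # hemisphere -> generated-spec t
    random_r2: dict[str, list[float]] = field(default_factory=dict)


def _response_profile_r2(actuals: dict[str, ActivationMatrix],
                         flows: dict[str, FlowResult],
                         parcels: ParcelTable, hemisphere: str) -> float:
    """Pooled R^2 over held-out regions, conditions and participants."""
    idx = parcels.ccc_indices_hemi(hemisphere)
    a_all, g_all = [], []
    for sid, act in actuals.items():
        flow = flows[sid]
        a_all.append(act.betas[idx])
        g_all.append(np.stack([flow.row(int(j)) for j in idx]))
    _, r2, _, _ = _metrics(np.concatenate(a_all), np.concatenate(g_all))
    return r2


def _generated_spec_t(actuals: dict[str, ActivationMatrix],
                      flows: dict[str, FlowResult], parcels: ParcelTable,
                      hemisphere: str, n_perm: int, seed: int) -> float:
    specs = []
    for sid, act in actuals.items():
        idx = parcels.ccc_indices_hemi(hemisphere)
        rec = vergence_specificity(
            act.betas[idx],
            np.stack([flows[sid].row(int(j)) for j in idx]),
            act.conditions, subject=sid, hemisphere=hemisphere)
        if rec.valid:
            specs.append(rec.spec_generated)
    if len(specs) < 3:
        return float("nan")
    result = maxt_one_sample(np.asarray(specs)[:, None], mu0=1.0,
                             n_perm=n_perm, seed=seed)
    return float(result.t_obs[0])


def compare_submodels(actuals: dict[str, ActivationMatrix],
                      fcs: dict[str, FCMatrix], parcels: ParcelTable,
                      n_perm: int = 1000, seed: int = 0,
                      n_random_draws: int = 0) -> list[SubmodelEntry]:
    """Response-profile R^2 and specificity t per submodel.

    Evaluates the full circuit-holdout model, the five condensed network
    submodels, and the V1-initiated model; optionally each network submodel
    is compared against matched-size random subnetworks (drawn outside the
    model's networks and the circuit).
    """
    ccc = parcels.ccc_indices
    entries: list[SubmodelEntry] = []

    def flows_for(policy: SourcePolicy) -> dict[str, FlowResult]:
        return {sid: actflow_generate(actuals[sid], fcs[sid], ccc, policy,
                                      parcels)
                for sid in actuals}

    def entry_from_flows(name: str, flows: dict[str, FlowResult]
                         ) -> SubmodelEntry:
        r2 = {h: _response_profile_r2(actuals, flows, parcels, h)
              for h in HEMISPHERES}
        spec_t = {h: _generated_spec_t(actuals, flows, parcels, h,
                                       n_perm, seed)
                  for h in HEMISPHERES}
        return SubmodelEntry(name, r2, spec_t)

    entries.append(entry_from_flows(
        "full", flows_for(SourcePolicy(mode="exclude_ccc"))))

    rng = np.random.default_rng(seed)
    for name, networks in SUBMODELS.items():
        policy = SourcePolicy(mode="exclude_ccc",
                              allowed_networks=frozenset(networks))
        entry = entry_from_flows(name, flows_for(policy))
        if n_random_draws > 0:
            size = len(resolve_submodel_sources(parcels, networks))
            draws = random_subnetwork_draws(
                size, networks, n_random_draws,
                int(rng.integers(2 ** 31)), parcels)
            for hemi in HEMISPHERES:
                entry.random_r2[hemi] = []
            for draw in draws:
                policy_r = SourcePolicy(mode="exclude_ccc",
                                        explicit_sources=tuple(draw))
                flows_r = flows_for(policy_r)
                for hemi in HEMISPHERES:
                    entry.random_r2[hemi].append(
                        _response_profile_r2(actuals, flows_r, parcels, hemi))
        entries.append(entry)

    v1_flows = {sid: v1_initiated(actuals[sid], fcs[sid], parcels)
                for sid in actuals}
    entries.append(entry_from_flows("V1-initiated", v1_flows))
    return entries


def resolve_submodel_sources(parcels: ParcelTable,
                             networks: tuple[str, ...]) -> np.ndarray:
    """Non-circuit parcels belonging to a submodel's networks."""
    return np.flatnonzero(
        np.isin(parcels.networks, list(networks)) & ~parcels.is_ccc
    )
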
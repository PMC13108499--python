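"""Source policies and the flow-generation engine vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vergeflow.core import ActivationMatrix, CONDITIONS, FCMatrix, ValidationError
from vergeflow.actflow import (
    SourcePolicy,
    actflow_generate,
    network_partitioned_generate,
    random_subnetwork_draws,
    resolve_sources,
    secondary_circulation,
    v1_initiated,
)
from vergeflow.synth import make_parcellation

from conftest import loop_actflow, tiny_distances, tiny_parcel_table


def random_instance(p=10, n_ccc=3, seed=0, conditions=4):
    rng = np.random.default_rng(seed)
    parcels = tiny_parcel_table(p, n_ccc)
    dist = tiny_distances(p, seed)
    fc = rng.uniform(-0.6, 0.6, (p, p))
    fc = 0.5 * (fc + fc.T)
    np.fill_diagonal(fc, 0.0)
    act = rng.standard_normal((p, conditions))
    return (parcels, dist,
            FCMatrix(fc, method="glasso"),
            ActivationMatrix(act, CONDITIONS[:conditions]))


class TestResolveSources:
    def test_counts_at_full_scale(self):
        parcels, dist = make_parcellation(360, seed=0)
        policy = SourcePolicy(mode="exclude_ccc")
        non_ccc = int(np.setdiff1d(np.arange(360), parcels.ccc_indices)[0])
        assert resolve_sources(non_ccc, policy, parcels).size == 351
        ccc = int(parcels.ccc_indices[0])
        assert resolve_sources(ccc, policy, parcels).size == 352

    def test_small_radius_equals_plain_holdout(self):
        parcels, dist = make_parcellation(60, seed=1)
        scaled = type(dist)(dist.values + 20.0 * (1 - np.eye(60)))
        a = resolve_sources(5, SourcePolicy(mode="exclude_ccc"), parcels)
        b = resolve_sources(
            5, SourcePolicy(mode="exclude_ccc_radius", radius_mm=10.0),
            parcels, scaled)
        assert np.array_equal(a, b)

    def test_radius_requires_distances(self):
        parcels, _ = make_parcellation(60, seed=1)
        with pytest.raises(ValidationError):
            resolve_sources(0, SourcePolicy(mode="exclude_ccc_radius",
                                            radius_mm=10.0), parcels)

    def test_radius_field_consistency(self):
        with pytest.raises(ValidationError):
            SourcePolicy(mode="exclude_ccc_radius")
        with pytest.raises(ValidationError):
            SourcePolicy(mode="exclude_ccc", radius_mm=5.0)

    def test_empty_source_set_rejected(self):
        parcels = tiny_parcel_table(6, n_ccc=3)
        with pytest.raises(ValidationError, match="empty source"):
            resolve_sources(0, SourcePolicy(mode="exclude_ccc",
                                            allowed_networks=frozenset({"AUD"})),
                            parcels)


class TestActflowGenerate:
    def test_zero_fc_gives_zero(self):
        parcels, dist, fc, act = random_instance(seed=1)
        zero = FCMatrix(np.zeros_like(fc.values), method="glasso")
        flow = actflow_generate(act, zero, [0, 4], SourcePolicy("target_only"),
                                parcels)
        assert np.all(flow.generated == 0)

    def test_hand_computed_three_parcels(self):
        parcels = tiny_parcel_table(3, n_ccc=0)
        fc = np.zeros((3, 3))
        fc[0, 1] = fc[1, 0] = 0.5
        fcm = FCMatrix(fc, method="glasso")
        act = ActivationMatrix(np.array([[1.0], [2.0], [3.0]]),
                               (CONDITIONS[0],))
        flow = actflow_generate(act, fcm, [0, 1, 2],
                                SourcePolicy("target_only"), parcels)
        assert flow.generated[:, 0] == pytest.approx([1.0, 0.5, 0.0])

    @pytest.mark.parametrize("policy", [
        SourcePolicy("target_only"),
        SourcePolicy("exclude_ccc"),
        SourcePolicy("exclude_ccc_radius", radius_mm=15.0),
        SourcePolicy("exclude_ccc", allowed_networks=frozenset({"VIS1", "DAN"})),
        SourcePolicy("target_only", explicit_sources=(2, 5, 7, 8)),
    ])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_loop_oracle_exactly(self, policy, seed):
        parcels, dist, fc, act = random_instance(p=10, seed=seed)
        targets = np.arange(10)
        flow = actflow_generate(act, fc, targets, policy, parcels, dist)
        for pos, j in enumerate(targets):
            sources = resolve_sources(int(j), policy, parcels, dist)
            expected = loop_actflow(act.betas, fc.values, int(j), sources)
            assert np.max(np.abs(flow.generated[pos] - expected)) < 1e-12

    def test_flow_terms_sum_to_generated(self):
        parcels, dist, fc, act = random_instance(seed=3)
        flow = actflow_generate(act, fc, np.arange(10),
                                SourcePolicy("exclude_ccc"), parcels)
        flow.check_conservation(tol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), seed=st.integers(0, 50))
    def test_linearity(self, a, b, seed):
        parcels, dist, fc, act = random_instance(seed=seed)
        rng = np.random.default_rng(seed + 1)
        act2 = ActivationMatrix(rng.standard_normal(act.betas.shape),
                                act.conditions)
        policy = SourcePolicy("exclude_ccc")
        targets = [0, 1, 2]
        mixed = ActivationMatrix(a * act.betas + b * act2.betas,
                                 act.conditions)
        lhs = actflow_generate(mixed, fc, targets, policy, parcels).generated
        rhs = (a * actflow_generate(act, fc, targets, policy, parcels).generated
               + b * actflow_generate(act2, fc, targets, policy,
                                      parcels).generated)
        assert np.max(np.abs(lhs - rhs)) < 1e-9


class TestNetworkPartition:
    def test_components_sum_to_full_model(self):
        parcels, dist = make_parcellation(60, seed=2)
        rng = np.random.default_rng(2)
        fc = rng.uniform(-0.3, 0.3, (60, 60))
        fc = 0.5 * (fc + fc.T)
        np.fill_diagonal(fc, 0.0)
        fcm = FCMatrix(fc, method="glasso")
        act = ActivationMatrix(rng.standard_normal((60, 8)), CONDITIONS)
        policy = SourcePolicy("exclude_ccc")
        targets = parcels.ccc_indices
        full = actflow_generate(act, fcm, targets, policy, parcels)
        parts = network_partitioned_generate(act, fcm, targets, policy,
                                             parcels)
        total = sum(p.generated for p in parts.values())
        assert np.max(np.abs(total - full.generated)) < 1e-10

    def test_single_network_gets_everything(self):
        parcels = tiny_parcel_table(8, n_ccc=0)
        # put every parcel in one network
        frame = parcels.frame.copy()
        frame["network"] = "DMN"
        parcels = type(parcels)(frame)
        rng = np.random.default_rng(5)
        fc = rng.uniform(-0.3, 0.3, (8, 8))
        fc = 0.5 * (fc + fc.T)
        np.fill_diagonal(fc, 0.0)
        act = ActivationMatrix(rng.standard_normal((8, 2)), CONDITIONS[:2])
        parts = network_partitioned_generate(
            act, FCMatrix(fc, method="glasso"), [0, 1],
            SourcePolicy("target_only"), parcels)
        full = actflow_generate(act, FCMatrix(fc, method="glasso"), [0, 1],
                                SourcePolicy("target_only"), parcels)
        assert np.allclose(parts["DMN"].generated, full.generated)
        for net, p in parts.items():
            if net != "DMN":
                assert np.all(p.generated == 0)


class TestSecondaryCirculation:
    def test_zero_input_zero_output(self, small_cohort):
        parcels = small_cohort.parcels
        ccc = parcels.ccc_indices
        rng = np.random.default_rng(0)
        fc = rng.uniform(-0.3, 0.3, (60, 60))
        fc = 0.5 * (fc + fc.T)
        np.fill_diagonal(fc, 0.0)
        act = ActivationMatrix(np.zeros((60, 8)), CONDITIONS)
        gen1 = actflow_generate(act, FCMatrix(fc, method="glasso"), ccc,
                                SourcePolicy("exclude_ccc"), parcels)
        gen2 = secondary_circulation(gen1, FCMatrix(fc, method="glasso"),
                                     parcels)
        assert np.all(gen2.generated == 0)

    def test_two_region_circuit_swaps_and_halves(self):
        # analytic 2-region case embedded in a circuit of exactly 2 parcels
        import pandas as pd

        from vergeflow.core import ParcelTable

        frame = pd.DataFrame({
            "parcel_id": [1, 2], "name": ["a", "b"],
            "hemisphere": ["L", "R"], "network": ["VIS1", "VIS1"],
            "is_ccc": [True, True]})
        parcels = ParcelTable(frame)
        fc = FCMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]), method="glasso")
        from vergeflow.actflow import FlowResult

        gen1 = FlowResult(np.array([0, 1]), CONDITIONS[:1],
                          np.array([[2.0], [4.0]]),
                          [np.array([1]), np.array([0])],
                          [np.array([[2.0]]), np.array([[4.0]])])
        gen2 = secondary_circulation(gen1, fc, parcels)
        assert gen2.generated[:, 0] == pytest.approx([2.0, 1.0])

    def test_matches_eight_by_eight_loop(self, small_cohort):
        parcels = small_cohort.parcels
        ccc = parcels.ccc_indices
        rng = np.random.default_rng(7)
        fc = rng.uniform(-0.4, 0.4, (60, 60))
        fc = 0.5 * (fc + fc.T)
        np.fill_diagonal(fc, 0.0)
        fcm = FCMatrix(fc, method="glasso")
        act = ActivationMatrix(rng.standard_normal((60, 8)), CONDITIONS)
        gen1 = actflow_generate(act, fcm, ccc, SourcePolicy("exclude_ccc"),
                                parcels)
        gen2 = secondary_circulation(gen1, fcm, parcels)
        for pos, j in enumerate(ccc):
            expected = np.zeros(8)
            for i in ccc:
                if i == j:
                    continue
                expected += gen1.row(int(i)) * fc[i, j]
            assert np.max(np.abs(gen2.generated[pos] - expected)) < 1e-12


class TestV1Initiated:
    def _setup(self, seed=0):
        parcels, _ = make_parcellation(60, seed=seed)
        rng = np.random.default_rng(seed)
        fc = rng.uniform(-0.4, 0.4, (60, 60))
        fc = 0.5 * (fc + fc.T)
        np.fill_diagonal(fc, 0.0)
        act = rng.standard_normal((60, 8))
        return parcels, FCMatrix(fc, method="glasso"), act

    def test_constant_v1_profile_generates_nothing(self):
        parcels, fc, act = self._setup()
        v1 = parcels.v1_indices()
        act[v1] = 3.14  # constant across conditions -> centered to zero
        flow = v1_initiated(ActivationMatrix(act, CONDITIONS), fc, parcels)
        assert np.max(np.abs(flow.generated)) < 1e-12

    def test_v1_target_uses_contralateral_source_only(self):
        parcels, fc, act = self._setup(seed=1)
        left_v1, right_v1 = parcels.v1_indices()
        flow = v1_initiated(ActivationMatrix(act, CONDITIONS), fc, parcels)
        centered_r = act[right_v1] - act[right_v1].mean()
        assert np.allclose(flow.row(left_v1),
                           centered_r * fc.values[right_v1, left_v1])

    def test_centered_inputs_have_zero_mean(self):
        parcels, fc, act = self._setup(seed=2)
        flow = v1_initiated(ActivationMatrix(act, CONDITIONS), fc, parcels)
        v1 = parcels.v1_indices()
        non_v1 = [int(j) for j in parcels.ccc_indices if j not in v1]
        # flows into non-V1 targets are sums of centered vectors, hence
        # have zero mean over conditions
        for j in non_v1:
            assert abs(flow.row(j).mean()) < 1e-12


class TestRandomSubnetworks:
    def test_reproducible_and_sized(self):
        parcels, _ = make_parcellation(60, seed=0)
        a = random_subnetwork_draws(10, {"VIS1", "VIS2"}, 1000, 42, parcels)
        b = random_subnetwork_draws(10, {"VIS1", "VIS2"}, 1000, 42, parcels)
        assert len(a) == 1000
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_exclusions_respected(self):
        parcels, _ = make_parcellation(60, seed=0)
        draws = random_subnetwork_draws(12, {"DAN"}, 50, 1, parcels)
        for draw in draws:
            assert not np.isin(draw, parcels.ccc_indices).any()
            assert not (parcels.networks[draw] == "DAN").any()

    def test_oversized_request_rejected(self):
        parcels, _ = make_parcellation(60, seed=0)
        with pytest.raises(ValidationError):
            random_subnetwork_draws(60, set(), 5, 0, parcels)
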
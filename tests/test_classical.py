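"""Exact classical dynamics: STG, attractors, predecessors, weight flow."""

import math

import numpy as np
import pytest

from qbnet.boolnet import generate_random_network, parse_rules
from qbnet.classical import (
    InitSpec,
    WeightVector,
    async_successor,
    build_stg,
    find_attractors,
    garden_of_eden_states,
    initial_distribution,
    perturbation_mixture,
    predecessors,
    propagate_weights,
    successor,
    transient_times,
)

from conftest import random_init_spec


class TestSuccessor:
    def test_identity_network_fixes_everything(self, identity_net2):
        for s in range(4):
            assert successor(identity_net2, s) == s

    def test_negation_single_component(self):
        net = parse_rules("targets, factors\nA, !A\n")
        assert build_stg(net).succ.tolist() == [1, 0]

    def test_cortical_has_two_fixed_points(self, cortical):
        fixed = [s for s in range(32) if successor(cortical, s) == s]
        assert sorted(fixed) == [13, 18]

    @pytest.mark.parametrize("seed", range(10))
    def test_stg_matches_scalar_successor(self, seed):
        net = generate_random_network(6, 3, seed=seed)
        stg = build_stg(net)
        for s in range(64):
            assert int(stg.succ[s]) == successor(net, s)

    def test_stg_cap(self, cortical):
        with pytest.raises(ValueError, match="cap"):
            build_stg(cortical, n_cap=4)


class TestAsyncSuccessor:
    def test_order_matters(self, ring_negation):
        # from 00: updating A first gives 1, then B reads the new A -> 0
        assert async_successor(ring_negation, 0, ["A", "B"]) == 1
        assert async_successor(ring_negation, 0, ["B", "A"]) == 2

    def test_requires_permutation(self, ring_negation):
        with pytest.raises(ValueError):
            async_successor(ring_negation, 0, ["A", "A"])


class TestAttractors:
    def test_cortical_basins(self, cortical_attractors):
        rep = cortical_attractors
        frac = dict(zip((c[0] for c in rep.attractors), rep.basin_fraction))
        assert frac == {18: 0.875, 13: 0.125}

    def test_basins_partition_state_space(self, cortical_attractors):
        union = set()
        for b in cortical_attractors.basin:
            assert not (union & b)
            union |= b
        assert union == set(range(32))
        assert math.isclose(sum(cortical_attractors.basin_fraction), 1.0)

    def test_identity_n2_four_fixed_points(self, identity_net2):
        rep = find_attractors(identity_net2)
        assert sorted(c[0] for c in rep.attractors) == [0, 1, 2, 3]
        assert rep.basin_fraction == (0.25,) * 4

    def test_ring_negation_cycle_and_fixed_points(self, ring_negation):
        rep = find_attractors(ring_negation)
        cycles = sorted(rep.attractors, key=len)
        assert [set(c) for c in cycles[:2]] == [{1}, {2}]
        assert set(cycles[2]) == {0, 3}

    def test_cycles_closed_under_succ(self, cortical):
        net = generate_random_network(5, 3, seed=11)
        rep = find_attractors(net)
        for cyc in rep.attractors:
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                assert successor(net, a) == b


class TestPredecessors:
    def test_cortical_one_step(self, cortical_stg):
        assert predecessors(cortical_stg, 13, 1) == {9, 13}

    def test_cortical_two_step_equals_smaller_basin(
        self, cortical_stg, cortical_attractors
    ):
        preds = predecessors(cortical_stg, 13, 2)
        assert len(preds) == 4
        smaller = min(cortical_attractors.basin, key=len)
        assert preds == smaller

    def test_garden_of_eden_has_none(self, cortical_stg):
        for goe in garden_of_eden_states(cortical_stg):
            assert predecessors(cortical_stg, goe, 1) == frozenset()

    def test_horizon_validation(self, cortical_stg):
        with pytest.raises(ValueError):
            predecessors(cortical_stg, 13, 0)


class TestInitialDistribution:
    def test_unbiased_is_uniform(self, cortical):
        w = initial_distribution(cortical, InitSpec.unbiased(5))
        assert np.allclose(w.w, 1 / 32)

    def test_theta_zero_pins_component_off(self, cortical):
        init = InitSpec.biased(cortical, {cortical.components[0]: 0.0})
        w = initial_distribution(cortical, init)
        odd = [s for s in range(32) if s & 1]
        assert np.allclose(w.w[odd], 0.0)
        even = [s for s in range(32) if not s & 1]
        assert np.allclose(w.w[even], 1 / 16)

    def test_closed_form_single_qubit(self):
        net = parse_rules("targets, factors\nA, A\n")
        w = initial_distribution(net, InitSpec((math.pi / 3,)))
        assert math.isclose(w.w[0], 0.75)
        assert math.isclose(w.w[1], 0.25)

    def test_angle_validation(self):
        with pytest.raises(ValueError):
            InitSpec((4.0,))


class TestPropagation:
    def test_single_transition_support_and_peak(self, cortical):
        w = propagate_weights(
            cortical, initial_distribution(cortical, InitSpec.unbiased(5)), 1
        )
        assert len(w.support) == 7
        assert int(np.argmax(w.w)) == 0
        assert math.isclose(float(w.w[0]), 0.4375)

    def test_t4_leaves_attractors_at_basin_fractions(self, cortical):
        w = propagate_weights(
            cortical, initial_distribution(cortical, InitSpec.unbiased(5)), 4
        )
        assert set(w.support.tolist()) == {13, 18}
        assert math.isclose(float(w.w[18]), 0.875)
        assert math.isclose(float(w.w[13]), 0.125)

    def test_t0_is_identity(self, cortical):
        w0 = initial_distribution(cortical, InitSpec.unbiased(5))
        assert np.array_equal(propagate_weights(cortical, w0, 0).w, w0.w)

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_and_support_shrinkage(self, seed):
        net = generate_random_network(5, 3, seed=seed)
        rng = np.random.default_rng(seed)
        init = random_init_spec(net, rng, allow_frozen=False)
        w = initial_distribution(net, init)
        prev_support = len(w.support)
        for _ in range(4):
            w = propagate_weights(net, w, 1)
            assert abs(float(w.w.sum()) - 1.0) < 1e-9
            assert len(w.support) <= prev_support
            prev_support = len(w.support)

    def test_goe_weight_zero_after_one_step(self, cortical, cortical_stg):
        w = propagate_weights(
            cortical, initial_distribution(cortical, InitSpec.unbiased(5)), 1
        )
        for goe in garden_of_eden_states(cortical_stg):
            assert w.w[goe] == 0.0

    def test_long_run_support_in_attractors(self):
        net = generate_random_network(6, 3, seed=5)
        rep = find_attractors(net)
        attractor_states = {s for c in rep.attractors for s in c}
        w = initial_distribution(net, InitSpec.unbiased(6))
        w = propagate_weights(net, w, 64)
        assert set(w.support.tolist()) <= attractor_states

    def test_unknown_frozen_component(self, cortical):
        w = initial_distribution(cortical, InitSpec.unbiased(5))
        with pytest.raises(KeyError):
            propagate_weights(cortical, w, 1, frozenset({"Nope"}))


class TestPerturbationMixture:
    @pytest.mark.parametrize("seed", range(6))
    def test_mixture_equals_frozen_propagation(self, seed):
        net = generate_random_network(5, 3, seed=100 + seed)
        rng = np.random.default_rng(seed)
        init = random_init_spec(net, rng, allow_frozen=True)
        direct = propagate_weights(
            net, initial_distribution(net, InitSpec(init.thetas)), 3, init.frozen
        )
        mixed = perturbation_mixture(net, init, 3)
        assert np.allclose(direct.w, mixed.w, atol=1e-12)


class TestTransients:
    def test_cortical_transients(self, cortical_stg):
        tmax, tmean = transient_times(cortical_stg)
        assert tmax == 4
        assert 0 < tmean < 4

    def test_fixed_points_have_zero_transient(self, identity_net2):
        tmax, tmean = transient_times(build_stg(identity_net2))
        assert (tmax, tmean) == (0, 0.0)


class TestWeightVectorInvariants:
    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            WeightVector(np.array([0.5, 0.4]))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            WeightVector(np.array([1.5, -0.5]))
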
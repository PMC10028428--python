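"""Reversible rule synthesis and multi-transition circuit compilation.

The central contract: for any network, horizon, initial bias and frozen set,
the exact marginal law of the measured register equals the classical
weight-propagation oracle to 1e-9.
"""

import math

import numpy as np
import pytest

from qbnet.boolnet import generate_random_network, parse_rules
from qbnet.circuits import Circuit, QuantumState, run_circuit
from qbnet.classical import (
    InitSpec,
    async_successor,
    garden_of_eden_states,
    build_stg,
    initial_distribution,
    perturbation_mixture,
    propagate_weights,
)
from qbnet.compiler import (
    RegisterLayout,
    TransitionCircuitSpec,
    build_transition_circuit,
    measured_law,
    scan_component_bias,
    synthesize_rule,
    transition_block,
)

from conftest import random_init_spec


def law_vector(law, n):
    v = np.zeros(1 << n)
    for s, p in law.items():
        v[s] = p
    return v


class TestRuleSynthesis:
    def test_passthrough_rule_is_single_cx(self):
        net = parse_rules("targets, factors\nA, B\nB, B\n")
        gates = synthesize_rule(net, 0, {"B": 1}, target=2)
        assert len(gates) == 1
        assert gates[0].kind == "x" and gates[0].controls == ((1, 1),)

    def test_constant_one_is_single_x(self):
        net = parse_rules("targets, factors\nA, 1\n")
        gates = synthesize_rule(net, 0, {}, target=1)
        assert len(gates) == 1 and gates[0].controls == ()

    def test_constant_zero_is_empty(self):
        net = parse_rules("targets, factors\nA, 0\n")
        assert synthesize_rule(net, 0, {}, target=1) == []

    def test_and_rule_is_single_toffoli(self):
        net = parse_rules("targets, factors\nA, A & B\nB, B\n")
        gates = synthesize_rule(net, 0, {"A": 0, "B": 1}, target=2)
        assert len(gates) == 1
        assert sorted(gates[0].controls) == [(0, 1), (1, 1)]

    def test_target_collision_rejected(self):
        net = parse_rules("targets, factors\nA, B\nB, B\n")
        with pytest.raises(ValueError):
            synthesize_rule(net, 0, {"B": 1}, target=1)

    @pytest.mark.parametrize("optimize", [False, True])
    def test_block_computes_xor_f_on_all_inputs(self, cortical, optimize):
        # |x>|y> -> |x>|y xor f_i(x)>, and applying twice is the identity
        input_map = {name: i for i, name in enumerate(cortical.components)}
        for i in range(cortical.n):
            gates = synthesize_rule(cortical, i, input_map, 5, optimize)
            circ = Circuit(6, list(gates))
            twice = Circuit(6, list(gates) * 2)
            for x in range(32):
                for y in (0, 1):
                    basis = x | (y << 5)
                    values = {
                        nm: (x >> b) & 1
                        for b, nm in enumerate(cortical.components)
                    }
                    f = cortical.rules[i].evaluate(values)
                    out = run_circuit(circ, QuantumState.basis(6, basis))
                    assert out.amplitude(x | ((y ^ f) << 5)) == pytest.approx(1.0)
                    back = run_circuit(twice, QuantumState.basis(6, basis))
                    assert back.amplitude(basis) == pytest.approx(1.0)

    def test_optimized_blocks_are_no_larger(self):
        net = parse_rules("targets, factors\nA, B | C\nB, B\nC, C\n")
        plain = synthesize_rule(net, 0, {"B": 1, "C": 2}, 3, optimize=False)
        merged = synthesize_rule(net, 0, {"B": 1, "C": 2}, 3, optimize=True)
        assert len(merged) <= len(plain)


class TestLayout:
    def test_single_transition_qubit_count(self, cortical):
        circ, layout = build_transition_circuit(
            TransitionCircuitSpec(cortical, 1, InitSpec.unbiased(5))
        )
        assert circ.num_qubits == 10
        assert layout.final_register() == [5, 6, 7, 8, 9]

    def test_t4_qubit_count(self, cortical):
        circ, _ = build_transition_circuit(
            TransitionCircuitSpec(cortical, 4, InitSpec.unbiased(5))
        )
        assert circ.num_qubits == 25

    def test_frozen_layout_arithmetic(self, cortical):
        init = InitSpec.unbiased(5, frozen={"Pax6", "Coup_tfi"})
        circ, layout = build_transition_circuit(
            TransitionCircuitSpec(cortical, 3, init)
        )
        # (T+1)(n-|P|) + |P| = 4*3 + 2
        assert circ.num_qubits == 14
        frozen_qubits = {layout.qubit(t, cortical.index("Pax6")) for t in range(4)}
        assert len(frozen_qubits) == 1

    def test_unbiased_init_emits_hadamards(self, cortical):
        circ, _ = build_transition_circuit(
            TransitionCircuitSpec(cortical, 1, InitSpec.unbiased(5))
        )
        assert [g.kind for g in circ.gates[:5]] == ["h"] * 5


class TestQuantumClassicalEquivalence:
    def test_cortical_single_transition(self, cortical):
        circ, _ = build_transition_circuit(
            TransitionCircuitSpec(cortical, 1, InitSpec.unbiased(5))
        )
        law = measured_law(circ)
        oracle = propagate_weights(
            cortical, initial_distribution(cortical, InitSpec.unbiased(5)), 1
        )
        assert np.allclose(law_vector(law, 5), oracle.w, atol=1e-9)

    @pytest.mark.parametrize("seed", range(50))
    def test_random_networks_any_bias_any_frozen(self, seed):
        """The central property: quantum marginal == classical propagation."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(2, 7))
        net = generate_random_network(n, min(3, n), seed=seed)
        T = int(rng.integers(1, 4))
        init = random_init_spec(net, rng)
        circ, _ = build_transition_circuit(TransitionCircuitSpec(net, T, init))
        law = measured_law(circ)
        oracle = propagate_weights(
            net, initial_distribution(net, init), T, init.frozen
        )
        assert np.allclose(law_vector(law, n), oracle.w, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_goe_states_unmeasurable_after_one_transition(self, seed):
        net = generate_random_network(5, 3, seed=200 + seed)
        circ, _ = build_transition_circuit(
            TransitionCircuitSpec(net, 1, InitSpec.unbiased(5))
        )
        law = measured_law(circ)
        for goe in garden_of_eden_states(build_stg(net)):
            assert law.get(goe, 0.0) < 1e-12

    def test_support_monotone_in_T(self, cortical):
        sizes = []
        for T in range(1, 5):
            circ, _ = build_transition_circuit(
                TransitionCircuitSpec(cortical, T, InitSpec.unbiased(5))
            )
            sizes.append(len(measured_law(circ)))
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] == 7 and sizes[-1] == 2

    def test_perturbation_matches_classical_mixture(self, cortical):
        # Pax6 biased toward overexpression, Coup_tfi toward knockout
        init = InitSpec.biased(
            cortical,
            {"Pax6": 3 * math.pi / 4, "Coup_tfi": math.pi / 4},
            frozen={"Pax6", "Coup_tfi"},
        )
        circ, _ = build_transition_circuit(
            TransitionCircuitSpec(cortical, 3, init)
        )
        law = measured_law(circ)
        oracle = perturbation_mixture(cortical, init, 3)
        assert np.allclose(law_vector(law, 5), oracle.w, atol=1e-9)


class TestAsynchronous:
    @pytest.mark.parametrize("seed", range(5))
    def test_circuit_matches_ordered_classical_update(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        net = generate_random_network(n, min(3, n), seed=300 + seed)
        order = [str(c) for c in rng.permutation(net.components)]
        spec = TransitionCircuitSpec(
            net, 1, InitSpec.unbiased(n), mode="asynchronous", order=tuple(order)
        )
        layout = RegisterLayout(n, 1, frozenset())
        gates = transition_block(spec, layout, 1)
        for x in range(1 << n):
            out = run_circuit(
                Circuit(layout.num_qubits, list(gates)),
                QuantumState.basis(layout.num_qubits, x),
            )
            assert len(out.amplitudes) == 1
            result = next(iter(out.amplitudes)) >> n
            assert result == async_successor(net, x, order)

    def test_async_requires_order(self, cortical):
        with pytest.raises(ValueError):
            TransitionCircuitSpec(
                cortical, 1, InitSpec.unbiased(5), mode="asynchronous"
            )


class TestBiasScan:
    def test_unbiased_point_recovers_basin_fractions(self, cortical):
        records = scan_component_bias(
            cortical, "Fgf8", [math.pi / 2], T=4, shots=4000, seed=3
        )
        rec = records[0]
        assert rec["analytic"]["18"] == pytest.approx(0.875)
        assert rec["sampled"]["18"] == pytest.approx(0.875, abs=0.03)

    def test_some_components_matter_and_some_do_not(self, cortical):
        """Pinning an influential component off vs on changes the attractor
        law; an uninfluential one leaves it untouched regardless of bias."""
        spread = {}
        for comp in cortical.components:
            recs = scan_component_bias(
                cortical, comp, [0.0, math.pi], T=4, shots=1, seed=0
            )
            a0 = recs[0]["analytic"]
            a1 = recs[1]["analytic"]
            spread[comp] = max(abs(a0[k] - a1[k]) for k in a0)
        assert max(spread.values()) > 0.1
        assert min(spread.values()) < 1e-12
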
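"""Compile Boolean rules into reversible transition circuits.

Each rule ``f_i`` becomes a gate block computing ``|x>|y> -> |x>|y xor
f_i(x)>`` by truth-table minterm decomposition: one multi-controlled X per
satisfying assignment of the rule restricted to its support variables, with
0-controls expressed as control polarities.  Minterms are disjoint, so each
basis input flips the target exactly ``f_i(x)`` times — the block is correct
by construction and exactly reversible (applying it twice is the identity).

T repeated transitions use a single circuit of (T+1)n qubits: register 0
holds the (possibly biased) initial superposition, register t the state after
t synchronous updates.  Perturbed ("frozen") components are never updated;
their single register-0 qubit is read at every transition, which realizes a
superposed knockout/overexpression screen: the measured law is the
product-Bernoulli mixture over all 2^|P| pinned sub-networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boolnet import BooleanNetwork
from .circuits import Circuit, Gate, H, MCX, QuantumState, RY, run_circuit, sample
from .classical import (
    InitSpec,
    WeightVector,
    find_attractors,
    initial_distribution,
    propagate_weights,
)

__all__ = [
    "RegisterLayout",
    "TransitionCircuitSpec",
    "synthesize_rule",
    "build_transition_circuit",
    "measured_law",
    "scan_component_bias",
]

_HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class RegisterLayout:
    """Mapping (time index t, component i) -> physical qubit.

    Register 0 is qubits 0..n-1 in component order.  A frozen component keeps
    that single qubit at every t; unfrozen components get one fresh qubit per
    transition, so the total is (T+1)(n-|P|) + |P| qubits.
    """

    n: int
    T: int
    frozen_idx: frozenset[int]

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if any(not 0 <= i < self.n for i in self.frozen_idx):
            raise ValueError("frozen index out of range")

    @property
    def unfrozen(self) -> list[int]:
        return [i for i in range(self.n) if i not in self.frozen_idx]

    @property
    def num_qubits(self) -> int:
        return self.n + self.T * len(self.unfrozen)

    def qubit(self, t: int, i: int) -> int:
        if not 0 <= t <= self.T or not 0 <= i < self.n:
            raise ValueError("layout index out of range")
        if t == 0 or i in self.frozen_idx:
            return i
        rank = self.unfrozen.index(i)
        return self.n + (t - 1) * len(self.unfrozen) + rank

    def final_register(self) -> list[int]:
        """Qubits carrying the logical state after T transitions, component
        order; this is what gets measured."""
        return [self.qubit(self.T, i) for i in range(self.n)]


@dataclass(frozen=True)
class TransitionCircuitSpec:
    """What to compile: network, number of transitions, initial biases and
    frozen perturbations, synchronous or ordered-asynchronous updates."""

    net: BooleanNetwork
    T: int
    init: InitSpec
    mode: str = "synchronous"  # or "asynchronous"
    order: tuple[str, ...] | None = None  # async update order (permutation)

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if len(self.init.thetas) != self.net.n:
            raise ValueError("InitSpec length must equal n")
        if self.mode not in ("synchronous", "asynchronous"):
            raise ValueError("mode must be synchronous or asynchronous")
        if self.mode == "asynchronous":
            unfrozen = [
                c for c in self.net.components if c not in self.init.frozen
            ]
            if self.order is None or sorted(self.order) != sorted(unfrozen):
                raise ValueError(
                    "asynchronous mode needs an update order that is a "
                    "permutation of the unfrozen components"
                )


# ---------------------------------------------------------------------------
# Rule synthesis


def _merge_implicants(implicants: list[tuple[int, int]], k: int):
    """One Quine-McCluskey-style pass: merge implicant pairs differing in a
    single cared-for bit (an ESOP-preserving merge because minterm pairs are
    disjoint and their merged cube covers exactly their union)."""
    merged = True
    current = list(implicants)
    while merged:
        merged = False
        out: list[tuple[int, int]] = []
        used = [False] * len(current)
        for a in range(len(current)):
            if used[a]:
                continue
            va, ma = current[a]
            partner = -1
            for b in range(a + 1, len(current)):
                if used[b]:
                    continue
                vb, mb = current[b]
                if ma != mb:
                    continue
                diff = (va ^ vb) & ma
                if diff and (diff & (diff - 1)) == 0:
                    partner = b
                    break
            if partner >= 0:
                vb, mb = current[partner]
                bit = (va ^ vb) & ma
                out.append((va & ~bit, ma & ~bit))
                used[a] = used[partner] = True
                merged = True
            else:
                out.append((va, ma))
                used[a] = True
        current = out
    return current


def synthesize_rule(
    net: BooleanNetwork,
    component: int,
    input_qubits: dict[str, int],
    target: int,
    optimize: bool = False,
) -> list[Gate]:
    """Reversible block computing ``y xor f_i(x)`` onto ``target``.

    ``input_qubits`` maps component names to physical qubits; only the rule's
    support variables carry controls.  ``optimize=True`` merges complementary
    minterm pairs (dropping the distinguishing control) before emission.
    """
    rule = net.rules[component]
    support = sorted(rule.variables(), key=net.index)
    for name in support:
        if name not in input_qubits:
            raise KeyError(f"no input qubit for {name!r}")
        if input_qubits[name] == target:
            raise ValueError(f"target qubit collides with input {name!r}")

    k = len(support)
    if k == 0:
        value = rule.evaluate({})
        return [Gate("x", target)] if value else []

    # truth table over the support only
    ones: list[int] = []
    for assignment in range(1 << k):
        values = {name: (assignment >> b) & 1 for b, name in enumerate(support)}
        if rule.evaluate(values):
            ones.append(assignment)
    if not ones:
        return []
    if len(ones) == 1 << k:
        return [Gate("x", target)]

    implicants = [(v, (1 << k) - 1) for v in ones]
    if optimize:
        implicants = _merge_implicants(implicants, k)

    gates: list[Gate] = []
    for value, mask in implicants:
        controls = tuple(
            (input_qubits[support[b]], (value >> b) & 1)
            for b in range(k)
            if (mask >> b) & 1
        )
        gates.append(MCX(controls, target))
    return gates


# ---------------------------------------------------------------------------
# Multi-transition circuits


def init_layer(init: InitSpec, layout: RegisterLayout) -> list[Gate]:
    """Initialization on register 0: H where theta is exactly pi/2 (the
    unbiased case), RY(theta) otherwise."""
    gates = []
    for i, theta in enumerate(init.thetas):
        q = layout.qubit(0, i)
        gates.append(H(q) if theta == _HALF_PI else RY(theta, q))
    return gates


def transition_block(
    spec: TransitionCircuitSpec, layout: RegisterLayout, t: int, optimize=False
) -> list[Gate]:
    """Gates implementing transition t (register t-1 -> register t)."""
    net = spec.net
    frozen_idx = layout.frozen_idx
    if spec.mode == "synchronous":
        order = [net.components[i] for i in layout.unfrozen]
        updated: set[str] = set()  # sync: everything reads register t-1
    else:
        order = list(spec.order)
        updated = set()
    gates: list[Gate] = []
    for name in order:
        i = net.index(name)
        inputs = {}
        for vname in net.rules[i].variables():
            vi = net.index(vname)
            if vi in frozen_idx:
                inputs[vname] = layout.qubit(0, vi)
            elif spec.mode == "asynchronous" and vname in updated:
                inputs[vname] = layout.qubit(t, vi)
            else:
                inputs[vname] = layout.qubit(t - 1, vi)
        gates.extend(
            synthesize_rule(net, i, inputs, layout.qubit(t, i), optimize)
        )
        updated.add(name)
    return gates


def build_transition_circuit(
    spec: TransitionCircuitSpec, optimize: bool = False
) -> tuple[Circuit, RegisterLayout]:
    """Assemble the full (T+1)-register circuit with measurement marker on
    the final logical state (register T plus frozen qubits)."""
    net = spec.net
    frozen_idx = frozenset(net.index(c) for c in spec.init.frozen)
    layout = RegisterLayout(net.n, spec.T, frozen_idx)
    circ = Circuit(layout.num_qubits)
    circ.append(init_layer(spec.init, layout))
    for t in range(1, spec.T + 1):
        circ.append(transition_block(spec, layout, t, optimize))
    circ.measure = layout.final_register()
    return circ, layout


def measured_law(circ: Circuit, backend: str = "sparse") -> dict[int, float]:
    """Exact probability law of the circuit's measured register."""
    if not circ.measure:
        raise ValueError("circuit has no measurement marker")
    state = run_circuit(circ, backend=backend)
    return state.probabilities(circ.measure)


def law_as_weights(law: dict[int, float], n: int) -> WeightVector:
    w = np.zeros(1 << n, dtype=np.float64)
    for s, p in law.items():
        w[s] = p
    return WeightVector(w)


# ---------------------------------------------------------------------------
# Component bias scan


def scan_component_bias(
    net: BooleanNetwork,
    component: str,
    thetas: list[float],
    T: int,
    shots: int,
    seed: int,
) -> list[dict]:
    """Sweep the initial bias of one component, H-initializing all others.

    For each theta, builds the biased T-transition circuit, samples ``shots``
    measurements, and tallies per-attractor frequencies; the analytic curve
    (classical weight propagation summed over each basin's attractor states)
    is reported alongside.  Returns one record per theta.
    """
    idx = net.index(component)
    report = find_attractors(net)
    records = []
    for k, theta in enumerate(thetas):
        angles = [_HALF_PI] * net.n
        angles[idx] = float(theta)
        init = InitSpec(tuple(angles))
        circ, _layout = build_transition_circuit(
            TransitionCircuitSpec(net, T, init)
        )
        state = run_circuit(circ)
        dist = sample(state, circ.measure, shots, seed + k)
        freqs = dist.counts_by_int()
        analytic = propagate_weights(net, initial_distribution(net, init), T)
        record = {"component": component, "theta": float(theta)}
        sampled = {}
        exact = {}
        for a, cycle in enumerate(report.attractors):
            label = "/".join(str(s) for s in cycle)
            sampled[label] = sum(freqs.get(s, 0) for s in cycle) / shots
            exact[label] = float(sum(analytic.w[s] for s in cycle))
        record["sampled"] = sampled
        record["analytic"] = exact
        record["other_sampled"] = 1.0 - sum(sampled.values())
        records.append(record)
    return records
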
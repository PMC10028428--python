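"""Grover predecessor search on the state transition graph.

The oracle "is ``x`` a ``t_inv``-step predecessor of the marked state
``omega``?" is built from transition circuits: run ``t_inv`` forward
transitions on ancilla registers, phase-flip the final register when it
equals ``omega``, then uncompute the transitions so the ancillas return to
|0...0> and the phase sits on the search register alone.  One Grover
iteration appends the reflection about the prepared initial state,
``A (2|0><0| - I) A†`` with ``A`` the preparation layer (Hadamards by
default, or any per-component RY bias).

With ``M`` solutions among ``N = 2**n`` states and uniform preparation, the
measured mass on the solution set after ``G`` iterations is
``sin²((2G+1) arcsin sqrt(M/N))``, maximized near ``G_opt = floor(pi/4
sqrt(N/M))``.  A Garden-of-Eden target has ``M = 0``: the oracle never
fires and the circuit returns the prepared distribution unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .boolnet import BooleanNetwork, state_to_string
from .circuits import (
    Circuit,
    Gate,
    H,
    MCZ,
    MeasurementDistribution,
    RY,
    run_circuit,
    sample,
)
from .classical import InitSpec, build_stg, find_attractors, predecessors
from .compiler import (
    RegisterLayout,
    TransitionCircuitSpec,
    init_layer,
    transition_block,
)

__all__ = [
    "GroverSpec",
    "GroverResult",
    "g_opt",
    "grover_success_probability",
    "build_grover_circuit",
    "run_grover",
    "adaptive_grover_search",
]

_HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class GroverSpec:
    net: BooleanNetwork
    omega: int  # marked state, integer encoding
    t_inv: int = 1
    iterations: int = 1
    init: InitSpec | None = None  # non-uniform preparation; uniform if None

    def __post_init__(self):
        if not 0 <= self.omega < self.net.n_states:
            raise ValueError("marked state out of range")
        if self.t_inv < 1:
            raise ValueError("t_inv must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.init is not None and self.init.frozen:
            raise ValueError("frozen components are not part of the search")


@dataclass(frozen=True)
class GroverResult:
    spec_echo: dict
    distribution: MeasurementDistribution
    solutions: frozenset[int]
    cumulative_frequency: float
    analytic_probability: float
    warnings: tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        n = self.spec_echo["n"]
        return {
            "spec": self.spec_echo,
            "solutions": sorted(self.solutions),
            "solutions_register_order": [
                state_to_string(s, n, "register") for s in sorted(self.solutions)
            ],
            "solutions_file_order": [
                state_to_string(s, n, "file") for s in sorted(self.solutions)
            ],
            "counts": dict(sorted(self.distribution.counts.items())),
            "shots": self.distribution.shots,
            "seed": self.distribution.seed,
            "cumulative_frequency": self.cumulative_frequency,
            "analytic_probability": self.analytic_probability,
            "warnings": list(self.warnings),
        }


def g_opt(N: int, M: int) -> int:
    """Optimal iteration count floor((pi/4) sqrt(N/M))."""
    if not 1 <= M <= N:
        raise ValueError("need 1 <= M <= N (M=0 means nothing to amplify)")
    return int(math.floor((math.pi / 4.0) * math.sqrt(N / M)))


def grover_success_probability(N: int, M: int, G: int) -> float:
    """Closed-form solution mass sin²((2G+1) arcsin sqrt(M/N)) after G
    iterations from uniform preparation."""
    if not 1 <= M <= N:
        raise ValueError("need 1 <= M <= N")
    if G < 0:
        raise ValueError("G must be >= 0")
    theta = math.asin(math.sqrt(M / N))
    return math.sin((2 * G + 1) * theta) ** 2


# ---------------------------------------------------------------------------
# Circuit construction


def _preparation(spec: GroverSpec, layout: RegisterLayout) -> list[Gate]:
    init = spec.init or InitSpec.unbiased(spec.net.n)
    return init_layer(init, layout)


def oracle_gates(spec: GroverSpec, layout: RegisterLayout) -> list[Gate]:
    """The phase oracle: forward transitions onto ancilla registers, a phase
    mark on register ``t_inv`` conditioned on equality with ``omega``, then
    the uncompute that returns every ancilla register to |0...0>.  Acting on
    a search-register basis state |x> (ancillas zero) it yields exactly
    ``(-1)^[x is a t_inv-step predecessor of omega] |x>``."""
    net = spec.net
    n = net.n
    tspec = TransitionCircuitSpec(
        net, spec.t_inv, spec.init or InitSpec.unbiased(n)
    )
    forward: list[Gate] = []
    for t in range(1, spec.t_inv + 1):
        forward.extend(transition_block(tspec, layout, t))
    mark = MCZ(
        [
            (layout.qubit(spec.t_inv, i), (spec.omega >> i) & 1)
            for i in range(n)
        ]
    )
    uncompute = [g.adjoint() for g in reversed(forward)]
    return forward + mark + uncompute


def diffusion_gates(spec: GroverSpec, layout: RegisterLayout) -> list[Gate]:
    """Reflection about the prepared state, emitted as ``A (I - 2|0><0|)
    A†`` — the textbook diffusion up to a global phase of -1 (irrelevant for
    sampling; quantum counting compensates it explicitly)."""
    prep = _preparation(spec, layout)
    unprep = [g.adjoint() for g in reversed(prep)]
    # -1 iff register 0 is all zeros (0-polarity controls on every qubit)
    zero_flip = MCZ([(layout.qubit(0, i), 0) for i in range(spec.net.n)])
    return unprep + zero_flip + prep


def grover_iterate_gates(
    spec: GroverSpec, layout: RegisterLayout
) -> list[Gate]:
    """One Grover iteration: oracle then reflection about the prepared state."""
    return oracle_gates(spec, layout) + diffusion_gates(spec, layout)


def build_grover_circuit(spec: GroverSpec) -> tuple[Circuit, RegisterLayout]:
    """(t_inv+1)n-qubit Grover circuit with measurement on the search
    register (register 0)."""
    layout = RegisterLayout(spec.net.n, spec.t_inv, frozenset())
    circ = Circuit(layout.num_qubits)
    circ.append(_preparation(spec, layout))
    iterate = grover_iterate_gates(spec, layout)
    for _ in range(spec.iterations):
        circ.append(iterate)
    circ.measure = [layout.qubit(0, i) for i in range(spec.net.n)]
    return circ, layout


# ---------------------------------------------------------------------------
# Execution


def run_grover(spec: GroverSpec, shots: int, seed: int) -> GroverResult:
    """Simulate the search, sample the search register, and score the sampled
    mass on the classically verified solution set."""
    if shots < 1:
        raise ValueError("shots must be >= 1")
    circ, _layout = build_grover_circuit(spec)
    state = run_circuit(circ)
    dist = sample(state, circ.measure, shots, seed)

    stg = build_stg(spec.net)
    solutions = predecessors(stg, spec.omega, spec.t_inv)
    M, N = len(solutions), spec.net.n_states
    freqs = dist.counts_by_int()
    cumulative = sum(freqs.get(s, 0) for s in solutions) / shots
    if M == 0:
        analytic = 0.0
    elif spec.init is None:
        analytic = grover_success_probability(N, M, spec.iterations)
    else:
        # non-uniform preparation: exact mass from the statevector
        law = state.probabilities(circ.measure)
        analytic = sum(law.get(s, 0.0) for s in solutions)

    notes = []
    report = find_attractors(spec.net)
    for cyc in report.attractors:
        if spec.omega in cyc and len(cyc) > 1:
            notes.append(
                "marked state lies on a cyclic attractor; amplification may "
                "depend on which cycle state is marked"
            )
    echo = {
        "n": spec.net.n,
        "omega": spec.omega,
        "t_inv": spec.t_inv,
        "iterations": spec.iterations,
        "uniform_preparation": spec.init is None,
    }
    return GroverResult(echo, dist, solutions, cumulative, analytic, tuple(notes))


def adaptive_grover_search(
    net: BooleanNetwork,
    omega: int,
    t_inv: int,
    seed: int,
    c: float = 1.2,
    max_rounds: int = 40,
) -> dict:
    """Boyer-style search when the solution count M is unknown.

    Round k draws G uniformly from [0, ceil(c**k)], runs the circuit with G
    iterations, measures once, and classically verifies the outcome (does
    ``succ^t_inv`` map it onto ``omega``?).  Terminates on the first verified
    solution; returns it with the total oracle-call count.  Returns
    ``solution=None`` after ``max_rounds`` failures (e.g. a Garden-of-Eden
    target, for which no solution exists).
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    stg = build_stg(net)
    oracle_calls = 0
    for k in range(1, max_rounds + 1):
        m = math.ceil(c**k)
        G = int(rng.integers(0, m + 1))
        spec = GroverSpec(net, omega, t_inv, G)
        circ, _ = build_grover_circuit(spec)
        state = run_circuit(circ)
        dist = sample(state, circ.measure, 1, int(rng.integers(0, 2**31)))
        outcome = next(iter(dist.counts_by_int()))
        oracle_calls += G
        image = outcome
        for _ in range(t_inv):
            image = int(stg.succ[image])
        if image == omega:
            return {
                "solution": outcome,
                "oracle_calls": oracle_calls,
                "rounds": k,
            }
    return {"solution": None, "oracle_calls": oracle_calls, "rounds": max_rounds}
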
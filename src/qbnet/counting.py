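"""Quantum counting: estimate the number of predecessors by phase estimation.

On the 2-dimensional rotation subspace spanned by the solution and
non-solution components of the uniform superposition, the Grover operator has
eigenvalues ``exp(±2i·arcsin(sqrt(M/N)))``.  Phase estimation with ``r``
readout qubits — Hadamards on the readout register, controlled powers
``G^(2^j)`` from readout qubit ``j``, then an inverse quantum Fourier
transform — therefore concentrates the readout integer ``y`` near
``2^r·theta/pi`` and its mirror ``2^r - y``, and each outcome maps to the
estimate ``M_hat = N·sin²(pi·y/2^r)``.

The search-register preparation is uniform, so both eigenvectors carry weight
1/2 and the two mirror peaks are equally likely; they yield the same
``M_hat``.  A Garden-of-Eden target (``M = 0``) makes the Grover operator act
as the identity on the prepared state, so the readout is deterministically
``y = 0``.

The library's Grover iterate equals the textbook operator times a global
phase of -1 (its reflection is ``A (I - 2|0><0|) A†``); a controlled global
phase is a physical relative phase, so each controlled iterate is paired with
a P(pi) on its control qubit to restore the textbook eigenvalue convention.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .boolnet import BooleanNetwork
from .circuits import Circuit, Gate, H, P, run_circuit, sample
from .classical import InitSpec, build_stg, predecessors
from .compiler import RegisterLayout
from .grover import GroverSpec, grover_iterate_gates

__all__ = [
    "CountingSpec",
    "CountingResult",
    "build_counting_circuit",
    "estimate_M",
    "run_counting",
    "inverse_qft_gates",
]


@dataclass(frozen=True)
class CountingSpec:
    net: BooleanNetwork
    omega: int
    t_inv: int = 1
    r: int = 4  # readout qubits
    shots: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if not 0 <= self.omega < self.net.n_states:
            raise ValueError("marked state out of range")
        if self.t_inv < 1:
            raise ValueError("t_inv must be >= 1")
        if self.shots < 1:
            raise ValueError("shots must be >= 1")


@dataclass(frozen=True)
class CountingResult:
    spec_echo: dict
    y_counts: dict[int, int]
    estimates: dict[float, int]  # M_hat -> count
    mean: float
    mode: float
    classical_M: int

    def to_tsv(self) -> str:
        """Plot-ready table of (y, count, M_hat)."""
        r = self.spec_echo["r"]
        N = 1 << self.spec_echo["n"]
        lines = ["y\tcount\tM_hat"]
        for y in sorted(self.y_counts):
            lines.append(
                f"{y}\t{self.y_counts[y]}\t{estimate_M(y, r, N):.6f}"
            )
        return "\n".join(lines) + "\n"

    def to_json_dict(self) -> dict:
        return {
            "spec": self.spec_echo,
            "y_counts": {str(y): c for y, c in sorted(self.y_counts.items())},
            "estimates": {f"{m:.6f}": c for m, c in sorted(self.estimates.items())},
            "mean_M": self.mean,
            "mode_M": self.mode,
            "classical_M": self.classical_M,
        }


def estimate_M(y: int, r: int, N: int) -> float:
    """Map a readout integer to a solution-count estimate
    ``N·sin²(pi·y/2^r)``; symmetric under ``y -> 2^r - y``."""
    if not 0 <= y < (1 << r):
        raise ValueError("y out of range")
    y = min(y, (1 << r) - y)  # sin(pi - x) = sin(x): exact mirror symmetry
    return N * math.sin(math.pi * y / (1 << r)) ** 2


def inverse_qft_gates(qubits: list[int]) -> list[Gate]:
    """Swap-free inverse quantum Fourier transform on the listed qubits.

    On input, qubit ``qubits[j]`` carries phase weight ``2^j``; on output the
    result integer appears bit-reversed, with bit ``j`` on
    ``qubits[r-1-j]``.  Callers fold the reversal into the readout order
    instead of spending three CX per swap; controlled phases use the
    symmetric two-qubit P gate.
    """
    r = len(qubits)
    gates: list[Gate] = []
    # adjoint of the textbook QFT (bit j on qubits[j], swap-free layout)
    for j in range(r - 1, -1, -1):
        for k in range(r - 1, j, -1):
            gates.append(
                P(-math.pi / (1 << (k - j)), qubits[k]).controlled(qubits[j])
            )
        gates.append(H(qubits[j]))
    return gates


def build_counting_circuit(
    spec: CountingSpec,
) -> tuple[Circuit, RegisterLayout, list[int]]:
    """Readout register of r qubits on top of the (t_inv+1)n Grover layout.

    Returns (circuit, grover layout, readout qubit list); the measurement
    marker covers the readout register only.
    """
    gspec = GroverSpec(spec.net, spec.omega, spec.t_inv, iterations=0)
    layout = RegisterLayout(spec.net.n, spec.t_inv, frozenset())
    base = layout.num_qubits
    readout = [base + j for j in range(spec.r)]
    circ = Circuit(base + spec.r)

    for q in readout:
        circ.append(H(q))
    for i in range(spec.net.n):
        circ.append(H(layout.qubit(0, i)))

    iterate = grover_iterate_gates(gspec, layout)
    for j, ctrl in enumerate(readout):
        controlled = [g.controlled(ctrl) for g in iterate]
        # restore the textbook global-phase convention per application
        controlled.append(P(math.pi, ctrl))
        for _ in range(1 << j):
            circ.append(controlled)

    circ.append(inverse_qft_gates(readout))
    # the swap-free iQFT leaves the result bit-reversed: undo it at readout
    circ.measure = list(reversed(readout))
    return circ, layout, readout


def run_counting(spec: CountingSpec) -> CountingResult:
    """Simulate, sample the readout register, and map outcomes to M̂."""
    circ, _layout, readout = build_counting_circuit(spec)
    state = run_circuit(circ)
    dist = sample(state, circ.measure, spec.shots, spec.seed)
    y_counts = dist.counts_by_int()

    N = spec.net.n_states
    est = Counter()
    for y, c in y_counts.items():
        est[estimate_M(y, spec.r, N)] += c
    mean = sum(m * c for m, c in est.items()) / spec.shots
    mode = max(est, key=lambda m: (est[m], -m))

    stg = build_stg(spec.net)
    truth = len(predecessors(stg, spec.omega, spec.t_inv))
    echo = {
        "n": spec.net.n,
        "omega": spec.omega,
        "t_inv": spec.t_inv,
        "r": spec.r,
        "shots": spec.shots,
        "seed": spec.seed,
    }
    return CountingResult(echo, dict(y_counts), dict(est), mean, mode, truth)
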
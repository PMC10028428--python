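"""Gate-level circuit description and statevector simulation.

The gate set is deliberately small: X, H, RY(theta) and the phase gate
P(lambda), each optionally decorated with any number of polarized controls
(a 0-control fires when its qubit is 0).  This covers everything the toolkit
compiles: CX is X with one control, a Toffoli / multi-controlled X is X with
more, and a multi-controlled Z is P(pi) with controls.  Wrapping a gate with
an extra control — needed for the controlled Grover powers in quantum
counting — is then a one-liner.

Simulation is sparse by default: amplitudes live in a dict keyed by basis
integers.  Transition circuits are basis permutations past the initial
superposition layer, so the support never exceeds 2**n regardless of how many
ancilla registers the circuit has; this is what makes (T+1)n-qubit circuits
cheap.  A dense NumPy backend (capped at 24 qubits) is kept as a cross-check.
"""

from __future__ import annotations

import cmath
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Gate",
    "Circuit",
    "QuantumState",
    "MeasurementDistribution",
    "run_circuit",
    "sample",
    "inverse",
    "to_openqasm",
]

_AMP_PRUNE = 1e-14  # drop amplitudes below this after each gate


@dataclass(frozen=True)
class Gate:
    """One gate: a single-qubit operator plus polarized controls.

    ``kind`` is one of ``x``, ``h``, ``ry``, ``p``; ``param`` is the angle for
    ``ry``/``p``.  ``controls`` is a tuple of ``(qubit, polarity)`` pairs: the
    gate acts only on basis states where every control qubit equals its
    polarity.
    """

    kind: str
    target: int
    controls: tuple[tuple[int, int], ...] = ()
    param: float | None = None

    def __post_init__(self):
        if self.kind not in ("x", "h", "ry", "p"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind in ("ry", "p") and self.param is None:
            raise ValueError(f"{self.kind} requires a parameter")
        qubits = [self.target] + [q for q, _ in self.controls]
        if len(set(qubits)) != len(qubits):
            raise ValueError("target and control qubits must be distinct")
        for _, pol in self.controls:
            if pol not in (0, 1):
                raise ValueError("control polarity must be 0 or 1")

    def qubits(self) -> list[int]:
        return [self.target] + [q for q, _ in self.controls]

    def adjoint(self) -> "Gate":
        if self.kind in ("ry", "p"):
            return replace(self, param=-self.param)
        return self  # x, h self-adjoint

    def controlled(self, control: int, polarity: int = 1) -> "Gate":
        return replace(self, controls=self.controls + ((control, polarity),))


# convenience constructors
def X(t, controls=()):
    return Gate("x", t, tuple(controls))


def H(t, controls=()):
    return Gate("h", t, tuple(controls))


def RY(theta, t, controls=()):
    return Gate("ry", t, tuple(controls), param=theta)


def P(lam, t, controls=()):
    return Gate("p", t, tuple(controls), param=lam)


def MCX(controls, target):
    """Multi-controlled X; ``controls`` is a list of (qubit, polarity)."""
    return Gate("x", target, tuple(controls))


def MCZ(qubits_with_polarity):
    """Phase flip -1 iff every listed qubit matches its polarity.

    The last listed qubit is used as the phase target: a 1-polarity entry
    becomes the target of P(pi); a 0-polarity target is X-conjugated.
    Returns a gate list.
    """
    if not qubits_with_polarity:
        raise ValueError("MCZ needs at least one qubit")
    *ctrl, (tq, tpol) = list(qubits_with_polarity)
    core = P(math.pi, tq, tuple(ctrl))
    if tpol == 1:
        return [core]
    return [X(tq), core, X(tq)]


@dataclass
class Circuit:
    """Ordered gate list on an indexed register, plus a measurement marker."""

    num_qubits: int
    gates: list[Gate] = field(default_factory=list)
    measure: list[int] | None = None  # qubits to read out, in register order

    def append(self, gate_or_list):
        gates = gate_or_list if isinstance(gate_or_list, list) else [gate_or_list]
        for g in gates:
            for q in g.qubits():
                if not 0 <= q < self.num_qubits:
                    raise ValueError(
                        f"gate touches qubit {q} outside register of "
                        f"{self.num_qubits}"
                    )
            self.gates.append(g)
        return self

    @property
    def depth(self) -> int:
        """Greedy-layering depth: gates sharing no qubit share a layer."""
        level: dict[int, int] = {}
        depth = 0
        for g in self.gates:
            qs = g.qubits()
            layer = 1 + max((level.get(q, 0) for q in qs), default=0)
            for q in qs:
                level[q] = layer
            depth = max(depth, layer)
        return depth

    def summary(self) -> dict:
        kinds: dict[str, int] = {}
        for g in self.gates:
            label = g.kind if not g.controls else f"c{len(g.controls)}{g.kind}"
            kinds[label] = kinds.get(label, 0) + 1
        return {
            "num_qubits": self.num_qubits,
            "num_gates": len(self.gates),
            "depth": self.depth,
            "gate_counts": kinds,
        }


# ---------------------------------------------------------------------------
# States


class QuantumState:
    """Complex amplitudes over basis states, sparse dict keyed by integer."""

    def __init__(self, num_qubits: int, amplitudes: dict[int, complex]):
        self.num_qubits = num_qubits
        self.amplitudes = amplitudes

    @classmethod
    def zero(cls, num_qubits: int) -> "QuantumState":
        return cls(num_qubits, {0: 1.0 + 0.0j})

    @classmethod
    def basis(cls, num_qubits: int, state: int) -> "QuantumState":
        if not 0 <= state < (1 << num_qubits):
            raise ValueError("basis state out of range")
        return cls(num_qubits, {state: 1.0 + 0.0j})

    def norm_sq(self) -> float:
        return sum(abs(a) ** 2 for a in self.amplitudes.values())

    def amplitude(self, basis_state: int) -> complex:
        return self.amplitudes.get(basis_state, 0.0 + 0.0j)

    def probabilities(self, qubits: list[int] | None = None) -> dict[int, float]:
        """Marginal law of the listed qubits (entry ``k``: bit ``b`` of ``k``
        is the value of ``qubits[b]``); all qubits if None."""
        if qubits is None:
            qubits = list(range(self.num_qubits))
        if not qubits:
            raise ValueError("empty qubit list")
        probs: dict[int, float] = {}
        for basis, amp in self.amplitudes.items():
            key = 0
            for b, q in enumerate(qubits):
                key |= ((basis >> q) & 1) << b
            probs[key] = probs.get(key, 0.0) + abs(amp) ** 2
        return probs

    def to_dense(self) -> np.ndarray:
        vec = np.zeros(1 << self.num_qubits, dtype=np.complex128)
        for basis, amp in self.amplitudes.items():
            vec[basis] = amp
        return vec


@dataclass(frozen=True)
class MeasurementDistribution:
    """Shot counts over measured bitstrings (register order: highest listed
    qubit leftmost, so the key is the binary expansion of the outcome)."""

    counts: dict[str, int]
    shots: int
    seed: int
    width: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.shots:
            raise ValueError("counts must sum to shots")
        for key in self.counts:
            if len(key) != self.width or set(key) - {"0", "1"}:
                raise ValueError(f"malformed bitstring key {key!r}")

    def frequencies(self) -> dict[str, float]:
        return {k: v / self.shots for k, v in self.counts.items()}

    def counts_by_int(self) -> dict[int, int]:
        return {int(k, 2): v for k, v in self.counts.items()}

    def to_json(self) -> str:
        payload: dict = dict(sorted(self.counts.items()))
        payload["_shots"] = self.shots
        payload["_seed"] = self.seed
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MeasurementDistribution":
        raw = json.loads(text)
        shots = raw.pop("_shots")
        seed = raw.pop("_seed", 0)
        width = len(next(iter(raw))) if raw else 0
        return cls(dict(raw), shots, seed, width)


# ---------------------------------------------------------------------------
# Simulation


def _controls_satisfied(basis: int, controls) -> bool:
    for q, pol in controls:
        if (basis >> q) & 1 != pol:
            return False
    return True


def _apply_gate_sparse(
    amps: dict[int, complex], gate: Gate
) -> dict[int, complex]:
    t = gate.target
    mask = 1 << t
    if gate.kind == "p":
        lam = gate.param
        phase = cmath.exp(1j * lam)
        out = {}
        for basis, amp in amps.items():
            if (basis & mask) and _controls_satisfied(basis, gate.controls):
                amp = amp * phase
            out[basis] = amp
        return out
    if gate.kind == "x":
        out = {}
        for basis, amp in amps.items():
            if _controls_satisfied(basis, gate.controls):
                basis ^= mask
            out[basis] = out.get(basis, 0.0) + amp
        return out
    # h / ry: real 2x2 [[a, b], [c, d]] acting on the target bit
    if gate.kind == "h":
        s = 1.0 / math.sqrt(2.0)
        a, b, c, d = s, s, s, -s
    else:  # ry
        half = gate.param / 2.0
        a, b = math.cos(half), -math.sin(half)
        c, d = math.sin(half), math.cos(half)
    out: dict[int, complex] = {}
    for basis, amp in amps.items():
        if not _controls_satisfied(basis, gate.controls):
            out[basis] = out.get(basis, 0.0) + amp
            continue
        if basis & mask:  # target is |1>
            lo, hi = basis ^ mask, basis
            out[lo] = out.get(lo, 0.0) + b * amp
            out[hi] = out.get(hi, 0.0) + d * amp
        else:
            lo, hi = basis, basis ^ mask
            out[lo] = out.get(lo, 0.0) + a * amp
            out[hi] = out.get(hi, 0.0) + c * amp
    return out


def _prune(amps: dict[int, complex]) -> dict[int, complex]:
    return {b: a for b, a in amps.items() if abs(a) > _AMP_PRUNE}


def _gate_matrix(gate: Gate) -> np.ndarray:
    if gate.kind == "x":
        return np.array([[0, 1], [1, 0]], dtype=np.complex128)
    if gate.kind == "h":
        s = 1.0 / math.sqrt(2.0)
        return np.array([[s, s], [s, -s]], dtype=np.complex128)
    if gate.kind == "ry":
        half = gate.param / 2.0
        return np.array(
            [
                [math.cos(half), -math.sin(half)],
                [math.sin(half), math.cos(half)],
            ],
            dtype=np.complex128,
        )
    lam = gate.param
    return np.array([[1, 0], [0, cmath.exp(1j * lam)]], dtype=np.complex128)


def _apply_gate_dense(vec: np.ndarray, gate: Gate, num_qubits: int) -> np.ndarray:
    states = np.arange(len(vec), dtype=np.int64)
    active = np.ones(len(vec), dtype=bool)
    for q, pol in gate.controls:
        active &= ((states >> q) & 1) == pol
    mask = 1 << gate.target
    U = _gate_matrix(gate)
    out = vec.copy()
    lo = active & (((states >> gate.target) & 1) == 0)
    hi_idx = states[lo] ^ mask
    v0, v1 = vec[states[lo]], vec[hi_idx]
    out[states[lo]] = U[0, 0] * v0 + U[0, 1] * v1
    out[hi_idx] = U[1, 0] * v0 + U[1, 1] * v1
    return out


def run_circuit(
    circ: Circuit,
    init: QuantumState | None = None,
    backend: str = "sparse",
) -> QuantumState:
    """Apply the circuit's gates in order to ``init`` (all-zeros by default)."""
    if init is None:
        init = QuantumState.zero(circ.num_qubits)
    if init.num_qubits != circ.num_qubits:
        raise ValueError("initial state width must match circuit")
    if abs(init.norm_sq() - 1.0) > 1e-9:
        raise ValueError("initial state must be normalized")
    if backend == "dense":
        if circ.num_qubits > 24:
            raise ValueError("dense backend capped at 24 qubits")
        vec = init.to_dense()
        for gate in circ.gates:
            vec = _apply_gate_dense(vec, gate, circ.num_qubits)
        amps = {
            int(b): complex(vec[b])
            for b in np.flatnonzero(np.abs(vec) > _AMP_PRUNE)
        }
        return QuantumState(circ.num_qubits, amps)
    if backend != "sparse":
        raise ValueError("backend must be 'sparse' or 'dense'")
    amps = dict(init.amplitudes)
    for gate in circ.gates:
        amps = _prune(_apply_gate_sparse(amps, gate))
    return QuantumState(circ.num_qubits, amps)


def sample(
    state: QuantumState, qubits: list[int], shots: int, seed: int
) -> MeasurementDistribution:
    """Draw i.i.d. measurement outcomes of the listed qubits.

    Reproducible: outcomes are a multinomial draw from the marginal law under
    ``numpy``'s seeded PCG64 stream.
    """
    if shots < 1:
        raise ValueError("shots must be >= 1")
    if not qubits:
        raise ValueError("empty qubit list")
    probs = state.probabilities(qubits)
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=np.float64)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(shots, p)
    width = len(qubits)
    counts = {
        format(k, f"0{width}b"): int(c)
        for k, c in zip(keys, draws)
        if c > 0
    }
    return MeasurementDistribution(counts, shots, seed, width)


def inverse(circ: Circuit) -> Circuit:
    """Adjoint circuit: reversed order, each gate replaced by its adjoint."""
    inv = Circuit(circ.num_qubits)
    inv.gates = [g.adjoint() for g in reversed(circ.gates)]
    inv.measure = circ.measure
    return inv


# ---------------------------------------------------------------------------
# OpenQASM 2.0 export


def to_openqasm(circ: Circuit) -> str:
    """Emit OpenQASM 2.0.

    Multi-controlled X uses the qelib1 forms (cx/ccx/c3x/c4x); larger controls
    and multi-controlled phase gates beyond cp are declared ``opaque`` so the
    program stays grammatically valid.  0-controls are X-conjugated.
    """
    lines = ['OPENQASM 2.0;', 'include "qelib1.inc";']
    opaque: dict[str, str] = {}
    body: list[str] = []

    def q(i):
        return f"q[{i}]"

    for gate in circ.gates:
        ctrl = list(gate.controls)
        neg = [c for c, pol in ctrl if pol == 0]
        cq = [c for c, _ in ctrl]
        for c in neg:
            body.append(f"x {q(c)};")
        k = len(cq)
        args = ",".join(q(c) for c in cq + [gate.target])
        if gate.kind == "x":
            name = {0: "x", 1: "cx", 2: "ccx", 3: "c3x", 4: "c4x"}.get(k)
            if name is None:
                name = f"mcx{k}"
                opaque.setdefault(
                    name,
                    f"opaque {name} " + ",".join(f"a{i}" for i in range(k + 1)) + ";",
                )
            body.append(f"{name} {args};")
        elif gate.kind == "h":
            if k == 0:
                body.append(f"h {args};")
            else:
                name = f"mch{k}"
                opaque.setdefault(
                    name,
                    f"opaque {name} " + ",".join(f"a{i}" for i in range(k + 1)) + ";",
                )
                body.append(f"{name} {args};")
        elif gate.kind == "ry":
            if k == 0:
                body.append(f"ry({gate.param!r}) {args};")
            elif k == 1:
                body.append(f"cry({gate.param!r}) {args};")
            else:
                name = f"mcry{k}"
                opaque.setdefault(
                    name,
                    f"opaque {name}(theta) "
                    + ",".join(f"a{i}" for i in range(k + 1))
                    + ";",
                )
                body.append(f"{name}({gate.param!r}) {args};")
        else:  # p
            if k == 0:
                body.append(f"u1({gate.param!r}) {args};")
            elif k == 1:
                body.append(f"cu1({gate.param!r}) {args};")
            else:
                name = f"mcp{k}"
                opaque.setdefault(
                    name,
                    f"opaque {name}(lambda) "
                    + ",".join(f"a{i}" for i in range(k + 1))
                    + ";",
                )
                body.append(f"{name}({gate.param!r}) {args};")
        for c in neg:
            body.append(f"x {q(c)};")

    lines.extend(sorted(opaque.values()))
    lines.append(f"qreg q[{circ.num_qubits}];")
    if circ.measure:
        lines.append(f"creg c[{len(circ.measure)}];")
    lines.extend(body)
    if circ.measure:
        for b, qq in enumerate(circ.measure):
            lines.append(f"measure q[{qq}] -> c[{b}];")
    return "\n".join(lines) + "\n"
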
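"""Exact classical dynamics of synchronous Boolean networks.

Everything here is exhaustive over the ``N = 2**n`` state space: the state
transition graph (STG) is a functional graph (every state has exactly one
synchronous successor), so attractors are the cycles of an iterated map and
basins are found by pointer chasing.  The probability-weight propagation
implements the weight-shift picture of a quantum state transition — weight
``w_j`` at state ``j`` moves wholesale onto ``succ(j)`` — and serves as the
brute-force oracle that every circuit-level result in the package is checked
against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .boolnet import BooleanNetwork, truth_table

__all__ = [
    "StateTransitionGraph",
    "AttractorReport",
    "WeightVector",
    "InitSpec",
    "successor",
    "async_successor",
    "build_stg",
    "find_attractors",
    "predecessors",
    "garden_of_eden_states",
    "initial_distribution",
    "propagate_weights",
    "transient_times",
    "perturbation_mixture",
    "stg_to_tsv",
    "attractor_report_to_json",
]

DEFAULT_N_CAP = 20


# ---------------------------------------------------------------------------
# Containers


@dataclass(frozen=True)
class StateTransitionGraph:
    """Functional graph on the 2**n states: ``succ[j]`` is j's successor."""

    n: int
    succ: np.ndarray  # int64, length 2**n

    def __post_init__(self):
        if self.succ.shape != (1 << self.n,):
            raise ValueError("succ must have length 2**n")

    @property
    def n_states(self) -> int:
        return 1 << self.n


@dataclass(frozen=True)
class AttractorReport:
    """Attractor cycles with their basins.

    ``attractors[k]`` is a cycle (list of states, closed under succ);
    ``basin[k]`` is the set of states whose trajectory ends in cycle ``k``
    (the attractor states themselves included); ``basin_fraction[k]`` is
    ``len(basin[k]) / 2**n``.
    """

    n: int
    attractors: tuple[tuple[int, ...], ...]
    basin: tuple[frozenset[int], ...]

    @property
    def basin_fraction(self) -> tuple[float, ...]:
        total = 1 << self.n
        return tuple(len(b) / total for b in self.basin)

    def fixed_points(self) -> list[int]:
        return [cyc[0] for cyc in self.attractors if len(cyc) == 1]


@dataclass(frozen=True)
class WeightVector:
    """Probability weights over all 2**n network states at time ``t``."""

    w: np.ndarray
    t: int = 0

    def __post_init__(self):
        if np.any(self.w < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(float(self.w.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.w > 1e-12)


@dataclass(frozen=True)
class InitSpec:
    """Per-component initial bias angles plus an optional frozen set.

    ``thetas[i]`` in [0, pi] sets the probability ``sin²(theta/2)`` that
    component ``i`` starts active; pi/2 is unbiased (Hadamard), 0 pins the
    component off, pi pins it on.  ``frozen`` components are perturbed: they
    keep their initial value at every transition (superposed knockout /
    overexpression).
    """

    thetas: tuple[float, ...]
    frozen: frozenset[str] = frozenset()

    def __post_init__(self):
        for th in self.thetas:
            if not 0.0 <= th <= math.pi + 1e-12:
                raise ValueError(f"theta {th} outside [0, pi]")

    @classmethod
    def unbiased(cls, n: int, frozen: frozenset[str] | set[str] = frozenset()):
        return cls(tuple([math.pi / 2] * n), frozenset(frozen))

    @classmethod
    def biased(
        cls,
        net: BooleanNetwork,
        biases: dict[str, float],
        frozen: set[str] | frozenset[str] = frozenset(),
    ):
        thetas = [math.pi / 2] * net.n
        for name, theta in biases.items():
            thetas[net.index(name)] = theta
        return cls(tuple(thetas), frozenset(frozen))


# ---------------------------------------------------------------------------
# Successor maps


def successor(net: BooleanNetwork, state: int) -> int:
    """Synchronous image: every rule evaluated at once on ``state``."""
    values = {
        name: (state >> i) & 1 for i, name in enumerate(net.components)
    }
    out = 0
    for i, rule in enumerate(net.rules):
        out |= rule.evaluate(values) << i
    return out


def async_successor(net: BooleanNetwork, state: int, order: list[str]) -> int:
    """Deterministic asynchronous image: components updated one at a time in
    ``order`` (a permutation of the components), each rule reading the
    partially updated state."""
    if sorted(order) != sorted(net.components):
        raise ValueError("order must be a permutation of the components")
    current = state
    for name in order:
        i = net.index(name)
        values = {
            nm: (current >> j) & 1 for j, nm in enumerate(net.components)
        }
        bit = net.rules[i].evaluate(values)
        current = (current & ~(1 << i)) | (bit << i)
    return current


def build_stg(net: BooleanNetwork, n_cap: int = DEFAULT_N_CAP) -> StateTransitionGraph:
    """Exhaustive synchronous STG via vectorized truth tables."""
    if net.n > n_cap:
        raise ValueError(f"n={net.n} exceeds cap {n_cap}")
    succ = np.zeros(net.n_states, dtype=np.int64)
    for i in range(net.n):
        succ |= truth_table(net, i).astype(np.int64) << i
    return StateTransitionGraph(net.n, succ)


# ---------------------------------------------------------------------------
# Attractors & basins


def find_attractors(
    net: BooleanNetwork, n_cap: int = DEFAULT_N_CAP
) -> AttractorReport:
    """All attractor cycles and their basins, by memoized pointer chasing.

    Walks each state's trajectory until it hits a previously colored state or
    closes a new cycle; every visited state inherits the cycle's color, so the
    whole STG is processed in O(N).
    """
    stg = build_stg(net, n_cap)
    succ = stg.succ
    N = stg.n_states
    color = np.full(N, -1, dtype=np.int64)
    cycles: list[tuple[int, ...]] = []

    for start in range(N):
        if color[start] != -1:
            continue
        path: list[int] = []
        on_path: dict[int, int] = {}
        x = start
        while color[x] == -1 and x not in on_path:
            on_path[x] = len(path)
            path.append(x)
            x = int(succ[x])
        if color[x] != -1:
            c = int(color[x])
        else:
            # new cycle discovered: rotate so the cycle starts at its minimum
            cycle = path[on_path[x]:]
            pivot = cycle.index(min(cycle))
            cycles.append(tuple(cycle[pivot:] + cycle[:pivot]))
            c = len(cycles) - 1
        for s in path:
            color[s] = c

    basins = tuple(
        frozenset(int(s) for s in np.flatnonzero(color == c))
        for c in range(len(cycles))
    )
    return AttractorReport(net.n, tuple(cycles), basins)


def predecessors(
    stg: StateTransitionGraph, target: int, t_inv: int = 1
) -> frozenset[int]:
    """States mapped onto ``target`` by exactly ``t_inv`` synchronous steps.

    For a fixed-point target this set also contains every shorter-horizon
    predecessor (and the target itself), since the target re-enters itself.
    An empty set means ``target`` is unreachable at that horizon (e.g. a
    Garden-of-Eden state at ``t_inv = 1``).
    """
    if t_inv < 1:
        raise ValueError("t_inv must be >= 1")
    if not 0 <= target < stg.n_states:
        raise ValueError("target out of range")
    image = np.arange(stg.n_states, dtype=np.int64)
    for _ in range(t_inv):
        image = stg.succ[image]
    return frozenset(int(s) for s in np.flatnonzero(image == target))


def garden_of_eden_states(stg: StateTransitionGraph) -> frozenset[int]:
    """States with no incoming STG edge (unreachable after one transition)."""
    reached = np.zeros(stg.n_states, dtype=bool)
    reached[stg.succ] = True
    return frozenset(int(s) for s in np.flatnonzero(~reached))


# ---------------------------------------------------------------------------
# Weight propagation (the quantum-transition oracle)


def initial_distribution(net: BooleanNetwork, init: InitSpec) -> WeightVector:
    """Product-Bernoulli law induced by rotating each qubit of |0> by theta_i:
    ``w(x) = prod_i sin²(theta_i/2)`` if ``x_i = 1`` else ``cos²(theta_i/2)``.
    """
    if len(init.thetas) != net.n:
        raise ValueError("InitSpec length must equal n")
    for name in init.frozen:
        net.index(name)  # raises KeyError if unknown
    w = np.ones(net.n_states, dtype=np.float64)
    states = np.arange(net.n_states, dtype=np.int64)
    for i, theta in enumerate(init.thetas):
        p1 = math.sin(theta / 2.0) ** 2
        bit = ((states >> i) & 1).astype(np.float64)
        w *= bit * p1 + (1.0 - bit) * (1.0 - p1)
    return WeightVector(w, t=0)


def _frozen_succ(net: BooleanNetwork, frozen: frozenset[str]) -> np.ndarray:
    """Successor map with frozen components pinned to their current value."""
    stg = build_stg(net)
    if not frozen:
        return stg.succ
    mask = 0
    for name in frozen:
        mask |= 1 << net.index(name)
    states = np.arange(net.n_states, dtype=np.int64)
    return (stg.succ & ~mask) | (states & mask)


def propagate_weights(
    net: BooleanNetwork,
    w: WeightVector,
    T: int,
    frozen: frozenset[str] | set[str] = frozenset(),
) -> WeightVector:
    """Push probability weights along the STG for ``T`` synchronous steps.

    ``w'[i] = sum_j [succ(j) = i] w[j]``, with frozen components held at their
    per-state value.  Total weight is conserved exactly; the support can only
    shrink (several states may share a successor, none splits).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    frozen = frozenset(frozen)
    succ = _frozen_succ(net, frozen)
    weights = w.w.astype(np.float64).copy()
    for _ in range(T):
        weights = np.bincount(succ, weights=weights, minlength=net.n_states)
    return WeightVector(weights, t=w.t + T)


def transient_times(stg: StateTransitionGraph) -> tuple[int, float]:
    """(max, mean) number of steps until a trajectory enters its attractor
    cycle; used to pick a sufficient transition count T."""
    succ = stg.succ
    N = stg.n_states
    on_cycle = np.zeros(N, dtype=bool)
    image = np.arange(N, dtype=np.int64)
    for _ in range(N):  # after N iterations every state sits on its cycle
        image = succ[image]
    on_cycle[np.unique(image)] = True
    steps = np.zeros(N, dtype=np.int64)
    current = np.arange(N, dtype=np.int64)
    pending = ~on_cycle[current]
    k = 0
    while pending.any():
        k += 1
        current = np.where(pending, succ[current], current)
        steps[pending] += 1
        pending = ~on_cycle[current]
    return int(steps.max()), float(steps.mean())


def perturbation_mixture(
    net: BooleanNetwork, init: InitSpec, T: int
) -> WeightVector:
    """Propagated law under frozen perturbations, computed the classical way.

    Enumerates all 2**|P| knockout/overexpression combinations of the frozen
    set, propagates each pinned sub-network from the conditioned initial law,
    and mixes the results with the product-Bernoulli weights of the frozen
    components.  Equals ``propagate_weights`` with the same frozen set; kept
    separate as an independent oracle for the circuit-level perturbation test.
    """
    frozen = sorted(init.frozen, key=net.index)
    w0 = initial_distribution(net, InitSpec(init.thetas))
    if not frozen:
        return propagate_weights(net, w0, T)
    idx = [net.index(name) for name in frozen]
    total = np.zeros(net.n_states, dtype=np.float64)
    for combo in range(1 << len(frozen)):
        pi = 1.0
        mask_val = 0
        for b, (name, i) in enumerate(zip(frozen, idx)):
            bit = (combo >> b) & 1
            p1 = math.sin(init.thetas[i] / 2.0) ** 2
            pi *= p1 if bit else (1.0 - p1)
            mask_val |= bit << i
        if pi == 0.0:
            continue
        # condition the unfrozen product law on the frozen assignment
        states = np.arange(net.n_states, dtype=np.int64)
        sel = np.ones(net.n_states, dtype=bool)
        for i in idx:
            sel &= ((states >> i) & 1) == ((mask_val >> i) & 1)
        w = np.where(sel, w0.w, 0.0)
        w = w / w.sum()
        out = propagate_weights(
            net, WeightVector(w), T, frozenset(frozen)
        )
        total += pi * out.w
    return WeightVector(total, t=T)


# ---------------------------------------------------------------------------
# Exports


def stg_to_tsv(net: BooleanNetwork) -> str:
    """STG edge list as TSV: state, successor, basin id (row per state)."""
    report = find_attractors(net)
    stg = build_stg(net)
    basin_of = {}
    for k, basin in enumerate(report.basin):
        for s in basin:
            basin_of[s] = k
    lines = ["state\tsuccessor\tbasin"]
    for j in range(stg.n_states):
        lines.append(f"{j}\t{int(stg.succ[j])}\t{basin_of[j]}")
    return "\n".join(lines) + "\n"


def attractor_report_to_json(net: BooleanNetwork, report: AttractorReport) -> str:
    from .boolnet import state_to_string

    payload = {
        "n": report.n,
        "attractors": [
            {
                "states": list(cyc),
                "register_order": [
                    state_to_string(s, report.n, "register") for s in cyc
                ],
                "file_order": [
                    state_to_string(s, report.n, "file") for s in cyc
                ],
                "basin_size": len(report.basin[k]),
                "basin_fraction": report.basin_fraction[k],
            }
            for k, cyc in enumerate(report.attractors)
        ],
    }
    return json.dumps(payload, indent=2)
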
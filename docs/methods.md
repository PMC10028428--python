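# Methods

## Model and encodings

A Boolean network is an ordered list of `n` named components with one rule
`f_i` each over AND/OR/NOT, constants 0/1 and parentheses, read from the
BoolNet "targets, factors" text dialect.  Unregulated inputs must carry an
explicit rule line (typically `A, A`); nothing is implied silently.

All internal logic uses integer state encodings: component `i` (file order,
0-indexed) is bit `i` and qubit `i`, and a state encodes as `Σ x_i·2^i`
(little-endian).  Because printed bit strings are ambiguous without a
declared order, two renderers are provided: *register order* (highest qubit
leftmost — the plain binary expansion, and the convention of all strings in
this documentation) and *file order* (component 0 leftmost).  The cortical
fixture orders its components (Fgf8, Emx2, Pax6, Sp8, Coup_tfi); under the
register rendering its attractors read 10010 (anterior, state 18) and 01101
(posterior, state 13), with 01001 (state 9) the posterior attractor's only
non-trivial one-step predecessor.  This ordering was fixed by verifying the
rendered strings against the brute-force attractor search.

## Classical engine (the oracle)

Everything classical is exhaustive and exact up to a configurable cap of
`n ≤ 20`:

* the STG is built from vectorized truth tables (`succ[j]` for all `2^n`
  states at once);
* attractors are the cycles of the iterated map, found by pointer chasing
  with per-basin memoization (O(N)); basins include the attractor states
  themselves, which is what makes the cortical basins come out at 28/32 and
  4/32;
* `t_inv`-step predecessors are the preimage of the `t_inv`-fold composed
  map;
* probability propagation pushes weights along `succ` with `bincount`; a
  frozen set pins the corresponding bits of `succ` to their per-state
  values.

A separate `perturbation_mixture` routine recomputes the frozen-set law the
long way — enumerate all `2^|P|` knockout/overexpression combinations,
propagate each pinned sub-network from the conditioned initial law, mix with
the product-Bernoulli weights — so the circuit-level perturbation test has
an oracle that does not share code with the direct frozen propagation.

Deterministic asynchronous updates (a fixed component order, each rule
reading the partially updated state) are supported in both the classical
engine and the compiler; random-order asynchrony is just a seeded choice of
orders on top.

## Circuits and simulation

The gate set is X, H, RY(θ) and the phase gate P(λ), each with any number of
polarized controls (0-controls are native control polarities, not separate
primitives; at QASM export they become X conjugation).  A multi-controlled Z
is P(π) with controls; the H·MCX·H realization is asserted equivalent in the
tests.  Every gate is its own adjoint except RY/P, which negate their angle;
circuit inversion reverses the gate list and takes adjoints.

Simulation is a sparse amplitude map keyed by basis integers.  The rule
blocks are basis permutations, so between registers the support of a
transition circuit never exceeds `2^n` — this is why `(T+1)n`-qubit circuits
(25 qubits for the cortical `T=4` run) simulate in milliseconds, and why a
counting circuit's support stays at `2^r·2^n`.  Amplitudes below 1e-14 are
pruned after each gate; all equality checks in the tests use 1e-9.  A dense
NumPy backend (capped at 24 qubits) cross-checks the sparse one on random
circuits.  Sampling draws a multinomial from the exact marginal law under
NumPy's seeded PCG64 generator; every CLI output records its seed, and
replaying a recorded config+seed reproduces byte-identical JSON.

## Rule synthesis

Each rule becomes one block targeting a fresh qubit: one multi-controlled X
per satisfying assignment of the rule restricted to its support variables.
Minterms are disjoint, so the block computes `y ⊕ f_i(x)` exactly and is its
own inverse.  An optional flag merges implicant pairs differing in one
cared-for literal (one Quine–McCluskey pass; the merge preserves the XOR
semantics because a merged cube covers exactly its two disjoint parents).
No ancilla sharing across rules: blocks write to fresh qubits so the layout
stays at `(T+1)(n−|P|)+|P|` qubits, with frozen components keeping their
single register-0 qubit.  At biological in-degrees (≤ 5 in the fixture) the
blocks are tiny — every cortical rule is a single multi-controlled X.

Initialization emits H when θ is exactly π/2 and RY(θ) otherwise, keeping
gate counts of the unbiased circuits minimal.  Measurement markers cover
only the final logical register (register T plus frozen qubits).

## Grover search

The library's iterate is `[A(I−2|0⟩⟨0|)A†]·O`: the oracle `O` (forward
transitions, phase mark on register `t_inv` conditioned bitwise on ω,
uncompute) followed by the reflection about the prepared state `A|0⟩`.
This differs from the textbook operator by a global phase of −1, which is
irrelevant for search.  The preparation `A` defaults to `H⊗n` but accepts
any per-component RY bias, in which case the diffusion automatically becomes
the reflection about that prepared state; the closed-form success
probability is only quoted for uniform preparation, and the non-uniform case
reports the exact statevector mass instead.

Cyclic-attractor targets are permitted but flagged with a warning in the
result (amplification can depend on which cycle state is marked).  When the
solution count is unknown, an adaptive schedule (iteration counts drawn
uniformly from a geometrically growing range, c = 6/5, each measurement
verified by a classical successor check) terminates on the first verified
solution and reports total oracle calls; the classical verification makes
the loop safe for targets with no predecessors.

## Quantum counting

Phase estimation over the Grover operator: `r` readout qubits in uniform
superposition control `G^(2^j)`; wrapping each gate of the iterate with the
control is exact because the preparation/uncompute structure keeps ancillas
clean.  Since a controlled global phase is a physical relative phase, each
controlled iterate is paired with P(π) on its control qubit, restoring the
convention in which the operator's eigenvalues on the rotation subspace are
`e^{±2i·arcsin√(M/N)}`.  The inverse QFT is emitted swap-free; the resulting
bit reversal is undone by the readout order rather than by three-CX swaps.
A readout `y` maps to `M̂ = N·sin²(πy/2^r)` (computed on `min(y, 2^r−y)` so
the mirror symmetry is exact in floating point); the reported point estimate
is the distribution mean, with the mode alongside.  With uniform
preparation both eigenvectors carry weight 1/2, so the two mirror peaks are
equally likely and map to the same `M̂`.  An `M = 0` target leaves the
prepared state an eigenvector with phase 0, so the readout is
deterministically `y = 0`.

## Problem sizes and test design

All shipped analyses are exhaustive-by-construction and sized accordingly:
the fixture has `n = 5` (`N = 32`), sampled runs use 10,000 shots for
transition/Grover experiments and 1,000 for counting, and the property
suites sweep 50 seeded random networks with `n ≤ 6`, `T ≤ 3`, random biases
and frozen sets, plus readout registers `r ∈ {3..6}`.  The central
correctness property — the measured-register law equals classical weight
propagation to 1e-9 for arbitrary bias/frozen/mode choices — is what every
other result rests on; sampled assertions use 3–4 binomial standard errors.

The random-network generator draws uniform in-degrees up to a bound,
uniform regulator sets and uniform non-constant truth tables.  That gives
syntactically valid, well-conditioned test inputs but does not emulate the
scale-free topology, canalizing rules or long transients of curated
biological models, so passing property tests demonstrates correctness of
the machinery, not biological realism of random ensembles.

## Limitations

* No noise models, density matrices, hardware transpilation or error
  mitigation: the simulator is ideal by design, and hardware-fidelity
  questions are out of scope.
* Exhaustive methods cap at `n = 20` (classical) and sparse-support sizes;
  SAT/BDD attractor search for large networks is deliberately not provided.
* Probabilistic Boolean networks, multi-valued logic and SBML-qual import
  are not supported.
* OpenQASM export uses qelib1 multi-controlled forms up to four controls
  and declares larger ones `opaque`; consumers needing full decompositions
  must expand those themselves.
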
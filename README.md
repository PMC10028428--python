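# qbnet — quantum Boolean networks for gene-regulatory dynamics

`qbnet` compiles logical models of gene regulation (Boolean networks in the
BoolNet rule-file format) into reversible quantum circuits, simulates their
superposition dynamics exactly, and runs Grover predecessor search and
quantum counting on the model's state transition graph.  An exhaustive
classical engine computes the same quantities by brute force and serves as
the verification oracle for every circuit-level result.

It is aimed at systems biologists who work with Boolean network models of
regulatory processes — attractors as phenotypes, basin sizes as phenotype
frequencies, knockouts/overexpressions as perturbations — and want to
explore how those analyses map onto quantum algorithms.

## The model

A Boolean network couples `n` components with binary activities
`x_i(t) ∈ {0,1}` through rules `f_i` built from AND/OR/NOT; a synchronous
update applies all rules at once.  The dynamics is the functional graph
(state transition graph, STG) on the `N = 2^n` states; every trajectory ends
in an attractor cycle, and the set of states reaching a given attractor is
its basin.

The quantum encoding assigns component `i` to qubit `i`.  A transition is
compiled as a reversible circuit mapping `|x⟩|0⟩ → |x⟩|f(x)⟩` (one
multi-controlled-X block per rule, obtained from its truth-table minterms),
so a Hadamard layer on the input register evaluates all `N` classical
transitions at once; `T` repeated transitions use one circuit of `(T+1)n`
qubits.  Measuring the final register samples states with the weights
obtained by pushing the initial probability law along the STG:
`w'_i = Σ_j δ_{succ(j),i} w_j`.  After enough transitions only attractor
states survive, with probabilities equal to their basin fractions.
Initial biases are `Ry(θ)` rotations (`P(x_i=1) = sin²(θ/2)`); freezing a
component's qubit across all transitions yields a superposed
knockout/overexpression screen: the measured law is the product-Bernoulli
mixture over all `2^|P|` pinned sub-networks.

On top of the transition circuits:

* **Grover predecessor search** marks a state ω and amplifies all states
  that reach it in exactly `T_inv` steps.  The oracle is "forward
  transitions, phase flip on equality with ω, uncompute"; after `G`
  iterations the solution set of size `M` carries probability
  `sin²((2G+1)·arcsin√(M/N))`, maximal near `G_opt = ⌊(π/4)√(N/M)⌋`.
* **Quantum counting** estimates `M` itself by phase estimation of the
  Grover operator (eigenvalues `e^{±2i·arcsin√(M/N)}`) with `r` readout
  qubits; a readout `y` maps to `M̂ = N·sin²(πy/2^r)`.

Measured distributions are compared with the squared Hellinger fidelity
`F_s(I,O) = (Σ_s √(p_I(s)·p_O(s)))²`, its uniform-baseline-normalized form,
and the binomial sampling error `ε = √(p(1−p)/m)`.

## Worked example

The package ships the `n=5` mammalian cortical area development network
(Fgf8, Emx2, Pax6, Sp8, Coup_tfi) as `fixture_cortical()` / `--fixture
cortical`.  Its two fixed-point attractors are the anterior (10010) and
posterior (01101) expression phenotypes (register-order strings, highest
qubit leftmost):

```text
$ qbn attractors --fixture cortical --out out
attractor 0: 10010 (basin 28/32 = 0.8750)
attractor 1: 01101 (basin 4/32 = 0.1250)

$ qbn transit --fixture cortical -T 4 --shots 10000 --seed 1 --out out
circuit: {"num_qubits": 25, "num_gates": 25, ...}
seed=1 shots=10000 outcomes=2
```

After four transitions from the uniform superposition only the two
attractors remain, sampled at their basin fractions (≈87% / 13%).  Searching
for the predecessors of the rarer attractor:

```text
$ qbn grover --fixture cortical --target 01101 --tinv 1 -G 3 --shots 10000 --seed 1 --out out
cumulative solution frequency 0.9601 (analytic 0.9613)
```

i.e. with the optimal three Grover iterations, 96% of measurements land on
the two states (01101 itself and 01001) that reach the attractor in one
step, although they make up only 6.25% of the state space.  Counting them
instead of searching:

```text
$ qbn count --fixture cortical --target 01101 --tinv 1 -r 6 --shots 1000 --seed 1 --out out
M estimate: mean 1.94, mode 1.889 (classical truth 2)
```

All subcommands accept any BoolNet-format rule file via `--rules`; see
`examples/` for runnable scripts covering basins, bias scans, perturbations,
search and counting.

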
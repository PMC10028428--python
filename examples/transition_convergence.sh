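#!/bin/sh
# Single transition from uniform superposition (7 outcomes, 00000 at 43.75%),
# then T=4 convergence: only the two attractors remain, at basin weights.
set -e
qbn transit --fixture cortical -T 1 --shots 10000 --seed 1 --out out/transit_T1
qbn transit --fixture cortical -T 4 --shots 10000 --seed 1 --out out/transit_T4
qbn qasm-export --fixture cortical -T 1 --out out/qasm
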
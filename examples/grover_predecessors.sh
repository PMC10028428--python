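#!/bin/sh
# Grover search for the predecessors of the smaller attractor 01101:
# Tinv=1 (solutions 01101, 01001) with G=1 and the optimal G=3;
# Tinv=2 (the whole 4-state basin) with G=1 and the optimal G=2.
set -e
qbn grover --fixture cortical --target 01101 --tinv 1 -G 1 --shots 10000 --seed 1 --out out/grover_t1_g1
qbn grover --fixture cortical --target 01101 --tinv 1 -G 3 --shots 10000 --seed 1 --out out/grover_t1_g3
qbn grover --fixture cortical --target 01101 --tinv 2 -G 1 --shots 10000 --seed 1 --out out/grover_t2_g1
qbn grover --fixture cortical --target 01101 --tinv 2 -G 2 --shots 10000 --seed 1 --out out/grover_t2_g2
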
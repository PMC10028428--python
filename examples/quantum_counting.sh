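#!/bin/sh
# Quantum counting of the predecessors of attractor 01101 for growing
# readout registers; the M estimates bracket the classical truths
# M=2 (Tinv=1) and M=4 (Tinv=2).
set -e
for r in 3 4 5 6; do
  qbn count --fixture cortical --target 01101 --tinv 1 -r "$r" --shots 1000 --seed 1 --out "out/count_t1_r$r"
  qbn count --fixture cortical --target 01101 --tinv 2 -r "$r" --shots 1000 --seed 1 --out "out/count_t2_r$r"
done
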
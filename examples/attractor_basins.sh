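#!/bin/sh
# Exhaustive attractor/basin analysis of the cortical fixture:
# two fixed points (10010, 01101) with basins 87.5% / 12.5%.
set -e
qbn attractors --fixture cortical --out out/attractors
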
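#!/bin/sh
# Ry(theta) bias scan per component (which genes shift the attractor law?)
# and a 2-component superposed perturbation: Pax6 biased toward
# overexpression, Coup_tfi toward knockout, both frozen over T=3.
set -e
for c in Fgf8 Emx2 Pax6 Sp8 Coup_tfi; do
  qbn bias-scan --fixture cortical --component "$c" -T 4 --shots 10000 \
      --seed 1 --out out/bias
done
qbn perturb --fixture cortical -T 3 --shots 10000 --seed 1 \
    --frozen Pax6 --theta 'Pax6=3*pi/4' \
    --frozen Coup_tfi --theta 'Coup_tfi=pi/4' \
    --out out/perturb
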
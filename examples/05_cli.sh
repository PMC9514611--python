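#!/bin/sh
# The same computations from the shell: write a model config, report the
# graph structure, tabulate the exact bSFS, and cross-check it by simulation.
set -e

cat > /tmp/im_demo.yaml <<'YAML'
model:
  demes: [A, B, AB]
  samples: {A: 2, B: 2}
  relative_sizes: {A: 1.0, B: 0.4615, AB: 1.1538}
  migrations:
    - {source: A, dest: B, rate: 1.82}
  event: {sources: [A, B], dest: AB, time: 3.846}
theta: 1.152
kmax: 2
YAML

coalgf graph-stats --config /tmp/im_demo.yaml
coalgf exact --config /tmp/im_demo.yaml --out /tmp/im_exact.tsv
coalgf mc --config /tmp/im_demo.yaml --reps 500 --seed 1 --out /tmp/im_mc.tsv
head -12 /tmp/im_exact.tsv
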
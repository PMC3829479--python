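#!/usr/bin/env bash
# End-to-end shell pipeline: simulate genotypes, reduce, cluster with partial
# labels, evaluate against the truth.  Every output gets a JSON manifest.
set -euo pipefail
work=$(mktemp -d)

cat > "$work/model.yaml" <<'YAML'
p: 600
F_g: 0.15
groups:
  G1:
    - {name: a, size: 20, F: 0.05}
    - {name: b, size: 20, F: 0.05}
  G2:
    - {name: c, size: 20, F: 0.05}
YAML

sssc simulate --model "$work/model.yaml" --seed 1 --out-prefix "$work/sim"
sssc pca --genotypes "$work/sim.genotypes.tsv" -j 5 --out "$work/scores.tsv"

# reveal every third sample's subpopulation as partial labels
tail -n +2 "$work/sim.subpopulations.tsv" | awk 'NR % 3 == 1' > "$work/partial.tsv"

sssc cluster --coords "$work/scores.tsv" --labels "$work/partial.tsv" \
    --k 3 --alpha 1 --beta 10 --t 5 --seed 0 --out "$work/clusters.tsv"
sssc evaluate --pred "$work/clusters.tsv" --truth "$work/sim.subpopulations.tsv"

rm -r "$work"
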
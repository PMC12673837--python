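#!/usr/bin/env bash
# Full shell pipeline: simulate -> train -> evaluate -> predict -> attention.
set -euo pipefail
WORK=$(mktemp -d)

dtifuse simulate --preset tiny_complete --out "$WORK/data"

# a fast curriculum so all three modalities engage within the short demo run
cat > "$WORK/cfg.yaml" <<'YAML'
batch_size: 16
probe_size: 16
curriculum:
  midpoint: 1
  fade_window: 1
  steepness: 2.0
YAML

dtifuse train --data "$WORK/data" --out "$WORK/ckpt" \
    --config "$WORK/cfg.yaml" --epochs 5 --seed 1

# metrics on the test split, plus a drop-modality and a missing-rate sweep
dtifuse evaluate --checkpoint "$WORK/ckpt" --out "$WORK/metrics" \
    --drop-modality transcriptomics --missing-rate 0.3

dtifuse predict --checkpoint "$WORK/ckpt" --out "$WORK/scores.csv"
dtifuse inspect-attention --checkpoint "$WORK/ckpt" --out "$WORK/attention.csv"

echo "--- per-sample modality weights (first lines) ---"
head -n 4 "$WORK/attention.csv"
rm -rf "$WORK"
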
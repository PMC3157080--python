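#!/usr/bin/env bash
# Shell workflow: simulate a cohort, score it leave-one-out, evaluate.
# Every output is plain TSV with a commented parameter header.
set -euo pipefail

outdir="${1:-/tmp/nodalrisk_demo}"
mkdir -p "$outdir"

nodalrisk simulate --what cohort --n-samples 200 --effect-size 1.5 \
    --seed 42 --outdir "$outdir/data"

nodalrisk predict \
    --reference-matrix "$outdir/data/matrix.tsv" \
    --reference-labels "$outdir/data/labels.tsv" \
    --panel "$outdir/data/panel.tsv" \
    --query-matrix "$outdir/data/matrix.tsv" \
    --leave-one-out \
    --out "$outdir/predictions.tsv"

nodalrisk evaluate \
    --predictions "$outdir/predictions.tsv" \
    --labels "$outdir/data/labels.tsv" \
    --prevalence 0.23 \
    --out "$outdir/report.tsv"

echo "---"
cat "$outdir/report.tsv"
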
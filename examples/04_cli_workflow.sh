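#!/usr/bin/env bash
# Shell workflow: export a simulated dataset, then scan it from the CLI.
set -euo pipefail

# one replicate with a 500 bp causal cluster, written as VCF + phenotype TSV
qpss simulate --export --n 200 --c 0.6 --cluster 500 \
    --region-length 100000 --seed 5 --out rep

# scan it with two window grids; the TSV gets a reproducibility header
qpss scan --vcf rep.vcf --pheno rep.pheno.tsv --region 1:1-100000 \
    --window-sizes 2000,500 --permutations 999 --seed 1 --out scan.tsv

head -5 scan.tsv
# the 'best' lines printed by the command give, per grid, the maximizing
# window and its permutation/GPD p-value
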
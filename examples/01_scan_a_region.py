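"""Scan a simulated region for a phenotype-associated rare-variant cluster.

Builds a small dataset with a known causal cluster, runs the sliding-window
scan with permutation/GPD p-values, and prints the best window per grid.
"""

import numpy as np

import qpss

# a haplotype pool over 100 kb with a rare-skewed frequency spectrum
pool = qpss.simulate_haplotypes(n_hap=4000, region_length=100_000, seed=1)
genotypes = qpss.draw_genotypes(pool, n=500, seed=2)

# plant a 500 bp causal cluster: every rare variant inside it raises the
# phenotype by beta_j = c * |log10 MAF_j|
causal, (c_start, c_end) = qpss.place_cluster(genotypes, 500, seed=3)
y, betas = qpss.simulate_phenotype(genotypes, causal, c=0.6, seed=4)
print(f"true cluster {c_start}-{c_end} with {len(causal)} causal variants, "
      f"h2 = {qpss.heritability(genotypes, causal, betas, y):.3f}")

region = qpss.Region("1", 1, 100_000)
specs = [qpss.WindowSpec(2000, 1000), qpss.WindowSpec(500, 250)]
result = qpss.scan_with_pvalues(y, genotypes, region, specs, B=999, seed=5)

print(f"carriers n_G = {result.n_carriers}, windows m = {result.m_total}, "
      f"Bonferroni alpha* = {0.05 / result.m_total:.2e}")
for _, row in result.best_rows().iterrows():
    hit = "overlaps" if row.window_start <= c_end and c_start <= row.window_end \
        else "misses"
    print(f"  [{row.spec}] best window {row.window_start}-{row.window_end} "
          f"signed stat {row.signed_stat:+.2f}, p = {row.p_value:.2e} "
          f"({row.p_method}) -> {hit} the true cluster")
# A positive signed statistic means carriers inside the window have higher
# phenotype values than carriers outside it; p far below alpha* localizes
# the cluster.
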
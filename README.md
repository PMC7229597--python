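# qpss

Sliding-window scan statistic for localizing clusters of rare variants
associated with a **continuous** phenotype inside a larger genomic region.

Rare-variant association tests such as burden tests or SKAT answer "is this
gene associated?" for a pre-specified variant set. `qpss` answers a
different, *competitive* question: **where** inside a region of interest do
phenotype-associated rare variants cluster? It slides windows of several
sizes across the region, compares rare-allele carriers inside each window
against carriers outside it, and reports the window maximizing a signed
log likelihood ratio together with a permutation p-value. Intended users
are statistical geneticists working with WGS/WES genotypes and quantitative
endophenotypes (e.g. CSF biomarker levels).

## The statistic

Let *G* be the region, *n<sub>G</sub>* the samples carrying ≥ 1 rare allele
(MAF < 0.05 by default) in *G*, and *W ⊆ G* a window splitting those
carriers into *n<sub>W+</sub>* (≥ 1 rare allele inside *W*) and
*n<sub>W−</sub>*. With group means μ̂<sub>W+</sub>, μ̂<sub>W−</sub> and
maximum-likelihood variances (divisor *n<sub>G</sub>*)

```
σ̂²_W = (1/n_G) [ Σ_{W+} (y_i − μ̂_{W+})² + Σ_{W−} (y_i − μ̂_{W−})² ]
σ̂²_0 = (1/n_G)   Σ_G    (y_i − μ̂_0)²

ln L̂R_W = (n_G / 2) · ln(σ̂²_0 / σ̂²_W)
```

the scan reports `max_W | ln L̂R_W · sgn(μ̂_{W+} − μ̂_{W−}) |`; the sign
separates risk (carriers high) from protective (carriers low) clusters.
The null distribution is unknown, so p-values come from permuting
phenotypes among the *n<sub>G</sub>* carriers, with a generalized-Pareto
(GPD) tail fit to the largest null statistics for p-values far below 1/B.
Significance is judged against the Bonferroni level α/m, m being the
number of windows examined.

## Worked example

```python
import qpss

pool      = qpss.simulate_haplotypes(n_hap=4000, region_length=100_000, seed=1)
genotypes = qpss.draw_genotypes(pool, n=500, seed=2)           # MAF<0.05, no singletons
causal, (c_start, c_end) = qpss.place_cluster(genotypes, 500, seed=3)
y, betas  = qpss.simulate_phenotype(genotypes, causal, c=0.6, seed=4)

region = qpss.Region("1", 1, 100_000)
specs  = [qpss.WindowSpec(2000, 1000), qpss.WindowSpec(500, 250)]
result = qpss.scan_with_pvalues(y, genotypes, region, specs, B=999, seed=5)
```

Running `python examples/01_scan_a_region.py` (which is this code) prints:

```
true cluster 80565-81064 with 2 causal variants, h2 = 0.056
carriers n_G = 500, windows m = 500, Bonferroni alpha* = 1.00e-04
  [2000/1000] best window 80001-82000 signed stat +4.78, p = 4.64e-03 (gpd) -> overlaps the true cluster
  [500/250] best window 80501-81000 signed stat +15.42, p = 1.75e-06 (gpd) -> overlaps the true cluster
```

The 500 bp grid pins the planted 500 bp cluster exactly: its best window
sits inside the true interval, the positive sign says carriers have raised
phenotype values, and p = 1.8 × 10⁻⁶ beats the Bonferroni level 10⁻⁴.
The coarser 2 kb grid finds the same locus with less resolution.

The same workflow is available from the shell (`qpss scan --vcf ...
--pheno ... --region chrom:start-end`, `qpss simulate ...`); see
`examples/04_cli_workflow.sh`. Genotypes can be VCF or PLINK bed/bim/fam;
phenotypes a TSV/CSV keyed by sample id.

## Simulation study

`qpss.SimScenario` + `qpss.run_scenario` reproduce the evaluation design:
10,000 synthetic haplotypes over 1 Mb with a rare-skewed frequency
spectrum, diploid samples (n = 500/1000), common variants and singletons
removed, phenotypes `y = Σ β_j g_j + ε` with `β_j = c·|log10 MAF_j|`,
window grids 5 k/2 k/1 k/500 bp slid by half their size. Empirical type-I
error and power (with or without the requirement that the best window
overlap the true cluster) are aggregated per grid.

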
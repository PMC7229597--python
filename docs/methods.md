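# Methods

## The scan model

The scan treats the phenotypes of rare-variant carriers in a region *G*
as Gaussian and asks, window by window, whether carriers of a rare allele
*inside* the window W are more homogeneous (and shifted) relative to
carriers whose rare alleles all lie *outside* it. Under the null the
pooled two-group maximum-likelihood variance σ̂²_W equals the single-group
variance σ̂²_0, so the log likelihood ratio

    ln L̂R_W = (n_G / 2) · ln(σ̂²_0 / σ̂²_W) ≥ 0

measures the variance reduction achieved by splitting the carriers at W.
Attaching sgn(μ̂_{W+} − μ̂_{W−}) distinguishes risk from protective
clusters; the scan maximizes the absolute signed statistic over all
windows of each (size, slide) grid. This is a *competitive* test: the
null hypothesis is equal association inside and outside the window, not
no association at all, which is what lets the scan localize a signal
within an already-interesting region.

Assumptions worth stating: normality of carrier phenotypes within groups
(only through the likelihood form; inference is permutation-based and
therefore exact in distribution), a shared within-group variance, same
direction of effect within a cluster (means are compared, so opposing
effects inside one window cancel), and no covariate adjustment.

## Conventions and degenerate cases

* Coordinates are 1-based inclusive; a 2000 bp window `a..a+1999`.
* Windows anchor at the region start and advance by the slide; trailing
  windows truncate at the region end, so a region of length L yields
  exactly ceil(L / slide) windows per grid (400/1000/2000/4000 for 1 Mb).
* "Rare" is strict: 0 < MAF < threshold (default 0.05); a variant at
  exactly the threshold is excluded. Singleton removal is a flag — on in
  the simulation pipeline, off by default for file-based scans.
* MAF is folded (≤ 0.5) and computed over non-missing calls; missing
  dosages count as non-carrier when forming groups (conservative call).
* Windows with no variants, or with an empty W+ or W− group, are skipped
  by the argmax but still counted in m: the Bonferroni denominator is the
  geometric window count, not the evaluated count.
* Exact mean tie μ̂_{W+} = μ̂_{W−}: sign 0, signed statistic 0. Argmax
  ties resolve to the first window in genomic order. σ̂²_W = 0 with
  σ̂²_0 > 0 (degenerate duplicated phenotypes) is reported as an infinite
  sentinel and flagged rather than fed silently into results; σ̂²_0 = 0
  makes every statistic 0.
* The statistic is invariant to shifting and (nonzero) scaling of the
  phenotype, so no standardization is applied.

## Permutation inference and the GPD tail

Phenotype labels are permuted among the n_G region carriers only — the
statistic is a function of carrier phenotypes alone, so permuting
non-carriers would only dilute the null. The W+/W− structure is held
fixed; because the statistic depends on a permutation only through the
sum of phenotypes assigned to W+, one batch of B permutations provides
the null for every window size via prefix sums.

The empirical p-value uses the add-one convention p = (1 + r)/(B + 1),
which keeps the estimator valid. When fewer than 10 of the B null values
reach the observed statistic, a generalized Pareto distribution is fitted
by maximum likelihood to the top 250 null statistics above a threshold
midway between the 250th and 251st largest, and

    p = (n_exc / B) · (1 − F_GPD(t_obs − u)).

A Kolmogorov–Smirnov check at level 0.05 guards the fit; on failure the
tail shrinks by 10 values and refits, down to a floor of 50, after which
the empirical p is returned with a warning. All of these constants are
arguments, not hard-coded.

One estimator detail matters greatly in the deep tail. The statistic is a
likelihood ratio whose null tail is χ²-like, i.e. exponential-type: very
large reference samples give small *positive* fitted GPD shapes
(+0.03…+0.07 at these thresholds). At B = 999, however, unconstrained
MLE frequently returns a *negative* shape by chance; a negative shape
puts a finite endpoint just beyond the data and collapses extrapolated
p-values toward zero, which inflates the type-I error of the downstream
Bonferroni test several-fold. The fit is therefore constrained to
shape ≥ 0, taking the exponential MLE on the boundary. With this
constraint the p-value estimator is approximately calibrated (slightly
conservative) down to the 10⁻⁵–10⁻⁶ range needed for α/m with m up to
4000, as the acceptance checks verify empirically.

p-values are assigned to the maximizing window of each grid and compared
with α/m. In simulation summaries m is each grid's own window count; in
application-style scans the default sums m over all grids
(`bonferroni="combined"`), which is the more conservative convention for
a multi-grid search of one region.

## Synthetic data

The generator stands in for a coalescent simulation. Variant positions
are uniform; allele frequencies follow a truncated power-law site
frequency spectrum with density ∝ f^(−α), α = 1 by default (the neutral
1/f shape), on [1/n_hap, 0.5]; alleles are assigned to the 10,000
haplotypes independently. Diploid genotypes are sums of two haplotypes
drawn without replacement; common variants (MAF > 0.05) and singletons
are then removed. The default density of 0.005 variants/bp leaves a
post-filter rare-variant panel in the low thousands per 1 Mb, the scale
of a European coalescent panel; at this density a 500 bp cluster holds
only a handful of rare variants, so absolute power values are modest and
the evaluation focuses on orderings (power vs. effect size, sample size,
and window/cluster match) rather than absolute levels.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent), recombination and demographic structure, genotyping
error, and covariate structure. Passing tests therefore demonstrate the
statistical machinery — size, calibration, localization geometry — not
robustness to LD-induced carrier correlation between windows, which on
real data mainly affects how often neighboring windows tie.

Phenotypes follow y_i = Σ_j β_j g_ij + ε_i with β_j = c·|log10 MAF_j|
(rarer ⇒ larger effect) and ε ~ N(0,1); the MAF entering β is the
post-filter *sample* MAF. Clusters of 200/500 bp are fully causal and
consecutive; 2 kb clusters contain a random 20% causal subset. Effect
constants c ∈ {0.2, 0.4, 0.6}, with c = 0 the null.

## Problem sizes used in checks

Type-I error runs 200 null replicates per sample size with B = 999 and
GPD acceleration, all four grids scanned on shared replicates (the
published per-grid rates likewise derive from one replicate set); power
cells use 100 replicates. The full 1000-replicate configuration is a
`SimScenario` field away. Smaller unit tests use a 100 kb mini-region
pool with 2000 haplotypes.

## Known limitations

* No covariate adjustment — population-structure confounding must be
  handled upstream (e.g. residualizing the phenotype), and residualizing
  changes the permutation null only through the carrier phenotype values.
* Per-window permutation p-values with Bonferroni over m windows, rather
  than a single max-over-windows permutation null; the latter would need
  no multiplicity correction but tests a different global hypothesis.
* Independent-variant synthetic data (no LD), see above.
* VCF input uses hard GT calls only; dosage (DS) fields are not read.
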
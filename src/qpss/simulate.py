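"""Synthetic haplotypes, genotypes, causal clusters and phenotypes.

The generator stands in for a coalescent simulator: variant positions
are uniform over the region and allele frequencies follow a rare-skewed
site frequency spectrum with density proportional to ``f**-alpha``
(``alpha = 1`` is the neutral expectation), truncated to
``[1/n_hap, 0.5]``.  Variants are sampled independently, so the pool
carries no linkage disequilibrium; the scan's permutation inference does
not depend on LD, and power scenarios depend mainly on the frequency
spectrum and cluster geometry.

Phenotypes follow the additive rare-variant model

.. math:: y_i = \\sum_{j \\in C} \\beta_j g_{ij} + \\varepsilon_i,
          \\qquad \\beta_j = c\\,|\\log_{10} MAF_j|,
          \\qquad \\varepsilon_i \\sim N(0, 1),

where *C* is a causal cluster of rare variants, so rarer causal alleles
carry larger effects.  ``c = 0`` gives the null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, compute_maf, rare_mask
from .windows import DEFAULT_SPECS, WindowSpec


@dataclass(frozen=True)
class HaplotypePool:
    """A panel of binary haplotypes over a region."""

    region_length: int
    positions: np.ndarray
    frequencies: np.ndarray
    haplotypes: np.ndarray  # (n_hap, n_variants) uint8

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]


@dataclass(frozen=True)
class SimScenario:
    """One simulation condition of the type-I-error / power study.

    Defaults mirror the study design: diploid samples drawn from a
    10,000-haplotype pool over 1 Mb, rare variants (MAF < 0.05, no
    singletons), clusters of 200/500 bp (all variants causal) or 2 kb
    (a random 20%), effect constant ``c`` in {0, 0.2, 0.4, 0.6}.
    """

    n: int = 500
    cluster_size: int = 500
    causal_fraction: float = 1.0
    c: float = 0.2
    specs: tuple[WindowSpec, ...] = DEFAULT_SPECS
    replicates: int = 1000
    seed: int = 0
    region_length: int = 1_000_000
    n_hap: int = 10_000
    variant_density: float = 5e-3
    sfs_alpha: float = 1.0

    @property
    def is_null(self) -> bool:
        return self.c == 0.0


@dataclass(frozen=True)
class SimReplicate:
    """One simulated dataset: filtered genotypes, cluster, phenotypes."""

    genotypes: GenotypeMatrix
    causal_ids: np.ndarray
    betas: np.ndarray
    y: np.ndarray
    cluster_start: int | None
    cluster_end: int | None


def simulate_haplotypes(
    n_hap: int = 10_000,
    region_length: int = 1_000_000,
    variant_density: float = 5e-3,
    sfs_alpha: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> HaplotypePool:
    """Draw a haplotype pool with a rare-skewed frequency spectrum.

    ``variant_density`` is variants per bp before any frequency filter
    (the default 0.005/bp leaves a post-filter rare-variant count per
    1 Mb in the low thousands).  Frequencies are sampled from the
    truncated power-law spectrum by inverse-CDF; alleles are assigned to
    haplotypes independently at those frequencies.
    """
    if n_hap < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_var = int(round(variant_density * region_length))
    positions = np.sort(rng.choice(region_length, size=n_var, replace=False)) + 1
    freqs = _sample_sfs(n_var, sfs_alpha, 1.0 / n_hap, 0.5, rng)
    haps = np.empty((n_hap, n_var), dtype=np.uint8)
    step = max(1, 10_000_000 // max(n_var, 1))  # bound temp float allocations
    for i in range(0, n_hap, step):
        j = min(i + step, n_hap)
        haps[i:j] = rng.random((j - i, n_var)) < freqs
    return HaplotypePool(region_length, positions.astype(np.int64), freqs, haps)


def _sample_sfs(n: int, alpha: float, fmin: float, fmax: float,
                rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling from density ~ f**-alpha on [fmin, fmax]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return fmin * (fmax / fmin) ** u
    a = 1.0 - alpha
    return (fmin**a + u * (fmax**a - fmin**a)) ** (1.0 / a)


def draw_genotypes(
    pool: HaplotypePool,
    n: int,
    seed: int | np.random.Generator | None = None,
    rare_threshold: float = 0.05,
    drop_singletons: bool = True,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Pair random pool haplotypes into diploid genotypes, then filter.

    Haplotypes are drawn without replacement (``2n <= n_hap``
    required).  Common variants (sample MAF > threshold, strict `<`
    kept) and singletons are removed, mirroring the simulation design.
    """
    if 2 * n > pool.n_hap:
        raise ValueError("need 2n <= n_hap for without-replacement pairing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(pool.n_hap, size=2 * n, replace=False)
    dosages = (pool.haplotypes[idx[:n]] + pool.haplotypes[idx[n:]]).astype(np.int8)
    gm = GenotypeMatrix(
        np.array([f"S{i:05d}" for i in range(n)]),
        pool.positions,
        dosages,
        chrom=chrom,
    )
    maf = compute_maf(gm)
    mask = rare_mask(
        maf, rare_threshold,
        drop_singletons=drop_singletons,
        minor_allele_count=gm.minor_allele_count(),
    )
    return gm.subset_variants(mask)


def place_cluster(
    genotypes: GenotypeMatrix,
    cluster_size: int,
    causal_fraction: float = 1.0,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 100,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Choose a causal cluster interval and the causal variants in it.

    The cluster start is uniform over positions keeping the interval
    inside the region.  With ``causal_fraction = 1`` every rare variant
    in the interval is causal (a consecutive run); otherwise a random
    subset of ``round(fraction * m)`` variants is chosen.  Intervals
    empty of variants are redrawn up to ``max_retries`` times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = genotypes.positions
    region_end = int(pos[-1]) if len(pos) else cluster_size
    lo, hi = 1, max(region_end - cluster_size + 1, 1)
    for _ in range(max_retries):
        start = int(rng.integers(lo, hi + 1))
        end = start + cluster_size - 1
        a, b = np.searchsorted(pos, (start, end + 1))
        if b > a:
            in_cluster = np.arange(a, b)
            if causal_fraction >= 1.0:
                causal = in_cluster
            else:
                k = max(int(round(causal_fraction * len(in_cluster))), 1)
                causal = np.sort(rng.choice(in_cluster, size=k, replace=False))
            return causal, (start, end)
    raise RuntimeError(
        f"no variants found in any candidate {cluster_size} bp cluster "
        f"after {max_retries} draws"
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    causal_ids: np.ndarray,
    c: float,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypes from the additive model with beta_j = c |log10 MAF_j|.

    MAF is the post-filter sample frequency.  Returns ``(y, betas)``
    over all samples; with ``c = 0`` the phenotype is pure N(0, 1)
    noise.
    """
    if c < 0:
        raise ValueError("effect constant c must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    causal_ids = np.asarray(causal_ids, dtype=int)
    eps = rng.standard_normal(genotypes.n_samples)
    if c == 0.0 or len(causal_ids) == 0:
        return eps, np.zeros(len(causal_ids))
    maf = compute_maf(genotypes)[causal_ids]
    if np.any(maf <= 0):
        raise ValueError("causal variants must have positive MAF")
    betas = c * np.abs(np.log10(maf))
    g = np.maximum(genotypes.dosages[:, causal_ids], 0)  # missing -> 0
    y = g @ betas + eps
    return y, betas


def heritability(
    genotypes: GenotypeMatrix,
    causal_ids: np.ndarray,
    betas: np.ndarray,
    y: np.ndarray,
) -> float:
    """Empirical h^2 = Var(genetic value) / Var(y) over samples."""
    y = np.asarray(y, float)
    var_y = y.var()
    if var_y == 0:
        raise ValueError("phenotype variance is zero")
    causal_ids = np.asarray(causal_ids, dtype=int)
    if len(causal_ids) == 0:
        return 0.0
    g = np.maximum(genotypes.dosages[:, causal_ids], 0)
    return float((g @ np.asarray(betas, float)).var() / var_y)


def simulate_replicate(
    scenario: SimScenario,
    pool: HaplotypePool,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> SimReplicate:
    """One full replicate: genotypes, cluster (if c > 0), phenotypes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gm = draw_genotypes(pool, scenario.n, rng)
    if scenario.is_null:
        y, betas = simulate_phenotype(gm, np.array([], dtype=int), 0.0, rng)
        return SimReplicate(gm, np.array([], dtype=int), betas, y, None, None)
    causal, (start, end) = place_cluster(
        gm, scenario.cluster_size, scenario.causal_fraction, rng
    )
    y, betas = simulate_phenotype(gm, causal, scenario.c, rng)
    return SimReplicate(gm, causal, betas, y, start, end)
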
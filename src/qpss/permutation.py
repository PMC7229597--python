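"""Permutation inference with a generalized-Pareto tail approximation.

The null distribution of the window statistic is unknown, so p-values
come from permuting phenotype values among the region carriers while the
genotypes (and hence the W+/W- partition sizes) stay fixed.  When the
observed statistic lands far in the permutation tail, a generalized
Pareto distribution (GPD) fitted to the largest null statistics
extrapolates the tail probability well below 1/B, after Knijnenburg's
scheme for permutation tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .scan import ScanResult, scan
from .genotypes import GenotypeMatrix
from .windows import Region, WindowSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationNull:
    """Observed |statistic| plus B permuted null |statistics|."""

    observed_stat: float
    null_stats: np.ndarray
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.null_stats)


@dataclass(frozen=True)
class GpdTailFit:
    """A maximum-likelihood GPD fit to the permutation-null tail."""

    threshold: float
    n_exc: int
    shape: float
    scale: float
    gof_p: float


def _null_lr_stats(y: np.ndarray, n_plus_values: np.ndarray, B: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Null |ln LR| for each of B carrier permutations and each n+.

    Because the statistic depends on the permuted phenotypes only
    through the sum over the W+ group, one batch of permutations serves
    every window: row prefix sums give the W+ sum for any group size.
    Returns an array of shape ``(len(n_plus_values), B)``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    tot = y.sum()
    s2_0 = float(np.square(y - tot / n).mean())
    perms = rng.permuted(np.broadcast_to(y, (B, n)), axis=1)
    prefix = np.cumsum(perms, axis=1)
    out = np.empty((len(n_plus_values), B))
    for i, k in enumerate(np.asarray(n_plus_values, dtype=int)):
        if not 0 < k < n:
            raise ValueError("degenerate partition in permutation null")
        sum_plus = prefix[:, k - 1]
        diff = sum_plus / k - (tot - sum_plus) / (n - k)
        s2_w = s2_0 - k * (n - k) * diff**2 / (n * n)
        np.clip(s2_w, 1e-300, None, out=s2_w)
        if s2_0 <= 0.0:
            out[i] = 0.0
        else:
            out[i] = 0.5 * n * np.log(s2_0 / s2_w)
    np.clip(out, 0.0, None, out=out)
    return out


def permute_null(
    y: np.ndarray,
    n_plus: int,
    B: int,
    seed: int | np.random.Generator | None = None,
    observed_stat: float | None = None,
) -> PermutationNull:
    """Permutation null of |ln LR| for one window.

    Phenotypes are reshuffled among the ``n_G = len(y)`` region carriers
    with the W+ group size ``n_plus`` held fixed; each permutation's
    absolute statistic enters the null set.  If ``observed_stat`` is not
    given it is computed from the identity assignment (first ``n_plus``
    entries of ``y`` forming W+).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = _null_lr_stats(np.asarray(y, float), np.array([n_plus]), B, rng)[0]
    if observed_stat is None:
        from .scan import signed_lr

        mask = np.zeros(len(y), dtype=bool)
        mask[:n_plus] = True
        observed_stat = signed_lr(y, mask)[0]
    return PermutationNull(
        observed_stat=float(observed_stat),
        null_stats=null,
        seed=seed if isinstance(seed, int) else None,
    )


def empirical_p(null: PermutationNull) -> float:
    """Add-one empirical p-value ``(1 + r) / (B + 1)``.

    ``r`` counts null statistics at least as extreme as the observed
    one; the +1 keeps the estimator valid (never zero).
    """
    r = int(np.count_nonzero(null.null_stats >= null.observed_stat))
    return (1 + r) / (null.B + 1)


def gpd_tail_p(
    null: PermutationNull,
    min_exceedances: int = 10,
    fit_size: int = 250,
    gof_level: float = 0.05,
    shrink_step: int = 10,
    min_fit_size: int = 50,
) -> tuple[float, GpdTailFit | None, str]:
    """P-value with GPD tail acceleration.

    If at least ``min_exceedances`` null statistics reach the observed
    value, the plain empirical p is returned.  Otherwise a GPD is fitted
    by maximum likelihood to the largest ``fit_size`` null statistics in
    excess of a threshold placed halfway between the ``fit_size``-th and
    the next largest value, and

    .. math:: p = \\frac{n_{exc}}{B}\\,(1 - F_{GPD}(t_{obs} - u))

    A Kolmogorov-Smirnov goodness-of-fit check at ``gof_level`` guards
    the fit; on failure the tail is shrunk by ``shrink_step`` and
    refitted, down to ``min_fit_size``, after which the empirical p is
    returned with a warning.

    Returns ``(p, fit or None, method)`` with method in
    ``{"permutation", "gpd"}``.
    """
    n_exceed = int(np.count_nonzero(null.null_stats >= null.observed_stat))
    if n_exceed >= min_exceedances:
        return empirical_p(null), None, "permutation"

    z = np.sort(null.null_stats)[::-1]
    B = null.B
    size = min(fit_size, B - 1)
    while size >= min_fit_size:
        threshold = 0.5 * (z[size - 1] + z[size])
        exc = z[:size] - threshold
        if exc[-1] <= 0 or not np.all(np.isfinite(exc)):
            break
        try:
            shape, loc, scale = sps.genpareto.fit(exc, floc=0.0)
        except Exception:  # pragma: no cover - scipy fit failure
            break
        if shape < 0.0:
            # the statistic is a likelihood ratio with an exponential-type
            # upper tail; a negative shape puts a finite endpoint just past
            # the data and collapses extrapolated p-values toward zero, so
            # the MLE is constrained to shape >= 0 (boundary: exponential)
            shape, loc, scale = 0.0, 0.0, float(np.mean(exc))
        gof = sps.kstest(exc, sps.genpareto.cdf, args=(shape, loc, scale)).pvalue
        if gof >= gof_level:
            tail = sps.genpareto.sf(null.observed_stat - threshold, shape, loc, scale)
            p = min(max((size / B) * float(tail), 0.0), 1.0)
            fit = GpdTailFit(float(threshold), size, float(shape), float(scale), float(gof))
            return p, fit, "gpd"
        size -= shrink_step
    logger.warning("GPD tail fit failed; falling back to empirical p-value")
    return empirical_p(null), None, "permutation"


def scan_with_pvalues(
    y,
    genotypes: GenotypeMatrix,
    region: Region,
    specs: list[WindowSpec],
    B: int = 999,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    rare_threshold: float = 0.05,
    drop_singletons: bool = False,
    bonferroni: str = "combined",
    gpd_min_exceedances: int = 10,
    gpd_fit_size: int = 250,
) -> ScanResult:
    """Scan, then assign a permutation/GPD p-value to each spec's best window.

    The p-value is window-wise: the maximizing window of each (size,
    slide) spec gets B carrier-permutation statistics and, if needed,
    GPD tail acceleration.  Significance is judged against the
    Bonferroni level ``alpha / m`` (``m`` per spec or combined across
    specs per the ``bonferroni`` mode).  Extra columns: ``p_method``,
    ``B``, ``gpd_shape``, ``gpd_scale``, ``gof_p``, ``significant``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    result = scan(y, genotypes, region, specs, rare_threshold, drop_singletons)
    table = result.table
    for col, default in (
        ("p_method", ""), ("B", 0), ("gpd_shape", np.nan),
        ("gpd_scale", np.nan), ("gof_p", np.nan), ("significant", False),
    ):
        table[col] = default

    # carrier phenotypes, reconstructed exactly as scan saw them
    yc = _carrier_phenotypes(y, genotypes, region, rare_threshold, drop_singletons)

    alpha_star = result.bonferroni_alpha(alpha, bonferroni)
    best_rows = [(label, idx) for label, idx in result.best.items()]
    n_plus_vals = np.array([table.at[idx, "n_wplus"] for _, idx in best_rows])
    ok = (n_plus_vals > 0) & (n_plus_vals < result.n_carriers)
    if ok.any():
        nulls = _null_lr_stats(yc, n_plus_vals[ok], B, rng)
        row = 0
        for (label, idx), good in zip(best_rows, ok):
            if not good:
                continue
            obs = abs(table.at[idx, "signed_stat"])
            pn = PermutationNull(float(obs), nulls[row])
            row += 1
            p, fit, method = gpd_tail_p(
                pn, min_exceedances=gpd_min_exceedances, fit_size=gpd_fit_size
            )
            table.at[idx, "p_value"] = p
            table.at[idx, "p_method"] = method
            table.at[idx, "B"] = B
            if fit is not None:
                table.at[idx, "gpd_shape"] = fit.shape
                table.at[idx, "gpd_scale"] = fit.scale
                table.at[idx, "gof_p"] = fit.gof_p
            table.at[idx, "significant"] = bool(p <= alpha_star[label])
    return result


def _carrier_phenotypes(y, genotypes, region, rare_threshold, drop_singletons):
    """Phenotype vector of the region carriers, in scan order."""
    from .genotypes import compute_maf, rare_mask
    from .scan import _align_phenotype, carrier_mask

    y_arr, keep, _ = _align_phenotype(y, genotypes)
    dos = genotypes.dosages if keep is None else genotypes.dosages[keep]
    gm = genotypes if keep is None else GenotypeMatrix(
        genotypes.sample_ids[keep], genotypes.positions, dos, genotypes.chrom
    )
    in_region = (gm.positions >= region.start) & (gm.positions <= region.end)
    maf = compute_maf(gm)
    mac = gm.minor_allele_count()
    rare = rare_mask(
        np.where(in_region, maf, np.nan), rare_threshold,
        drop_singletons=drop_singletons, minor_allele_count=mac,
    )
    carriers = carrier_mask(gm.dosages[:, rare])
    return y_arr[carriers]
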
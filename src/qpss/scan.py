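"""The window scan statistic.

For a region *G*, let :math:`n_G` be the number of samples carrying at
least one rare allele in *G*.  A window *W* splits these carriers into
:math:`n_{W+}` (at least one rare allele inside *W*) and
:math:`n_{W-}` (rare alleles only outside *W*).  With group-mean
estimates :math:`\\hat\\mu_{W+}, \\hat\\mu_{W-}` and maximum-likelihood
variances (divisor :math:`n_G`)

.. math::

   \\hat\\sigma_W^2 = \\frac{1}{n_G}\\Big(\\sum_{W+} (y_i-\\hat\\mu_{W+})^2
                     + \\sum_{W-} (y_i-\\hat\\mu_{W-})^2\\Big),
   \\qquad
   \\hat\\sigma_0^2 = \\frac{1}{n_G}\\sum_G (y_i-\\hat\\mu_0)^2,

the signed log likelihood ratio comparing the two-mean model to the
one-mean model is

.. math::

   \\ln\\widehat{LR}_W = \\frac{n_G}{2}
       \\ln\\frac{\\hat\\sigma_0^2}{\\hat\\sigma_W^2},
   \\qquad
   T_W = \\operatorname{sgn}(\\hat\\mu_{W+}-\\hat\\mu_{W-})
         \\cdot \\ln\\widehat{LR}_W .

The scan evaluates :math:`T_W` for every window of every (size, slide)
spec and reports :math:`\\arg\\max_W |T_W|`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    GenotypeMatrix,
    NoCarriersError,
    compute_maf,
    rare_mask,
)
from .windows import Region, Window, WindowSpec, generate_windows

logger = logging.getLogger(__name__)

#: Sentinel reported when the within-window fit is perfect
#: (sigma2_w == 0 while sigma2_0 > 0); flagged, never fed to the argmax
#: silently.
PERFECT_FIT_SENTINEL = np.inf


@dataclass(frozen=True)
class CarrierPartition:
    """Region carriers split by window-carrier status.

    ``w_plus_ids`` carry >= 1 rare allele inside the window;
    ``w_minus_ids`` are the remaining region carriers.
    """

    w_plus_ids: np.ndarray
    w_minus_ids: np.ndarray

    @property
    def n_plus(self) -> int:
        return len(self.w_plus_ids)

    @property
    def n_minus(self) -> int:
        return len(self.w_minus_ids)

    @property
    def n_carriers(self) -> int:
        return self.n_plus + self.n_minus

    @property
    def degenerate(self) -> bool:
        return self.n_plus == 0 or self.n_minus == 0


@dataclass(frozen=True)
class WindowStatistic:
    window: Window
    m_w: int
    n_plus: int
    n_minus: int
    mu_plus: float
    mu_minus: float
    mu_0: float
    sigma2_w: float
    sigma2_0: float
    ln_lr: float
    sign: int
    signed_stat: float
    degenerate: bool = False
    flag: str = ""
    p_value: float | None = None


def carrier_mask(dosages: np.ndarray) -> np.ndarray:
    """Per-sample indicator of carrying >= 1 minor allele (missing = 0)."""
    return (dosages > 0).any(axis=1)


def carrier_partition(
    genotypes: GenotypeMatrix,
    region_mask: np.ndarray,
    window_mask: np.ndarray,
) -> CarrierPartition:
    """Split region carriers by presence of a rare allele in the window.

    Missing dosages count as non-carrier calls, so a sample whose only
    window calls are missing but who carries elsewhere in the region is
    assigned to the W- group.
    """
    region_mask = np.asarray(region_mask, bool)
    window_mask = np.asarray(window_mask, bool)
    if np.any(window_mask & ~region_mask):
        raise ValueError("window variants must be a subset of region variants")
    in_region = carrier_mask(genotypes.dosages[:, region_mask])
    if not in_region.any():
        raise NoCarriersError("no carriers of rare variants in the region")
    in_window = carrier_mask(genotypes.dosages[:, window_mask])
    plus = in_region & in_window
    minus = in_region & ~in_window
    return CarrierPartition(np.where(plus)[0], np.where(minus)[0])


def signed_lr(y: np.ndarray, plus_mask: np.ndarray) -> tuple[float, int, float]:
    """Signed statistic for carrier phenotypes ``y`` and a W+ mask.

    Returns ``(ln_lr, sign, signed_stat)``.
    """
    y = np.asarray(y, dtype=float)
    plus_mask = np.asarray(plus_mask, bool)
    n = len(y)
    n_plus = int(plus_mask.sum())
    n_minus = n - n_plus
    if n_plus == 0 or n_minus == 0:
        raise ValueError("degenerate partition: both groups must be non-empty")
    yp = y[plus_mask]
    ym = y[~plus_mask]
    mu_plus = yp.mean()
    mu_minus = ym.mean()
    mu0 = y.mean()
    s2_0 = np.square(y - mu0).mean()
    s2_w = (np.square(yp - mu_plus).sum() + np.square(ym - mu_minus).sum()) / n
    ln_lr, sign, stat, _ = _finalize_stat(n, mu_plus, mu_minus, s2_w, s2_0)
    return ln_lr, sign, stat


def _finalize_stat(
    n_g: int, mu_plus: float, mu_minus: float, s2_w: float, s2_0: float
) -> tuple[float, int, float, str]:
    """Apply the degenerate-variance conventions and the sign."""
    sign = int(np.sign(mu_plus - mu_minus))
    flag = ""
    if s2_0 <= 0.0:
        # all carrier phenotypes identical: nothing to test
        ln_lr = 0.0
        sign = 0
    elif s2_w <= 0.0:
        ln_lr = PERFECT_FIT_SENTINEL
        flag = "zero_within_variance"
    else:
        ln_lr = 0.5 * n_g * np.log(s2_0 / s2_w)
        if ln_lr < 0.0:  # numerical round-off only
            ln_lr = 0.0
    return ln_lr, sign, sign * ln_lr, flag


def window_statistic(
    y: np.ndarray, partition: CarrierPartition, window: Window | None = None, m_w: int = 0
) -> WindowStatistic:
    """Evaluate the signed log likelihood ratio for one window.

    ``y`` holds the phenotypes of all region carriers, indexed so that
    ``partition.w_plus_ids`` / ``w_minus_ids`` address into it.
    """
    if partition.degenerate:
        raise ValueError("degenerate partition: both groups must be non-empty")
    y = np.asarray(y, dtype=float)
    yp = y[partition.w_plus_ids]
    ym = y[partition.w_minus_ids]
    n_g = partition.n_carriers
    mu_plus = yp.mean()
    mu_minus = ym.mean()
    mu0 = (yp.sum() + ym.sum()) / n_g
    s2_0 = (np.square(yp - mu0).sum() + np.square(ym - mu0).sum()) / n_g
    s2_w = (np.square(yp - mu_plus).sum() + np.square(ym - mu_minus).sum()) / n_g
    ln_lr, sign, stat, flag = _finalize_stat(n_g, mu_plus, mu_minus, s2_w, s2_0)
    return WindowStatistic(
        window=window or Window(0, 0),
        m_w=m_w,
        n_plus=partition.n_plus,
        n_minus=partition.n_minus,
        mu_plus=float(mu_plus),
        mu_minus=float(mu_minus),
        mu_0=float(mu0),
        sigma2_w=float(s2_w),
        sigma2_0=float(s2_0),
        ln_lr=float(ln_lr),
        sign=sign,
        signed_stat=float(stat),
        flag=flag,
    )


@dataclass
class ScanResult:
    """All per-window statistics of a scan plus the per-spec maxima.

    ``table`` has one row per generated window (degenerate ones
    included, flagged); ``best`` maps each spec label to the row index
    of the window maximizing ``|signed_stat|`` (ties broken by genomic
    order).  ``m_total`` counts every generated window across specs and
    drives the Bonferroni level ``alpha / m``.
    """

    region: Region
    table: pd.DataFrame
    best: dict[str, int]
    m_per_spec: dict[str, int]
    n_carriers: int
    n_dropped_samples: int = 0

    @property
    def m_total(self) -> int:
        return sum(self.m_per_spec.values())

    def bonferroni_alpha(self, alpha: float, mode: str = "combined") -> dict[str, float]:
        """Per-spec significance levels ``alpha / m``."""
        if mode == "combined":
            return {s: alpha / self.m_total for s in self.m_per_spec}
        if mode == "per-spec":
            return {s: alpha / m for s, m in self.m_per_spec.items()}
        raise ValueError("bonferroni mode must be 'combined' or 'per-spec'")

    def best_rows(self) -> pd.DataFrame:
        return self.table.loc[list(self.best.values())]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


_TABLE_COLUMNS = [
    "chrom", "window_start", "window_end", "spec", "m_w", "n_g",
    "n_wplus", "n_wminus", "mu_plus", "mu_minus", "ln_lr", "sign",
    "signed_stat", "p_value", "flags",
]


def scan(
    y: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix,
    region: Region,
    specs: list[WindowSpec],
    rare_threshold: float = 0.05,
    drop_singletons: bool = False,
) -> ScanResult:
    """Scan a region with one or more window grids.

    ``y`` holds one phenotype value per genotyped sample, in sample
    order (a :class:`pandas.Series` indexed by sample id is aligned by
    id).  Samples with missing phenotypes are dropped with a logged
    count.  Returns per-window statistics for every spec and the
    maximizing window of each.
    """
    y_arr, keep, n_dropped = _align_phenotype(y, genotypes)
    gm = genotypes if keep is None else GenotypeMatrix(
        genotypes.sample_ids[keep], genotypes.positions, genotypes.dosages[keep],
        genotypes.chrom,
    )

    in_region = (gm.positions >= region.start) & (gm.positions <= region.end)
    maf = compute_maf(gm)
    mac = gm.minor_allele_count()
    rare = rare_mask(
        np.where(in_region, maf, np.nan),
        rare_threshold,
        drop_singletons=drop_singletons,
        minor_allele_count=mac,
    )
    pos = gm.positions[rare]
    dos = gm.dosages[:, rare]

    carriers = carrier_mask(dos)
    n_g = int(carriers.sum())
    if n_g == 0:
        raise NoCarriersError("no carriers of rare variants in the region")
    yc = y_arr[carriers]
    # prefix counts of carried variants let every window's W+ mask be a
    # difference of two cumulative columns
    carried = (dos[carriers] > 0).astype(np.int32)
    prefix = np.zeros((n_g, len(pos) + 1), dtype=np.int32)
    np.cumsum(carried, axis=1, out=prefix[:, 1:])

    tot = yc.sum()
    mu0 = tot / n_g
    s2_0 = float(np.square(yc - mu0).mean())

    rows: list[dict] = []
    best: dict[str, int] = {}
    m_per_spec: dict[str, int] = {}
    row_offset = 0
    for spec in specs:
        windows = generate_windows(region, spec)
        m_per_spec[spec.label] = len(windows)
        starts = np.array([w.start for w in windows])
        ends = np.array([w.end for w in windows])
        a = np.searchsorted(pos, starts, side="left")
        b = np.searchsorted(pos, ends, side="right")
        plus = prefix[:, b] - prefix[:, a] > 0  # carriers x windows
        n_plus = plus.sum(axis=0)
        sum_plus = yc @ plus
        stats = _vector_stats(n_g, n_plus, sum_plus, tot, s2_0, yc, plus)
        best_idx = None
        best_val = -1.0
        for j, w in enumerate(windows):
            m_w = int(b[j] - a[j])
            degenerate = m_w == 0 or n_plus[j] == 0 or n_plus[j] == n_g
            ln_lr, sign, stat, flag = stats[j]
            if degenerate:
                flag = "degenerate"
                ln_lr = sign = stat = np.nan
            rows.append({
                "chrom": region.chrom,
                "window_start": w.start,
                "window_end": w.end,
                "spec": spec.label,
                "m_w": m_w,
                "n_g": n_g,
                "n_wplus": int(n_plus[j]),
                "n_wminus": int(n_g - n_plus[j]),
                "mu_plus": sum_plus[j] / n_plus[j] if n_plus[j] else np.nan,
                "mu_minus": (tot - sum_plus[j]) / (n_g - n_plus[j])
                if n_plus[j] < n_g else np.nan,
                "ln_lr": ln_lr,
                "sign": sign,
                "signed_stat": stat,
                "p_value": np.nan,
                "flags": flag,
            })
            if not degenerate and np.isfinite(ln_lr) and ln_lr > best_val:
                best_val = ln_lr
                best_idx = row_offset + j
        if best_idx is None:
            # every window degenerate or flagged; fall back to first
            logger.warning("no evaluable window for spec %s", spec.label)
            best_idx = row_offset
        best[spec.label] = best_idx
        row_offset += len(windows)

    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return ScanResult(
        region=region,
        table=table,
        best=best,
        m_per_spec=m_per_spec,
        n_carriers=n_g,
        n_dropped_samples=n_dropped,
    )


def _vector_stats(n_g, n_plus, sum_plus, tot, s2_0, yc, plus):
    """Per-window (ln_lr, sign, signed_stat, flag) from group sums.

    Uses the between/within decomposition: the pooled ML variance is
    sigma2_0 minus the between-group term n+ n- (mu+ - mu-)^2 / n_G^2.
    """
    n_plus = n_plus.astype(float)
    n_minus = n_g - n_plus
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_p = sum_plus / n_plus
        mu_m = (tot - sum_plus) / n_minus
        diff = mu_p - mu_m
        s2_w = s2_0 - n_plus * n_minus * diff**2 / (n_g * n_g)
    out = []
    for j in range(len(n_plus)):
        if n_plus[j] == 0 or n_minus[j] == 0:
            out.append((np.nan, 0, np.nan, "degenerate"))
            continue
        # the subtraction can leave round-off where the true pooled
        # variance is zero; snap such values to exact zero
        s2wj = s2_w[j] if s2_w[j] > 1e-12 * max(s2_0, 1e-300) else 0.0
        ln_lr, sign, stat, flag = _finalize_stat(n_g, mu_p[j], mu_m[j], s2wj, s2_0)
        out.append((ln_lr, sign, stat, flag))
    return out


def _align_phenotype(y, genotypes: GenotypeMatrix):
    """Align a phenotype vector/Series to genotype sample order.

    Returns (values, keep_mask_or_None, n_dropped).
    """
    if isinstance(y, pd.Series):
        ids = pd.Index(genotypes.sample_ids)
        matched = y.reindex(ids)
        keep = matched.notna().to_numpy()
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d genotyped samples without phenotype", n_dropped)
        if n_dropped == 0:
            return matched.to_numpy(float), None, 0
        return matched.to_numpy(float)[keep], keep, n_dropped
    y_arr = np.asarray(y, dtype=float)
    if len(y_arr) != genotypes.n_samples:
        raise ValueError("phenotype length does not match sample count")
    if np.isnan(y_arr).any():
        keep = ~np.isnan(y_arr)
        logger.info("dropping %d samples with missing phenotype", int((~keep).sum()))
        return y_arr[keep], keep, int((~keep).sum())
    return y_arr, None, 0
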
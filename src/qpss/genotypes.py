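"""Genotype container and minor-allele bookkeeping.

Genotypes are held as additive minor-allele dosages (0, 1, 2) with a
``-1`` sentinel for missing calls.  Minor-allele orientation is decided
per variant from the observed sample frequency, not from REF/ALT labels,
because the scan statistic is defined on minor alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MISSING: int = -1
"""Sentinel dosage for a missing genotype call."""


class NoRareVariantsError(ValueError):
    """Raised when a region contains no rare variants after filtering."""


class NoCarriersError(ValueError):
    """Raised when no sample carries a rare allele in the region."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x variants additive minor-allele dosage matrix.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers, one per row of ``dosages``.
    positions
        1-based physical positions, strictly increasing.
    dosages
        ``(n_samples, n_variants)`` integer array with values in
        ``{0, 1, 2}`` or :data:`MISSING`.
    chrom
        Chromosome label shared by all variants.
    """

    sample_ids: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        sample_ids = np.asarray(self.sample_ids)
        positions = np.asarray(self.positions, dtype=np.int64)
        dosages = np.asarray(self.dosages)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "dosages", dosages)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if dosages.shape != (len(sample_ids), len(positions)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(sample_ids)} samples x {len(positions)} variants"
            )
        if len(positions) and np.any(np.diff(positions) <= 0):
            raise ValueError("variant positions must be strictly increasing")
        bad = ~np.isin(dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or the missing sentinel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        return compute_maf(self)

    def minor_allele_count(self) -> np.ndarray:
        """Per-variant minor-allele count over non-missing calls."""
        d = self.dosages
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        n_called = called.sum(axis=0)
        # fold: the dosage orientation may still be the major allele
        return np.minimum(alt, 2 * n_called - alt)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.sample_ids, self.positions[mask], self.dosages[:, mask], self.chrom
        )


def compute_maf(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor allele frequency from non-missing calls.

    The frequency is folded so every value lies in ``[0, 0.5]``.  A
    variant with all calls missing gets ``nan`` (it is excluded from any
    downstream scan by :func:`rare_mask`).
    """
    d = genotypes.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
    return np.where(np.isnan(af), np.nan, np.minimum(af, 1.0 - af))


def fold_to_minor(dosages: np.ndarray) -> np.ndarray:
    """Reorient dosage columns so they count the minor allele.

    Columns whose coded-allele frequency exceeds 0.5 are flipped
    (``2 - dosage``); missing entries are preserved.
    """
    d = np.asarray(dosages)
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    flip = alt > n_called  # af > 0.5
    out = d.copy()
    cols = np.where(flip)[0]
    for j in cols:
        col = out[:, j]
        keep = col != MISSING
        col[keep] = 2 - col[keep]
    return out


def rare_mask(
    maf: np.ndarray,
    threshold: float = 0.05,
    *,
    drop_singletons: bool = False,
    minor_allele_count: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask selecting rare variants: ``0 < maf < threshold``.

    The boundary is strict: a variant with MAF exactly equal to the
    threshold is excluded.  With ``drop_singletons``, variants whose
    minor-allele count is exactly 1 are also removed (requires
    ``minor_allele_count``).

    Raises
    ------
    NoRareVariantsError
        If no variant survives the filter.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("rare-variant threshold must be in (0, 0.5]")
    maf = np.asarray(maf, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = (maf > 0.0) & (maf < threshold)
    mask &= ~np.isnan(maf)
    if drop_singletons:
        if minor_allele_count is None:
            raise ValueError("drop_singletons requires minor_allele_count")
        mask &= np.asarray(minor_allele_count) != 1
    if not mask.any():
        raise NoRareVariantsError("no rare variants in region after filtering")
    return mask
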
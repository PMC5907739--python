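"""Train/test splitters: traditional random allocation and PICV.

Proportional instance cross validation (PICV) splits within each
stratum of an independent variable (here the 9 two-SNP genotype
combinations) so the stratum proportions of the full data are preserved
in both partitions.  Both splitters place exactly
``floor(train_fraction * n)`` rows in the training partition so the two
methods are compared at identical train/test sizes; PICV distributes
that total over strata by largest-remainder apportionment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasim import GenotypeDataset

__all__ = ["SplitIndices", "traditional_split", "genotype_stratum_labels", "picv_split"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint, exhaustive train/test row indices."""

    train: np.ndarray
    test: np.ndarray

    @property
    def n(self) -> int:
        return len(self.train) + len(self.test)


def _global_train_size(n: int, train_fraction: float) -> int:
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    t = int(np.floor(train_fraction * n))
    if t == 0 or t == n:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty partition for n={n}"
        )
    return t


def traditional_split(
    n: int, train_fraction: float, rng: np.random.Generator
) -> SplitIndices:
    """Uniformly random split: floor(train_fraction * n) rows train, rest test."""
    if n < 2:
        raise ValueError(f"need at least 2 rows to split, got {n}")
    t = _global_train_size(n, train_fraction)
    perm = rng.permutation(n)
    return SplitIndices(train=np.sort(perm[:t]), test=np.sort(perm[t:]))


def genotype_stratum_labels(dataset: GenotypeDataset) -> np.ndarray:
    """Stratum id 3*snp1 + snp2 in {0..8} for each row (the 9 two-SNP genotypes)."""
    return 3 * dataset.snp1 + dataset.snp2


def _apportion_train_counts(sizes: np.ndarray, train_fraction: float, total: int):
    """Largest-remainder apportionment of the global train total over strata.

    Each stratum k of size m_k gets floor(f * m_k) or ceil(f * m_k)
    train members; the strata with the largest fractional parts are
    rounded up until the global total is met.  Ties are broken toward
    larger strata, then lower stratum index, so the apportionment is
    deterministic.
    """
    quota = train_fraction * sizes
    base = np.floor(quota).astype(int)
    extra = total - int(base.sum())
    if extra < 0 or extra > len(sizes):
        raise RuntimeError("apportionment bookkeeping failed")  # unreachable
    remainder = quota - base
    order = np.lexsort((np.arange(len(sizes)), -sizes, -remainder))
    counts = base.copy()
    counts[order[:extra]] += 1
    return counts


def picv_split(
    labels: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
    generic: bool = False,
) -> SplitIndices:
    """Stratified split preserving the label distribution in both partitions.

    ``labels`` are the per-row stratum ids (two-SNP genotype ids in
    {0..8} unless ``generic=True`` allows arbitrary integers).  Within
    each stratum the selection is uniform; strata of size 1-2 may end up
    with an empty train or test side, which the apportionment logs at
    debug level.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2:
        raise ValueError(f"need at least 2 rows to split, got {n}")
    if not generic and labels.size and not np.isin(labels, np.arange(9)).all():
        raise ValueError(
            "stratum labels outside {0..8}; pass generic=True for arbitrary "
            "integer strata"
        )
    total = _global_train_size(n, train_fraction)
    uniq, inverse = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inverse, minlength=len(uniq))
    counts = _apportion_train_counts(sizes, train_fraction, total)
    if np.any((counts == 0) | (counts == sizes)):
        logger.debug(
            "picv_split: %d strata have an empty train or test side",
            int(np.sum((counts == 0) | (counts == sizes))),
        )
    train_parts = []
    test_parts = []
    for k in range(len(uniq)):
        rows = np.flatnonzero(inverse == k)
        perm = rng.permutation(len(rows))
        train_parts.append(rows[perm[: counts[k]]])
        test_parts.append(rows[perm[counts[k] :]])
    return SplitIndices(
        train=np.sort(np.concatenate(train_parts)),
        test=np.sort(np.concatenate(test_parts)),
    )
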
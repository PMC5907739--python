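"""Classification performance measures and train/test consistency statistics.

The four confusion-matrix measures (sensitivity, specificity, PPV, NPV)
are computed with explicit undefined states (NaN) when their denominator
is zero, e.g. PPV with no predicted positives.  Consistency between a
training and a testing partition is the absolute gap |train - test| per
measure; distributions of such gaps from two cross-validation methods
are compared with a one-sided two-sample Kolmogorov-Smirnov test whose
alternative is that the second sample (PICV) is stochastically smaller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MEASURES",
    "PerformanceQuad",
    "GapSample",
    "confusion_measures",
    "train_test_gap",
    "ks_one_sided",
    "median_max_summary",
]

MEASURES = ("sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class PerformanceQuad:
    """Sensitivity/specificity/PPV/NPV; NaN marks an undefined measure."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sensitivity, self.specificity, self.ppv, self.npv])


@dataclass
class GapSample:
    """Per-replicate |train - test| values for one measure/method/model cell.

    ``values`` holds the retained (defined) gaps; ``n_dropped`` counts
    replicates excluded because the gap was undefined on either side.
    """

    values: np.ndarray
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.values)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_measures(truth: np.ndarray, pred: np.ndarray) -> PerformanceQuad:
    """The four 2x2-table measures of ``pred`` against ``truth``.

    Zero-denominator measures (e.g. PPV with no predicted positives)
    are returned as NaN rather than raising.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1 or truth.size == 0:
        raise ValueError("truth and pred must be equal-length non-empty vectors")
    for name, v in (("truth", truth), ("pred", pred)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    tp = int(np.sum((truth == 1) & (pred == 1)))
    tn = int(np.sum((truth == 0) & (pred == 0)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    return PerformanceQuad(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def train_test_gap(
    quad_train: PerformanceQuad, quad_test: PerformanceQuad
) -> np.ndarray:
    """Per-measure |train - test|; NaN if either side is undefined."""
    return np.abs(quad_train.as_array() - quad_test.as_array())


def ks_one_sided(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    method: str = "asymptotic",
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """One-sided two-sample KS test that ``sample_b`` is stochastically smaller.

    The statistic is D = sup_x (ECDF_b(x) - ECDF_a(x)) clipped at zero,
    evaluated over the pooled sample points: if b is stochastically
    smaller its ECDF dominates.  With ``method="asymptotic"`` the
    p-value is the standard one-sided bound exp(-2 D^2 n_a n_b /
    (n_a + n_b)) capped at 1; ``method="permutation"`` estimates it by
    label permutation, preferable at small sample sizes.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("samples must not contain NaN; drop undefined gaps first")
    d = _ks_stat(a, b)
    if method == "asymptotic":
        ne = a.size * b.size / (a.size + b.size)
        p = min(1.0, float(np.exp(-2.0 * d * d * ne)))
    elif method == "permutation":
        rng = np.random.default_rng(0) if rng is None else rng
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _ks_stat(perm[: a.size], perm[a.size :]) >= d:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return d, p


def _ks_stat(a: np.ndarray, b: np.ndarray) -> float:
    grid = np.concatenate([a, b])
    ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return max(0.0, float(np.max(ecdf_b - ecdf_a)))


def median_max_summary(gaps_trad: GapSample, gaps_picv: GapSample) -> dict:
    """Medians and maxima of two gap samples plus strict smaller-than indicators.

    Ties count as "not smaller".  An all-undefined sample marks the
    summary unavailable.
    """
    if gaps_trad.n == 0 or gaps_picv.n == 0:
        return {"available": False}
    med_t = float(np.median(gaps_trad.values))
    med_p = float(np.median(gaps_picv.values))
    max_t = float(np.max(gaps_trad.values))
    max_p = float(np.max(gaps_picv.values))
    return {
        "available": True,
        "median_traditional": med_t,
        "median_picv": med_p,
        "max_traditional": max_t,
        "max_picv": max_p,
        "picv_median_smaller": med_p < med_t,
        "picv_max_smaller": max_p < max_t,
        "n_dropped_traditional": gaps_trad.n_dropped,
        "n_dropped_picv": gaps_picv.n_dropped,
    }
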
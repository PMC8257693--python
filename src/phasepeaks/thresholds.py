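"""Poisson count thresholds: one global, three adaptive local.

The global threshold comes from the sample's genome-wide mean count per
window; the three local thresholds come from control coverage in spans
of 5x, 10x and 250x the window size around each position, scaled by the
NCIS factor r. A window must clear the most conservative (largest) of
the four. The threshold for rate lam at tail probability p is the
smallest integer k with P(X >= k | Poisson(lam)) <= p, so a window
passes iff its count is at least k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .coverage import WindowCounts, local_means_vec
from .ncis import NormalizationFactor

P_CUT = 1e-5
LOCAL_SPANS = (500, 1000, 25000)  # 5x, 10x, 250x the 100 bp window


def poisson_threshold(lam: float, p_cut: float = P_CUT) -> int:
    """Smallest integer k with P(X >= k) <= p_cut for X ~ Poisson(lam)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must be in (0, 1)")
    if lam == 0:
        return 1
    # isf gives the smallest k with sf(k) <= p, i.e. P(X >= k+1) <= p
    k = int(poisson.isf(p_cut, lam)) + 1
    # guard against edge rounding in isf
    while k > 1 and poisson.sf(k - 2, lam) <= p_cut:
        k -= 1
    while poisson.sf(k - 1, lam) > p_cut:
        k += 1
    return k


def poisson_threshold_vec(lam: np.ndarray, p_cut: float = P_CUT) -> np.ndarray:
    """Vectorized :func:`poisson_threshold` over an array of rates."""
    lam = np.asarray(lam, dtype=np.float64)
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must be in (0, 1)")
    if (lam < 0).any():
        raise ValueError("lam must be >= 0")
    k = np.where(lam > 0, poisson.isf(p_cut, np.maximum(lam, 1e-300)) + 1, 1).astype(np.int64)
    # the same rounding guards as the scalar version, vectorized
    for _ in range(4):
        dec = (k > 1) & (poisson.sf(k - 2, lam) <= p_cut)
        k[dec] -= 1
        inc = poisson.sf(k - 1, lam) > p_cut
        k[inc] += 1
        if not (dec.any() or inc.any()):
            break
    return k


@dataclass
class ThresholdSet:
    """Bundle of the global threshold and the machinery for local ones."""

    p_cut: float = P_CUT
    lambda_global: float = 0.0
    local_spans: tuple[int, ...] = LOCAL_SPANS
    r: NormalizationFactor | None = None
    threshold_global: int = field(init=False)

    def __post_init__(self) -> None:
        self.threshold_global = poisson_threshold(self.lambda_global, self.p_cut)


def conservative_threshold(
    window: int,
    chrom: str,
    control_counts: WindowCounts,
    r: float,
    threshold_set: ThresholdSet,
) -> int:
    """Most conservative of the global and the three scaled local thresholds.

    Local control lambdas are multiplied by r before thresholding; the
    global threshold uses the unscaled sample mean.
    """
    best = threshold_set.threshold_global
    for span in threshold_set.local_spans:
        lam = local_means_vec(control_counts, chrom, np.array([window]), span)[0] * r
        best = max(best, poisson_threshold(lam, threshold_set.p_cut))
    return best


def conservative_lambdas_vec(
    window_idx: np.ndarray,
    chrom: str,
    control_counts: WindowCounts,
    r: float,
    threshold_set: ThresholdSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (most conservative threshold, largest lambda) for many windows.

    The largest lambda (global vs scaled locals) is also the rate at
    which candidate p-values are computed, making the p-value consistent
    with the threshold that gated the window.
    """
    if len(window_idx) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    lam_max = np.full(len(window_idx), threshold_set.lambda_global)
    thr = np.full(len(window_idx), threshold_set.threshold_global, dtype=np.int64)
    for span in threshold_set.local_spans:
        lam = local_means_vec(control_counts, chrom, window_idx, span) * r
        thr = np.maximum(thr, poisson_threshold_vec(lam, threshold_set.p_cut))
        lam_max = np.maximum(lam_max, lam)
    return thr, lam_max
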
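"""NCIS background normalization.

ChIP and input libraries differ in depth, and the ChIP library
additionally carries signal, so the ratio of total counts overestimates
the background ratio. The NCIS estimate restricts the ratio to
low-coverage genomic bins: windows are stratified by combined
sample+control count t, the cumulative ratio

    r(t) = sum_{i: s_i + c_i <= t} s_i / sum_{i: s_i + c_i <= t} c_i

is computed over increasing t, and r is taken at the smallest t* where
the curve first turns upward (r(t*+1) > r(t*)) provided the bins at or
below t* cover at least 75% of the genome. The upward turn marks the
onset of signal-contaminated strata; the coverage floor keeps the
estimate from latching onto noise in the sparse low-t strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coverage import WindowCounts

log = logging.getLogger(__name__)

MIN_GENOME_FRACTION = 0.75


class EstimationError(RuntimeError):
    """Raised when the data cannot support an NCIS estimate."""


@dataclass(frozen=True)
class NormalizationFactor:
    """The NCIS ratio r (sample background / control background) with diagnostics.

    curve_t / curve_r hold the full cumulative ratio curve for plotting;
    converged is False when no qualifying upturn was found and r fell
    back to the all-windows ratio.
    """

    r: float
    total_cutoff: int
    bins_used: int
    bins_fraction: float
    curve_t: np.ndarray
    curve_r: np.ndarray
    converged: bool

    def diagnostics_table(self) -> list[tuple[int, float]]:
        return list(zip(self.curve_t.tolist(), self.curve_r.tolist()))


def estimate_ncis(
    sample_counts: WindowCounts,
    control_counts: WindowCounts,
    min_fraction: float = MIN_GENOME_FRACTION,
) -> NormalizationFactor:
    """Estimate the normalization coefficient r from matched window counts.

    Both WindowCounts must share the layout and phase (phase 0 in the
    pipeline; r is a global depth property so one phase suffices).
    Strata with equal combined count enter as a whole, which makes the
    curve — and therefore r — bit-reproducible for a fixed input.
    """
    if sample_counts.layout is not control_counts.layout and (
        sample_counts.layout.chrom_names != control_counts.layout.chrom_names
        or sample_counts.layout.chrom_lengths != control_counts.layout.chrom_lengths
    ):
        raise EstimationError("sample and control counts are on different layouts")
    if sample_counts.phase_offset != control_counts.phase_offset:
        raise EstimationError("sample and control counts are on different phases")

    chroms = sample_counts.layout.chrom_names
    s = np.concatenate([sample_counts.total[c] for c in chroms])
    c = np.concatenate([control_counts.total[c] for c in chroms])
    if c.sum() == 0:
        raise EstimationError(
            "control has no fragments; simulate deeper or provide more control data"
        )
    n = len(s)
    t = s + c
    tmax = int(t.max())
    # per-stratum sums via bincount, then cumulative over increasing t
    s_by_t = np.bincount(t, weights=s, minlength=tmax + 1)
    c_by_t = np.bincount(t, weights=c, minlength=tmax + 1)
    n_by_t = np.bincount(t, minlength=tmax + 1)
    cum_s = np.cumsum(s_by_t)
    cum_c = np.cumsum(c_by_t)
    cum_n = np.cumsum(n_by_t)

    # ratio defined only once some control mass has accumulated
    valid = cum_c > 0
    ratio = np.full(tmax + 1, np.nan)
    ratio[valid] = cum_s[valid] / cum_c[valid]

    curve_t = np.flatnonzero(valid)
    curve_r = ratio[curve_t]

    chosen: int | None = None
    for j in range(len(curve_t) - 1):
        tj = int(curve_t[j])
        if curve_r[j + 1] > curve_r[j] and cum_n[tj] >= min_fraction * n:
            chosen = j
            break
    if chosen is None:
        log.warning(
            "NCIS cumulative ratio never turned upward with >= %.0f%% genome coverage; "
            "falling back to the all-windows ratio",
            100 * min_fraction,
        )
        j_all = len(curve_t) - 1
        return NormalizationFactor(
            r=float(curve_r[j_all]),
            total_cutoff=int(curve_t[j_all]),
            bins_used=n,
            bins_fraction=1.0,
            curve_t=curve_t,
            curve_r=curve_r,
            converged=False,
        )
    t_star = int(curve_t[chosen])
    return NormalizationFactor(
        r=float(curve_r[chosen]),
        total_cutoff=t_star,
        bins_used=int(cum_n[t_star]),
        bins_fraction=float(cum_n[t_star] / n),
        curve_t=curve_t,
        curve_r=curve_r,
        converged=True,
    )
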
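"""Candidate scanning, merging, border refinement, shoulder trimming, FDR selection.

A window becomes a candidate when it (a) reaches the most conservative
of the global and scaled-local Poisson thresholds, (b) has an
NCIS-normalized log2 sample/control ratio above 2, and (c) shows less
than a 3:1 plus/minus strand imbalance. Candidates from all four grid
phases are merged (gap <= 100 bp), borders are refined at 1 bp
resolution against the region's own conservative threshold, low flanks
below the genome-wide mean + 2 SD are trimmed, nearby survivors are
re-merged, and final peaks are selected at Benjamini-Hochberg
FDR <= 1e-5 with a minimum normalized log2 fold change of 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .coverage import FragmentIndex, WindowCounts, count_windows, extend_to_fragments
from .genome_io import GenomeLayout, PeakRecord, ReadSet
from .ncis import estimate_ncis
from .thresholds import LOCAL_SPANS, P_CUT, ThresholdSet, conservative_lambdas_vec

log = logging.getLogger(__name__)

TINY_P = 1e-300


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable peak-calling parameters with their standard defaults."""

    p_cut: float = P_CUT
    local_spans: tuple[int, ...] = LOCAL_SPANS
    min_log2fc: float = 2.0
    strand_ratio_max: float = 3.0
    merge_gap: int = 100
    fdr_cut: float = 1e-5
    shoulder_z: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must be in (0, 1)")
        if not 0 < self.fdr_cut < 1:
            raise ValueError("fdr_cut must be in (0, 1)")
        if self.merge_gap < 0 or self.strand_ratio_max <= 1:
            raise ValueError("merge_gap >= 0 and strand_ratio_max > 1 required")


@dataclass(frozen=True)
class CandidateWindow:
    chrom: str
    start: int
    end: int
    phase: int
    sample_count: int
    control_count: int
    plus_count: int
    minus_count: int
    norm_log2fc: float
    pvalue: float
    threshold: int  # the conservative threshold this window cleared


@dataclass
class PeakRegion:
    """A merged candidate region and its running statistics."""

    chrom: str
    start: int
    end: int
    max_norm_log2fc: float
    min_pvalue: float
    threshold: int
    phases: frozenset[int]
    summit: int | None = None
    qvalue: float | None = None
    border_refined: bool = False
    shoulder_trimmed: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


def scan_phase(
    sample_counts: WindowCounts,
    control_counts: WindowCounts,
    r: float,
    threshold_set: ThresholdSet,
    config: PipelineConfig = PipelineConfig(),
) -> list[CandidateWindow]:
    """Extract candidate windows for one grid phase.

    Only windows at or above the global threshold are examined further —
    the conservative threshold can never be lower — then the adaptive
    local thresholds, the fold-change rule and the strand-balance rule
    are applied. The recorded p-value is the Poisson tail of the sample
    count at the window's largest (most conservative) lambda.
    """
    if sample_counts.phase_offset != control_counts.phase_offset:
        raise ValueError("sample and control counts are on different phases")
    if sample_counts.layout.chrom_names != control_counts.layout.chrom_names:
        raise ValueError("mismatched layouts")
    layout = sample_counts.layout
    phase = sample_counts.phase_offset
    out: list[CandidateWindow] = []
    for chrom in layout.chrom_names:
        s = sample_counts.total[chrom]
        idx = np.flatnonzero(s >= threshold_set.threshold_global)
        if len(idx) == 0:
            continue
        thr, lam_max = conservative_lambdas_vec(
            idx, chrom, control_counts, r, threshold_set
        )
        keep = s[idx] >= thr
        idx, thr, lam_max = idx[keep], thr[keep], lam_max[keep]
        if len(idx) == 0:
            continue
        c = control_counts.total[chrom][idx]
        # control floored at 1 so sparse controls cannot produce infinite ratios
        fc = np.log2(s[idx] / (r * np.maximum(c, 1)))
        pl = sample_counts.plus[chrom][idx]
        mi = sample_counts.minus[chrom][idx]
        ratio = (np.maximum(pl, mi) + 1) / (np.minimum(pl, mi) + 1)
        keep = (fc > config.min_log2fc) & (ratio < config.strand_ratio_max)
        if not keep.any():
            continue
        pvals = poisson.sf(s[idx[keep]] - 1, np.maximum(lam_max[keep], TINY_P))
        wstarts, wends = sample_counts.window_bounds(chrom)
        for i, j in enumerate(np.flatnonzero(keep)):
            w = idx[j]
            out.append(
                CandidateWindow(
                    chrom=chrom,
                    start=int(wstarts[w]),
                    end=int(wends[w]),
                    phase=phase,
                    sample_count=int(s[w]),
                    control_count=int(c[j]),
                    plus_count=int(pl[j]),
                    minus_count=int(mi[j]),
                    norm_log2fc=float(fc[j]),
                    pvalue=float(max(pvals[i], TINY_P)),
                    threshold=int(thr[j]),
                )
            )
    return out


def merge_candidates(
    candidates: list[CandidateWindow], merge_gap: int = 100
) -> list[PeakRegion]:
    """Merge overlapping or near-adjacent candidate windows into regions.

    Any two windows overlapping or separated by <= merge_gap bp merge
    transitively; a region carries the max fold change, the min p-value
    and the max conservative threshold of its constituents.
    """
    if not candidates:
        return []
    ordered = sorted(candidates, key=lambda w: (w.chrom, w.start, w.end))
    regions: list[PeakRegion] = []
    cur = None
    for w in ordered:
        if cur is not None and w.chrom == cur.chrom and w.start - cur.end <= merge_gap:
            cur.end = max(cur.end, w.end)
            cur.max_norm_log2fc = max(cur.max_norm_log2fc, w.norm_log2fc)
            cur.min_pvalue = min(cur.min_pvalue, w.pvalue)
            cur.threshold = max(cur.threshold, w.threshold)
            cur.phases = cur.phases | {w.phase}
        else:
            cur = PeakRegion(
                chrom=w.chrom,
                start=w.start,
                end=w.end,
                max_norm_log2fc=w.norm_log2fc,
                min_pvalue=w.pvalue,
                threshold=w.threshold,
                phases=frozenset({w.phase}),
            )
            regions.append(cur)
    return regions


def _merge_regions(regions: list[PeakRegion], merge_gap: int) -> list[PeakRegion]:
    """Re-merge refined/trimmed regions brought within merge_gap of each other."""
    if not regions:
        return []
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    out = [replace(ordered[0])]
    for reg in ordered[1:]:
        cur = out[-1]
        if reg.chrom == cur.chrom and reg.start - cur.end <= merge_gap:
            cur.end = max(cur.end, reg.end)
            cur.max_norm_log2fc = max(cur.max_norm_log2fc, reg.max_norm_log2fc)
            cur.min_pvalue = min(cur.min_pvalue, reg.min_pvalue)
            cur.threshold = max(cur.threshold, reg.threshold)
            cur.phases = cur.phases | reg.phases
            cur.border_refined = cur.border_refined or reg.border_refined
            cur.shoulder_trimmed = cur.shoulder_trimmed or reg.shoulder_trimmed
        else:
            out.append(replace(reg))
    return out


def refine_borders(
    region: PeakRegion,
    fragments: FragmentIndex,
    threshold: int,
    window_size: int = 100,
) -> PeakRegion:
    """Slide a window one window-size up/downstream of each border at 1 bp steps.

    The new left border is the smallest window start whose sample count
    reaches the region's conservative threshold; the right border is the
    mirror image. A side with no qualifying window keeps its border.
    Borders are clamped at the region midpoint so they can never cross.
    """
    L = fragments.layout.chrom_lengths[region.chrom]
    mid = (region.start + region.end) // 2
    W = window_size

    xs = np.arange(max(0, region.start - W), min(region.start + W, L - 1) + 1)
    counts = fragments.counts_in(region.chrom, xs, np.minimum(xs + W, L))
    ok = np.flatnonzero(counts >= threshold)
    new_start = int(xs[ok[0]]) if len(ok) else region.start
    new_start = min(new_start, mid)

    ys = np.arange(max(1, region.end - W), min(region.end + W, L) + 1)
    counts = fragments.counts_in(region.chrom, np.maximum(ys - W, 0), ys)
    ok = np.flatnonzero(counts >= threshold)
    new_end = int(ys[ok[-1]]) if len(ok) else region.end
    new_end = max(new_end, mid + 1)

    changed = (new_start != region.start) or (new_end != region.end)
    return replace(region, start=new_start, end=new_end, border_refined=changed)


def trim_shoulders(
    region: PeakRegion,
    fragments: FragmentIndex,
    mu: float,
    sd: float,
    z: float = 2.0,
    window_size: int = 100,
) -> PeakRegion | None:
    """Drop 100 bp border steps whose sample count is below mu + z*sd.

    mu and sd are genome-wide per-window sample statistics (phase 0).
    Trimming proceeds inward from each border and stops at the first
    step meeting the cutoff; a region trimmed to nothing is discarded.
    """
    cutoff = mu + z * sd
    W = window_size
    start, end = region.start, region.end
    while end - start >= W and fragments.count_in(region.chrom, start, start + W) < cutoff:
        start += W
    while end - start >= W and fragments.count_in(region.chrom, end - W, end) < cutoff:
        end -= W
    if end - start < W and fragments.count_in(region.chrom, start, end) < cutoff:
        log.debug(
            "region %s:%d-%d entirely below mu+%gsd, discarded",
            region.chrom, region.start, region.end, z,
        )
        return None
    changed = (start != region.start) or (end != region.end)
    return replace(region, start=start, end=end, shoulder_trimmed=changed)


def _summit(region: PeakRegion, fragments: FragmentIndex, window_size: int = 100) -> int:
    """Center of the 100 bp sliding window with maximal sample count (leftmost tie)."""
    if region.width <= window_size:
        return (region.start + region.end) // 2
    xs = np.arange(region.start, region.end - window_size + 1)
    counts = fragments.counts_in(region.chrom, xs, xs + window_size)
    best = int(xs[int(np.argmax(counts))])
    return best + window_size // 2


def assign_significance(
    regions: list[PeakRegion],
    fragments: FragmentIndex,
    fdr_cut: float = 1e-5,
    min_log2fc: float = 2.0,
    n_tests: int | None = None,
) -> list[PeakRegion]:
    """BH-adjust region p-values and select final peaks.

    The hypotheses actually tested are windows, so the pipeline passes
    n_tests = the total number of windows scanned over all phases and
    the BH adjustment runs at that family size, with each region ranked
    by its best window. Every untested-for-candidacy window has a larger
    p-value than every candidate, so ranking the candidate p-values
    directly reproduces the full-family BH ordering without
    materializing p-values for empty windows. With n_tests=None the
    family is just the regions themselves.

    A region survives with q <= fdr_cut and max normalized log2 fold
    change >= min_log2fc; survivors get their summit assigned.
    """
    if not regions:
        return []
    pvals = np.array([r.min_pvalue for r in regions])
    if n_tests is None or n_tests <= len(regions):
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        order = np.argsort(pvals, kind="stable")
        ranked = pvals[order] * n_tests / np.arange(1, len(pvals) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]  # monotone step of BH
        qvals = np.empty_like(pvals)
        qvals[order] = np.minimum(ranked, 1.0)
    out: list[PeakRegion] = []
    for reg, q in zip(regions, qvals):
        reg.qvalue = float(q)
        if reg.qvalue <= fdr_cut and reg.max_norm_log2fc >= min_log2fc:
            reg.summit = _summit(reg, fragments)
            out.append(reg)
    return out


def call_peaks(
    sample: ReadSet,
    control: ReadSet,
    layout: GenomeLayout,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[PeakRecord], dict]:
    """End-to-end peak calling; returns sorted PeakRecords and a stage report.

    Stages: fragment extension -> phase-0 counting -> NCIS -> global
    threshold -> four-phase candidate scan -> merge -> border refinement
    -> shoulder trimming -> re-merge -> BH selection. Deterministic
    given its inputs.
    """
    report: dict = {"stages": {}}
    if sample.total_count == 0:
        report["stages"]["sample_reads"] = 0
        return [], report

    frag_s = extend_to_fragments(sample, layout)
    frag_c = extend_to_fragments(control, layout)
    report["stages"]["sample_fragments"] = frag_s.total_count
    report["stages"]["control_fragments"] = frag_c.total_count

    counts_s0 = count_windows(frag_s, layout, 0)
    counts_c0 = count_windows(frag_c, layout, 0)
    ncis = estimate_ncis(counts_s0, counts_c0)
    report["ncis_r"] = ncis.r
    report["ncis_converged"] = ncis.converged

    tset = ThresholdSet(
        p_cut=config.p_cut,
        lambda_global=counts_s0.genome_mean,
        local_spans=config.local_spans,
        r=ncis,
    )
    report["lambda_global"] = tset.lambda_global
    report["threshold_global"] = tset.threshold_global
    mu, sd = counts_s0.genome_stats()
    report["shoulder_mu"], report["shoulder_sd"] = mu, sd

    candidates: list[CandidateWindow] = []
    per_phase: dict[int, int] = {}
    n_tests = 0
    for phase in layout.phases:
        cs = counts_s0 if phase == 0 else count_windows(frag_s, layout, phase)
        cc = counts_c0 if phase == 0 else count_windows(frag_c, layout, phase)
        found = scan_phase(cs, cc, ncis.r, tset, config)
        per_phase[phase] = len(found)
        candidates.extend(found)
        n_tests += sum(cs.n_windows(c) for c in layout.chrom_names)
    report["stages"]["candidates_per_phase"] = per_phase
    report["stages"]["windows_tested"] = n_tests

    regions = merge_candidates(candidates, config.merge_gap)
    report["stages"]["merged_regions"] = len(regions)

    regions = [refine_borders(reg, frag_s, reg.threshold) for reg in regions]
    trimmed = [trim_shoulders(reg, frag_s, mu, sd, config.shoulder_z) for reg in regions]
    regions = [reg for reg in trimmed if reg is not None]
    report["stages"]["after_trim"] = len(regions)

    regions = _merge_regions(regions, config.merge_gap)
    final = assign_significance(
        regions, frag_s, config.fdr_cut, config.min_log2fc, n_tests=n_tests
    )
    report["stages"]["final_peaks"] = len(final)

    final.sort(key=lambda r: (layout.chrom_names.index(r.chrom), r.start))
    records = [
        PeakRecord(
            chrom=reg.chrom,
            start=reg.start,
            end=reg.end,
            name=f"peak_{i + 1}",
            signal=reg.max_norm_log2fc,
            pvalue=-math.log10(max(reg.min_pvalue, TINY_P)),
            qvalue=-math.log10(max(reg.qvalue, TINY_P)),
            summit_offset=min(max(reg.summit - reg.start, 0), reg.width - 1),
        )
        for i, reg in enumerate(final)
    ]
    return records, report
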
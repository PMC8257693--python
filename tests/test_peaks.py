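"""Candidate scanning, region operations, and end-to-end peak calling."""

import math

import numpy as np
import pytest
from scipy.stats import poisson

from phasepeaks.coverage import count_windows, extend_to_fragments, local_mean
from phasepeaks.genome_io import write_peaks
from phasepeaks.ncis import estimate_ncis
from phasepeaks.peaks import (
    CandidateWindow,
    PeakRegion,
    PipelineConfig,
    assign_significance,
    call_peaks,
    merge_candidates,
    refine_borders,
    scan_phase,
    trim_shoulders,
)
from phasepeaks.simulate import SimConfig, default_layout, simulate_background, simulate_peaks
from phasepeaks.thresholds import ThresholdSet

from conftest import fragments_at, window_counts
from test_thresholds import oracle_threshold


def region(chrom="toy", start=1000, end=1400, fc=4.0, p=1e-9, thr=5, phases=(0,)):
    return PeakRegion(chrom, start, end, fc, p, thr, frozenset(phases))


class TestScanPhase:
    def test_candidate_arithmetic(self, toy_layout):
        """A 40-count window over control 2 at r=1.2: log2(40/2.4) ~ 4.06."""
        sample = {"toy": [(1005 + i, 1 if i < 22 else -1) for i in range(40)]}
        control = {"toy": [(1005 + i, 1) for i in range(2)]}
        sc = window_counts(toy_layout, sample)
        cc = window_counts(toy_layout, control)
        tset = ThresholdSet(p_cut=1e-5, lambda_global=sc.genome_mean)
        found = scan_phase(sc, cc, 1.2, tset)
        cand = [w for w in found if w.start == 1000]
        assert len(cand) == 1
        w = cand[0]
        assert (w.sample_count, w.control_count, w.plus_count, w.minus_count) == (40, 2, 22, 18)
        assert w.norm_log2fc == pytest.approx(math.log2(40 / 2.4))

    def test_strand_imbalance_rejected(self, toy_layout):
        sample = {"toy": [(1005 + i, 1 if i < 35 else -1) for i in range(40)]}
        sc = window_counts(toy_layout, sample)
        cc = window_counts(toy_layout, {"toy": []})
        tset = ThresholdSet(p_cut=1e-5, lambda_global=sc.genome_mean)
        found = scan_phase(sc, cc, 1.2, tset)
        assert not [w for w in found if w.start == 1000]  # (35+1)/(5+1) = 6 >= 3

    def test_subthreshold_rejected_despite_fold_change(self, toy_layout):
        sample = {"toy": [(1005 + i, 1 if i % 2 else -1) for i in range(8)]}
        sc = window_counts(toy_layout, sample)
        cc = window_counts(toy_layout, {"toy": []})
        tset = ThresholdSet(p_cut=1e-5, lambda_global=5.0)  # oracle threshold 18
        assert scan_phase(sc, cc, 1.0, tset) == []

    def test_matches_bruteforce_on_toy_chromosome(self, toy_layout):
        """Independent re-evaluation of all three rules on 100 hand-set windows."""
        rng = np.random.default_rng(42)
        sample_placed, control_placed = [], []
        for w in range(100):
            base = w * 100
            for _ in range(int(rng.poisson(1.0))):
                sample_placed.append((base + int(rng.integers(100)), int(rng.choice([1, -1]))))
            for _ in range(int(rng.poisson(1.0))):
                control_placed.append((base + int(rng.integers(100)), int(rng.choice([1, -1]))))
        # hot windows: clean peak / strand-skewed / control-matched
        for w, n_plus, n_minus, n_ctrl in [(10, 12, 10, 0), (40, 20, 2, 0), (70, 11, 11, 30)]:
            base = w * 100
            sample_placed += [(base + 2 * i, 1) for i in range(n_plus)]
            sample_placed += [(base + 2 * i + 1, -1) for i in range(n_minus)]
            control_placed += [(base + 3 * (i % 33), 1) for i in range(n_ctrl)]
        sc = window_counts(toy_layout, {"toy": sample_placed})
        cc = window_counts(toy_layout, {"toy": control_placed})
        r = 1.1
        tset = ThresholdSet(p_cut=1e-5, lambda_global=sc.genome_mean)
        got = {w.start: w for w in scan_phase(sc, cc, r, tset)}

        expected = {}
        for w in range(100):
            s = int(sc.total["toy"][w])
            c = int(cc.total["toy"][w])
            pl, mi = int(sc.plus["toy"][w]), int(sc.minus["toy"][w])
            lams = [tset.lambda_global] + [
                local_mean(cc, "toy", w, span) * r for span in (500, 1000, 25000)
            ]
            thr = max(oracle_threshold(lam, 1e-5) if lam > 0 else 1 for lam in lams)
            if s < thr:
                continue
            if not math.log2(s / (r * max(c, 1))) > 2:
                continue
            if not (max(pl, mi) + 1) / (min(pl, mi) + 1) < 3:
                continue
            expected[w * 100] = (s, c, poisson.sf(s - 1, max(lams)))
        assert set(got) == set(expected)
        for start, (s, c, p) in expected.items():
            assert got[start].sample_count == s
            assert got[start].control_count == c
            assert got[start].pvalue == pytest.approx(p, rel=1e-9)


class TestMerge:
    def test_gap_at_most_100_merges(self):
        a = CandidateWindow("c", 1000, 1100, 0, 10, 0, 5, 5, 4.0, 1e-8, 5)
        b = CandidateWindow("c", 1150, 1250, 0, 12, 1, 6, 6, 3.5, 1e-9, 6)
        merged = merge_candidates([a, b])
        assert len(merged) == 1
        m = merged[0]
        assert (m.start, m.end) == (1000, 1250)
        assert m.max_norm_log2fc == 4.0 and m.min_pvalue == 1e-9 and m.threshold == 6

    def test_gap_over_100_stays_split(self):
        a = CandidateWindow("c", 1000, 1100, 0, 10, 0, 5, 5, 4.0, 1e-8, 5)
        b = CandidateWindow("c", 1225, 1325, 0, 12, 1, 6, 6, 3.5, 1e-9, 6)
        assert len(merge_candidates([a, b])) == 2

    def test_cross_phase_overlap_merges(self):
        a = CandidateWindow("c", 1000, 1100, 0, 10, 0, 5, 5, 4.0, 1e-8, 5)
        b = CandidateWindow("c", 1025, 1125, 25, 10, 0, 5, 5, 4.0, 1e-8, 5)
        merged = merge_candidates([a, b])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (1000, 1125)
        assert merged[0].phases == frozenset({0, 25})

    def test_transitive_chain(self):
        wins = [
            CandidateWindow("c", s, s + 100, 0, 10, 0, 5, 5, 4.0, 1e-8, 5)
            for s in (1000, 1200, 1400)
        ]
        assert len(merge_candidates(wins)) == 1

    def test_empty(self):
        assert merge_candidates([]) == []


class TestRefineBorders:
    def test_left_border_moves_to_first_qualifying_window(self, toy_layout):
        frags = fragments_at(toy_layout, {"toy": [(1055 + i, 1) for i in range(5)]})
        out = refine_borders(region(start=1000, end=1400, thr=5), frags, threshold=5)
        assert out.start == 960  # smallest x in [900,1100] with >=5 midpoints in [x, x+100)
        assert out.border_refined

    def test_subthreshold_flanks_leave_borders(self, toy_layout):
        frags = fragments_at(toy_layout, {"toy": [(1200, 1), (1210, -1)]})
        out = refine_borders(region(start=1000, end=1400, thr=5), frags, threshold=5)
        assert (out.start, out.end) == (1000, 1400)
        assert not out.border_refined

    def test_bounded_search_range(self, toy_layout):
        """Never widens more than 100 bp per side, never shrinks past the midpoint."""
        rng = np.random.default_rng(3)
        frags = fragments_at(
            toy_layout, {"toy": sorted((int(m), 1) for m in rng.integers(500, 2500, 400))}
        )
        reg = region(start=1000, end=1400)
        for thr in (1, 3, 10, 50):
            out = refine_borders(reg, frags, threshold=thr)
            assert reg.start - 100 <= out.start <= (reg.start + reg.end) // 2
            assert (reg.start + reg.end) // 2 < out.end <= reg.end + 100
            assert out.start < out.end


class TestTrimShoulders:
    def test_all_windows_strong_unchanged(self, toy_layout):
        frags = fragments_at(toy_layout, {"toy": [(1000 + i, 1) for i in range(400)]})
        out = trim_shoulders(region(start=1000, end=1400), frags, mu=0.5, sd=0.7)
        assert (out.start, out.end) == (1000, 1400)
        assert not out.shoulder_trimmed

    def test_background_flanks_trimmed_one_window_each(self, toy_layout):
        placed = [(1050, 1), (1350, -1)] + [(1100 + i, 1 if i % 2 else -1) for i in range(200)]
        frags = fragments_at(toy_layout, {"toy": sorted(placed)})
        out = trim_shoulders(region(start=1000, end=1400), frags, mu=1.0, sd=0.5)
        assert (out.start, out.end) == (1100, 1300)
        assert out.shoulder_trimmed

    def test_fully_weak_region_discarded(self, toy_layout):
        frags = fragments_at(toy_layout, {"toy": [(1150, 1)]})
        assert trim_shoulders(region(start=1000, end=1400), frags, mu=2.0, sd=1.0) is None


class TestAssignSignificance:
    def test_single_region_small_family(self, toy_layout):
        frags = fragments_at(toy_layout, {"toy": [(1200, 1)]})
        out = assign_significance([region(p=1e-9)], frags)
        assert len(out) == 1 and out[0].qvalue == pytest.approx(1e-9)

    def test_equal_pvalues_all_kept_at_cutoff(self, toy_layout):
        frags = fragments_at(toy_layout, {"toy": [(1200, 1)]})
        regions = [region(start=1000 + 300 * i, end=1200 + 300 * i, p=1e-6) for i in range(20)]
        out = assign_significance(regions, frags)
        assert len(out) == 20
        assert all(r.qvalue == pytest.approx(1e-6) for r in out)

    def test_fold_change_conjunction(self, toy_layout):
        frags = fragments_at(toy_layout, {"toy": [(1200, 1)]})
        out = assign_significance([region(p=1e-9, fc=1.5)], frags)
        assert out == []

    def test_window_family_inflates_q(self, toy_layout):
        """With the genome-wide family size a lone p=2e-6 window is not a peak."""
        frags = fragments_at(toy_layout, {"toy": [(1200, 1)]})
        out = assign_significance([region(p=2e-6)], frags, n_tests=400_000)
        assert out == []

    def test_summit_is_max_sliding_window_center(self, toy_layout):
        placed = [(1250 + (i % 40), 1 if i % 2 else -1) for i in range(30)]
        frags = fragments_at(toy_layout, {"toy": sorted(placed)})
        out = assign_significance([region(start=1000, end=1500, p=1e-12)], frags)
        assert len(out) == 1
        assert abs(out[0].summit - 1270) <= 50

    def test_empty_input(self, toy_layout):
        frags = fragments_at(toy_layout, {"toy": []})
        assert assign_significance([], frags) == []


LAYOUT_10MB = default_layout(10_000_000)


@pytest.fixture(scope="module")
def spiked_run():
    cfg = SimConfig(layout=LAYOUT_10MB, n_peaks=50, seed=1)
    sample, control, truth = simulate_peaks(cfg)
    peaks, report = call_peaks(sample, control, LAYOUT_10MB)
    return cfg, sample, control, truth, peaks, report


class TestCallPeaks:
    def test_recovers_spiked_peaks(self, spiked_run):
        _, _, _, truth, peaks, _ = spiked_run
        recovered = summit_ok = 0
        for chrom, summit in zip(truth.peak_chroms, truth.peak_summits):
            for pk in peaks:
                if pk.chrom == chrom and pk.start - 100 <= summit <= pk.end + 100:
                    recovered += 1
                    if abs(pk.start + pk.summit_offset - summit) <= 100:
                        summit_ok += 1
                    break
        assert recovered >= 45
        assert summit_ok >= 0.8 * recovered
        off_truth = sum(
            not any(
                pk.chrom == ch and abs((pk.start + pk.end) // 2 - su) < 25_000
                for ch, su in zip(truth.peak_chroms, truth.peak_summits)
            )
            for pk in peaks
        )
        assert off_truth <= 2

    def test_final_peaks_disjoint_and_separated(self, spiked_run):
        _, _, _, _, peaks, _ = spiked_run
        for a, b in zip(peaks, peaks[1:]):
            if a.chrom == b.chrom:
                assert b.start - a.end > 100

    def test_run_report_stages(self, spiked_run):
        _, _, _, _, peaks, report = spiked_run
        assert report["ncis_r"] == pytest.approx(1.0, abs=0.05)
        assert report["stages"]["final_peaks"] == len(peaks)
        assert report["stages"]["windows_tested"] > 390_000

    def test_identical_sample_and_control_yield_nothing(self):
        layout = default_layout(1_000_000)
        sample, _, _ = simulate_background(SimConfig(layout=layout, seed=2))
        peaks, _ = call_peaks(sample, sample, layout)
        assert peaks == []

    def test_empty_sample_yields_nothing(self, mb_layout):
        from phasepeaks.genome_io import ReadSet

        empty = ReadSet.from_records(mb_layout, [])
        control, _, _ = simulate_background(SimConfig(layout=mb_layout, seed=3))
        peaks, report = call_peaks(empty, control, mb_layout)
        assert peaks == [] and report["stages"]["sample_reads"] == 0

    def test_four_phase_coverage_superset_of_phase0(self, spiked_run):
        cfg, sample, control, _, _, _ = spiked_run
        layout = cfg.layout
        frag_s = extend_to_fragments(sample, layout)
        frag_c = extend_to_fragments(control, layout)
        cs0 = count_windows(frag_s, layout, 0)
        cc0 = count_windows(frag_c, layout, 0)
        nf = estimate_ncis(cs0, cc0)
        tset = ThresholdSet(p_cut=1e-5, lambda_global=cs0.genome_mean)
        all_cands = []
        for phase in layout.phases:
            cs = cs0 if phase == 0 else count_windows(frag_s, layout, phase)
            cc = cc0 if phase == 0 else count_windows(frag_c, layout, phase)
            all_cands.extend(scan_phase(cs, cc, nf.r, tset))
        phase0 = [w for w in all_cands if w.phase == 0]
        cover_all = {
            (r.chrom, bp) for r in merge_candidates(all_cands) for bp in range(r.start, r.end)
        }
        cover_p0 = {
            (r.chrom, bp) for r in merge_candidates(phase0) for bp in range(r.start, r.end)
        }
        assert cover_p0 <= cover_all

    def test_translation_equivariance(self):
        """Shifting all reads +1000 bp shifts every peak by exactly +1000 bp."""
        from phasepeaks.genome_io import ReadSet

        inner = default_layout(2_000_000)
        outer = default_layout(2_010_000)
        cfg = SimConfig(layout=inner, n_peaks=10, seed=4)
        sample, control, _ = simulate_peaks(cfg)

        def embed(rs, shift):
            return ReadSet(
                outer,
                {c: s + shift for c, s in rs.starts.items()},
                {c: e + shift for c, e in rs.ends.items()},
                {c: st.copy() for c, st in rs.strands.items()},
                rs.fragment_length,
            )

        base, _ = call_peaks(embed(sample, 0), embed(control, 0), outer)
        moved, _ = call_peaks(embed(sample, 1000), embed(control, 1000), outer)
        assert len(base) == len(moved) >= 5
        for a, b in zip(base, moved):
            assert (b.start, b.end, b.summit_offset) == (a.start + 1000, a.end + 1000, a.summit_offset)

    def test_enrichment_monotonicity(self):
        layout = default_layout(5_000_000)

        def recovered(enrichment):
            cfg = SimConfig(layout=layout, n_peaks=25, peak_enrichment=enrichment, seed=6)
            sample, control, truth = simulate_peaks(cfg)
            peaks, _ = call_peaks(sample, control, layout)
            return sum(
                any(pk.chrom == ch and pk.start - 100 <= su <= pk.end + 100 for pk in peaks)
                for ch, su in zip(truth.peak_chroms, truth.peak_summits)
            )

        assert recovered(4.0) <= recovered(10.0)

    def test_deterministic_byte_identical_output(self, spiked_run, tmp_path):
        cfg, sample, control, _, peaks, _ = spiked_run
        again, _ = call_peaks(sample, control, cfg.layout)
        write_peaks(peaks, tmp_path / "a.narrowPeak")
        write_peaks(again, tmp_path / "b.narrowPeak")
        assert (tmp_path / "a.narrowPeak").read_bytes() == (tmp_path / "b.narrowPeak").read_bytes()


def test_pipeline_config_validation():
    with pytest.raises(ValueError):
        PipelineConfig(p_cut=0)
    with pytest.raises(ValueError):
        PipelineConfig(fdr_cut=1.5)
    with pytest.raises(ValueError):
        PipelineConfig(strand_ratio_max=1.0)
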
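# Methods

## Coordinate model and counting

All coordinates are 0-based half-open (BED convention). Each aligned
read is replaced by a fragment of exactly L = 150 bp anchored at the
read's 5′ end and extended in the read's orientation, clipped to the
chromosome; the fragment is represented by its midpoint
⌊(start + end)/2⌋. A midpoint belongs to exactly one window of each
grid phase, so window counts are Poisson-consistent: the global rate
λ_global = (assigned midpoints) / (number of windows) is simultaneously
the mean of the per-window counts. Assignment by midpoint rather than
by any-overlap is a deliberate choice — overlap assignment counts a
fragment in up to two windows and breaks that identity.

The W = 100 bp grid is evaluated at phase offsets {0, 25, 50, 75} bp.
For a nonzero phase φ, a leading partial window [0, φ) keeps the grid
covering the chromosome; chromosome-end windows are likewise truncated.
Local background means over spans of 500, 1000 and 25 000 bp (5×, 10×,
250× the window) are centered on the query window's midpoint, clipped
at chromosome ends, and scaled by W / (clipped width), so edge lambdas
are not deflated by the missing flank.

## NCIS normalization

Windows are stratified by combined sample+control count t (whole strata
enter together, which makes the estimate deterministic), and the
cumulative ratio r(t) = Σs_i / Σc_i over windows with s_i + c_i ≤ t is
scanned in increasing t. r is taken at the smallest t* where
r(t*+1) > r(t*) — the upturn marking signal-contaminated strata —
subject to the windows at or below t* covering ≥ 75 % of the genome.
If no stratum qualifies, the all-windows ratio is returned with a
warning (`converged=False`). Estimation uses phase-0 counts only; r is
a global depth property and is applied unchanged to all phases.

## Thresholds and candidate windows

The count threshold for rate λ at tail probability p = 1e−5 is the
smallest integer k with P(X ≥ k | Poisson(λ)) ≤ p (inclusive tail: a
count equal to the threshold is significant). Implementation uses
`scipy.stats.poisson` with an exact adjustment loop; the test suite
pins it to a direct pmf-summation oracle over
λ ∈ {0, 0.01, 0.1, 0.5, 1, 2, 5, 10, 50, 200} × p ∈ {1e−3, 1e−5}.
At λ = 0 the threshold is 1 (any count is significant).

A window is a candidate when

1. its sample count reaches max(global threshold, three local
   thresholds from control spans, each local λ multiplied by r);
   only the control-derived thresholds are scaled by r;
2. log2(s / (r · max(c, 1))) > 2 — the control count is floored at 1
   so empty-control windows cannot produce infinite fold changes;
3. (max(plus, minus) + 1) / (min(plus, minus) + 1) < 3 — +1
   pseudocounts keep zero-count strands well-defined.

The candidate's p-value is the Poisson tail of its sample count at the
largest of the four lambdas, keeping the p-value consistent with the
threshold that gated the window.

## Regions: merge, refine, trim, select

Candidates from all four phases merge transitively when overlapping or
≤ 100 bp apart; a region carries the max fold change, min p-value and
max threshold of its constituents. Borders are then refined by sliding
a 100 bp window from one window-size upstream to one downstream of each
border at 1 bp steps: the new left border is the smallest window start
whose count reaches the region's own conservative threshold (right
border mirrored); a side with no qualifying window keeps its border,
and borders are clamped at the region midpoint so they cannot cross.
Shoulders are trimmed inward in 100 bp steps while the windowed count
is below µ + 2·SD, where µ and SD are the genome-wide mean and SD of
phase-0 sample window counts — a region-internal µ + 2·SD would trim
nearly everything, so the genome-wide reading is the self-consistent
one. A region trimmed to nothing is discarded. Refined/trimmed regions
brought within 100 bp of each other are re-merged before selection.

**FDR family.** The hypotheses tested are windows, not regions, so the
Benjamini–Hochberg adjustment runs at family size m = total windows
scanned over all phases (~4×10^5 on a 10 Mb genome), with each region
ranked by its best window; every non-candidate window has a larger
p-value than every candidate, so ranking the candidates alone
reproduces the full-family ordering. This choice is what gives the
pipeline its type-I control: a lone background fluctuation reaching
p ≈ 2e−6 receives q ≈ 0.8 and is rejected, whereas a region-only
family (m = a handful of candidates) would pass it; genuine peaks sit
at p ≤ 1e−12 and are unaffected. `assign_significance` retains an
`n_tests=None` mode that adjusts across regions only, for small-family
analyses. Final peaks need q ≤ 1e−5 and fold change ≥ 2; the summit is
the center of the maximal 100 bp sliding window (leftmost on ties).

## Parameters

| parameter | default | meaning |
|---|---|---|
| fragment_length | 150 bp | library fragment size used for 5′ extension |
| window_size | 100 bp | counting window |
| phase_step | 25 bp | grid offset between the four phases |
| p_cut | 1e−5 | Poisson tail probability for all thresholds |
| local_spans | 500, 1000, 25000 bp | control spans for adaptive local λ |
| min_log2fc | 2 | normalized fold-change cutoff (candidates and final) |
| strand_ratio_max | 3 | pseudocounted plus/minus imbalance cutoff |
| merge_gap | 100 bp | maximum gap merged between candidate windows |
| fdr_cut | 1e−5 | BH q cutoff for final peaks |
| shoulder_z | 2 | SD multiplier for shoulder trimming |

## Synthetic data

The generator emulates exactly the structure the caller assumes:
homogeneous Poisson fragment midpoints in sample and control (control
rate = sample rate / depth_ratio, so depth_ratio is the true
normalization coefficient), plus sample-only peaks whose extra
midpoints are Normal(summit, 50 bp) — giving the summit/shoulder shape
the refinement and trimming stages exist to handle. Reads are 36 bp,
placed so that 150 bp extension recovers the drawn midpoint, with
fair-coin strands; at the default per-peak fragment count (40) the
binomial tail puts both strands within 3:1 with probability > 0.99.
Peaks are ≥ 50 kb apart and ≥ 25 kb from chromosome ends so the 25 kb
local-lambda spans of distinct peaks never interact. The per-peak
fragment count is deterministic:
round((enrichment − 1) · rate · W / (Φ(50/σ) − Φ(−50/σ))), so the
summit window's expected count is enrichment × the background window
mean.

**Depth default.** The default background rate is 0.03 fragments/bp
(λ = 3 per window). This comes from a Poisson power analysis: for a
10-fold summit enrichment to be callable at genome-wide-FDR
significance, the summit window must reach the count k with
P(X ≥ k | λ) ≤ q·rank/m, and the probability of that under the summit
mean (≈ 10λ) is 0.20 at λ = 1, 0.83 at λ = 2, 0.99 at λ = 3. λ = 3 is
the smallest integer rate at which a recovery experiment measures the
caller rather than the sequencing depth. NCIS recovery runs use
0.002 fragments/bp (~20 000 fragments per sample on 10 Mb) — the
estimator needs only low-coverage strata, not detection power.

What the simulator does **not** model: mappability and GC bias,
duplicate reads, input-side enrichment artifacts, real genome sequence.
Passing tests therefore show the algorithm is correct under its own
statistical assumptions, not that those assumptions hold for any given
real library.

## qPCR and DEG computations

ΔΔCt assumes amplification efficiency 2.0 (no efficiency correction);
replicates are averaged on the Ct scale before any subtraction. ChIP
fold enrichment is 2^−(Ct_target − Ct_normalizer) in each IP, ChIP
divided by empty-vector; it is invariant to any global Ct shift. The
DEG filter keeps genes with BH q < 0.001 and |log2FC| ≥ 1 — the
twofold cutoff is applied symmetrically in both directions, on the
log2 scale.

## Numerical and degenerate-input choices

- p-values are floored at 1e−300 before −log10 for narrowPeak output.
- Sample = control input yields zero peaks (the fold-change rule cannot
  pass); an empty sample short-circuits to an empty result.
- Reads on chromosomes absent from the layout are dropped with a logged
  count; "." strands are a hard error because the strand-balance filter
  requires orientation.
- Peak placement draws sorted uniforms in the spacing-reduced interval
  and adds the minimum gaps back, so dense placements terminate without
  rejection sampling while remaining uniform given the constraint.
- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give byte-identical BED and narrowPeak files.

## Problem sizes used in validation

Desk-scale runs use a single 10 Mb chromosome: background-only type-I
runs (20 seeds in the acceptance script, 10 in the test suite), one
50-peak recovery run, four NCIS depth-ratio runs at ~20 000 fragments,
a 100-window toy chromosome for the brute-force candidate check, and a
1000-gene expression table for the DEG check. A full pipeline run at
these sizes takes well under a second.

## Known limitations

- The NCIS stopping rule (first cumulative-ratio upturn with ≥ 75 %
  genome coverage) is one reasonable reading of the published
  procedure; other implementations stop on different diagnostics.
- Region significance is summarized by the minimum constituent window
  p-value, which is anti-conservative for very wide regions.
- Broad/diffuse enrichment (domains rather than point sources) is out
  of scope: the strand-balance filter and 100 bp windows target
  point-source binding.
- The caller assumes a Poisson background; overdispersed real inputs
  will inflate the false-positive rate relative to the synthetic
  results reported here.
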
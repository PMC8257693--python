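"""Synthetic ChIP-seq reads and qPCR Ct tables with known ground truth.

The read simulator emulates the statistical structure the caller
assumes: a homogeneous Poisson background of fragment midpoints in both
the ChIP sample and the input control (at a known depth ratio, the true
normalization coefficient), plus, in the sample only, spiked peaks whose
extra fragment midpoints are Normal-dispersed around a summit. Reads are
emitted as 36 bp intervals positioned so that 150 bp fragment extension
recovers the drawn midpoint, with fair-coin strands — so true summits
show the balanced plus/minus structure the strand filter expects.

It does not model mappability, GC bias, duplicate reads or input-side
enrichment artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome_io import FRAGMENT_LENGTH, GenomeLayout, ReadSet

READ_LENGTH = 36
HALF_FRAGMENT = FRAGMENT_LENGTH // 2

MIN_PEAK_SPACING = 50_000
MIN_EDGE_DISTANCE = 25_000


def default_layout(chrom_length: int = 10_000_000, name: str = "chrSim") -> GenomeLayout:
    """A single synthetic 10 Mb chromosome, the standard desk-scale genome."""
    return GenomeLayout((name,), {name: chrom_length})


@dataclass(frozen=True)
class SimConfig:
    """Synthetic dataset parameters.

    background_rate is fragments per bp in the sample; the default
    0.03/bp (3 per 100 bp window) is the depth a Poisson power analysis
    requires for a recovery study at 10-fold summit enrichment: the
    summit window then clears the genome-wide-FDR significance count
    with >97% probability, so missed peaks reflect the caller, not an
    underpowered design. The control rate is background_rate /
    depth_ratio, making depth_ratio the true normalization coefficient.
    peak_enrichment is the target windowed sample count at the summit
    as a multiple of the background window mean; peak_width_sd
    disperses peak fragment midpoints.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    background_rate: float = 0.03
    depth_ratio: float = 1.0
    n_peaks: int = 0
    peak_enrichment: float = 10.0
    peak_width_sd: float = 50.0
    fragment_length: int = FRAGMENT_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0 or self.depth_ratio <= 0:
            raise ValueError("rates must be positive")
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    depth_ratio: float
    peak_chroms: list[str]
    peak_summits: list[int]
    peak_n_fragments: list[int]
    peak_half_width: int

    @property
    def n_peaks(self) -> int:
        return len(self.peak_summits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_id": [f"truth_{i + 1}" for i in range(self.n_peaks)],
                "chrom": self.peak_chroms,
                "summit": self.peak_summits,
                "n_fragments": self.peak_n_fragments,
            }
        )


def _reads_from_midpoints(
    rng: np.random.Generator,
    layout: GenomeLayout,
    midpoints: dict[str, np.ndarray],
    fragment_length: int,
) -> ReadSet:
    """Place 36 bp reads so 5'-end fragment extension recovers each midpoint."""
    half = fragment_length // 2
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        mid = midpoints[chrom]
        strand = rng.choice(np.array([1, -1], dtype=np.int8), size=len(mid))
        # plus read starts where the fragment starts; minus read ends where it ends
        s = np.where(strand > 0, mid - half, mid + half - READ_LENGTH)
        e = s + READ_LENGTH
        order = np.argsort(s, kind="stable")
        starts[chrom] = s[order]
        ends[chrom] = e[order]
        strands[chrom] = strand[order]
    return ReadSet(layout, starts, ends, strands, fragment_length)


def _background_midpoints(
    rng: np.random.Generator, layout: GenomeLayout, rate: float, fragment_length: int
) -> dict[str, np.ndarray]:
    half = fragment_length // 2
    out = {}
    for chrom in layout.chrom_names:
        L = layout.chrom_lengths[chrom]
        lo, hi = half, L - half
        if hi <= lo:
            out[chrom] = np.empty(0, dtype=np.int64)
            continue
        n = rng.poisson(rate * L)
        # midpoints kept one half-fragment from the ends so reads stay on-chromosome
        out[chrom] = np.sort(rng.integers(lo, hi, size=n))
    return out


def simulate_background(config: SimConfig) -> tuple[ReadSet, ReadSet, SimTruth]:
    """Peak-free sample and control ReadSets at the configured depth ratio."""
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    sample_mid = _background_midpoints(rng, layout, config.background_rate, config.fragment_length)
    control_mid = _background_midpoints(
        rng, layout, config.background_rate / config.depth_ratio, config.fragment_length
    )
    for chrom in layout.chrom_names:
        if len(sample_mid[chrom]) == 0:
            import logging

            logging.getLogger(__name__).warning("chromosome %s received zero reads", chrom)
    sample = _reads_from_midpoints(rng, layout, sample_mid, config.fragment_length)
    control = _reads_from_midpoints(rng, layout, control_mid, config.fragment_length)
    truth = SimTruth(config.depth_ratio, [], [], [], 0)
    return sample, control, truth


def _place_summits(
    rng: np.random.Generator, layout: GenomeLayout, n_peaks: int
) -> tuple[list[str], list[int]]:
    """Draw peak summits >= 50 kb apart and >= 25 kb from chromosome ends.

    Summits are uniform conditional on the spacing constraint: sorted
    uniforms are drawn in the spacing-reduced interval and the minimum
    gaps are added back, so dense placements (e.g. 50 peaks on 10 Mb)
    terminate without rejection loops. Chromosome allocation is
    re-drawn (up to 1000 times) if a chromosome cannot fit its share.
    """
    lengths = np.array([layout.chrom_lengths[c] for c in layout.chrom_names], dtype=float)
    usable = np.maximum(lengths - 2 * MIN_EDGE_DISTANCE, 0)
    if usable.sum() <= 0:
        raise ValueError("chromosomes too short to place peaks away from ends")
    weights = usable / usable.sum()
    for _ in range(1000):
        chrom_idx = rng.choice(len(lengths), size=n_peaks, p=weights)
        counts = np.bincount(chrom_idx, minlength=len(lengths))
        reduced = usable - (counts - 1).clip(0) * MIN_PEAK_SPACING
        if (reduced[counts > 0] <= 0).any():
            continue
        chroms: list[str] = []
        summits: list[int] = []
        for i, k in enumerate(counts):
            if k == 0:
                continue
            base = np.sort(rng.uniform(0, reduced[i], size=k))
            pos = MIN_EDGE_DISTANCE + base + np.arange(k) * MIN_PEAK_SPACING
            chroms.extend([layout.chrom_names[i]] * int(k))
            summits.extend(int(p) for p in pos)
        return chroms, summits
    raise RuntimeError("could not place peaks with the required spacing in 1000 attempts")


def peak_fragment_count(config: SimConfig) -> int:
    """Fragments per peak so the summit window mean hits the target enrichment.

    The summit 100 bp window should average peak_enrichment x the
    background window mean; background contributes one unit of that, and
    a Normal(summit, sd) midpoint lands in the window with probability
    Phi(50/sd) - Phi(-50/sd).
    """
    W = config.layout.window_size
    bg_per_window = config.background_rate * W
    frac_in_window = norm.cdf(W / 2, scale=config.peak_width_sd) - norm.cdf(
        -W / 2, scale=config.peak_width_sd
    )
    return int(round((config.peak_enrichment - 1) * bg_per_window / frac_in_window))


def simulate_peaks(config: SimConfig) -> tuple[ReadSet, ReadSet, SimTruth]:
    """Background in both samples plus spiked sample-only peaks."""
    if config.n_peaks < 1:
        raise ValueError("simulate_peaks needs n_peaks >= 1")
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    sample_mid = _background_midpoints(rng, layout, config.background_rate, config.fragment_length)
    control_mid = _background_midpoints(
        rng, layout, config.background_rate / config.depth_ratio, config.fragment_length
    )
    chroms, summits = _place_summits(rng, layout, config.n_peaks)
    n_frag = peak_fragment_count(config)
    counts: list[int] = []
    extra: dict[str, list[np.ndarray]] = {c: [] for c in layout.chrom_names}
    for chrom, summit in zip(chroms, summits):
        mids = np.rint(rng.normal(summit, config.peak_width_sd, size=n_frag)).astype(np.int64)
        L = layout.chrom_lengths[chrom]
        mids = np.clip(mids, HALF_FRAGMENT, L - HALF_FRAGMENT - 1)
        extra[chrom].append(mids)
        counts.append(len(mids))
    for chrom in layout.chrom_names:
        if extra[chrom]:
            sample_mid[chrom] = np.sort(
                np.concatenate([sample_mid[chrom], *extra[chrom]])
            )
    sample = _reads_from_midpoints(rng, layout, sample_mid, config.fragment_length)
    control = _reads_from_midpoints(rng, layout, control_mid, config.fragment_length)
    half_width = int(round(2 * config.peak_width_sd))
    truth = SimTruth(config.depth_ratio, chroms, summits, counts, half_width)
    return sample, control, truth


def write_fixture(
    directory: str | Path, sample: ReadSet, control: ReadSet, truth: SimTruth
) -> dict[str, Path]:
    """Emit BED6 reads, chrom.sizes and the truth table into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "sample": directory / "sample.bed",
        "control": directory / "control.bed",
        "chrom_sizes": directory / "chrom.sizes",
        "truth": directory / "truth.tsv",
    }
    sample.to_bed(paths["sample"], name_prefix="s")
    control.to_bed(paths["control"], name_prefix="c")
    layout = sample.layout
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom in layout.chrom_names:
            fh.write(f"{chrom}\t{layout.chrom_lengths[chrom]}\n")
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_ct_table(
    genes: dict[str, float],
    reference_gene: str = "Actb",
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    base_ct: float = 25.0,
) -> pd.DataFrame:
    """Long-format Ct table over 'sample' and 'calibrator' conditions.

    ``genes`` maps gene -> true linear fold change (sample vs
    calibrator); the reference gene is added with fold 1. Sample Ct of
    a target = calibrator Ct - log2(fold) + Normal(0, ct_noise_sd);
    calibrator and reference-gene rows carry no noise (they are the
    fixed baseline), so the ddCt inversion recovers the folds exactly
    at zero noise and within sd/sqrt(n_replicates) cycles otherwise.
    """
    if any(f <= 0 for f in genes.values()):
        raise ValueError("true fold changes must be positive")
    rng = np.random.default_rng(seed)
    all_genes = dict(genes)
    all_genes.setdefault(reference_gene, 1.0)
    rows = []
    for gene, fold in all_genes.items():
        cal_ct = base_ct + rng.uniform(-3, 3)
        for condition, shift in (("calibrator", 0.0), ("sample", -np.log2(fold))):
            noisy = condition == "sample" and gene != reference_gene and ct_noise_sd > 0
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0, ct_noise_sd) if noisy else 0.0
                rows.append(
                    {
                        "sample_id": f"{condition}_{rep}",
                        "condition": condition,
                        "gene": gene,
                        "ct": cal_ct + shift + noise,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)
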
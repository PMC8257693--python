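"""Genomic file formats and the shared coordinate model.

All coordinates are 0-based half-open (BED convention). Reads come in as
BED6, the genome layout as a UCSC ``chrom.sizes`` two-column table, and
final peaks go out as ENCODE narrowPeak (BED6+4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

WINDOW_SIZE = 100
PHASE_STEP = 25
FRAGMENT_LENGTH = 150


class FormatError(ValueError):
    """A file violated its format contract."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the window grid geometry.

    window_size is the counting window width in bp and phase_step the
    offset between successive phased grids; window_size must be a
    multiple of phase_step so the phases tile consistently.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    window_size: int = WINDOW_SIZE
    phase_step: int = PHASE_STEP

    def __post_init__(self) -> None:
        if not self.chrom_names:
            raise FormatError("genome layout has no chromosomes")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise FormatError("duplicate chromosome names in layout")
        for name in self.chrom_names:
            if self.chrom_lengths[name] <= 0:
                raise FormatError(f"non-positive length for chromosome {name!r}")
        if self.window_size <= 0 or self.phase_step <= 0:
            raise FormatError("window_size and phase_step must be positive")
        if self.window_size % self.phase_step != 0:
            raise FormatError("window_size must be divisible by phase_step")

    @property
    def phases(self) -> tuple[int, ...]:
        return tuple(range(0, self.window_size, self.phase_step))

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)


@dataclass
class ReadSet:
    """Strand-annotated aligned-read intervals, sorted by start per chromosome.

    ``starts``/``ends``/``strands`` are parallel numpy arrays per chromosome;
    strand is stored as +1 / -1 (int8).
    """

    layout: GenomeLayout
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    strands: dict[str, np.ndarray] = field(default_factory=dict)
    fragment_length: int = FRAGMENT_LENGTH

    @property
    def total_count(self) -> int:
        return int(sum(len(v) for v in self.starts.values()))

    @classmethod
    def from_records(
        cls,
        layout: GenomeLayout,
        records: Iterable[tuple[str, int, int, str]],
        fragment_length: int = FRAGMENT_LENGTH,
    ) -> "ReadSet":
        """Build a ReadSet from (chrom, start, end, strand) tuples.

        Records on chromosomes absent from the layout are dropped with a
        logged count. Invalid coordinates or strands raise FormatError.
        """
        per_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in layout.chrom_names}
        dropped = 0
        for chrom, start, end, strand in records:
            if chrom not in per_chrom:
                dropped += 1
                continue
            if not (0 <= start < end <= layout.chrom_lengths[chrom]):
                raise FormatError(
                    f"bad interval {chrom}:{start}-{end} (chrom length "
                    f"{layout.chrom_lengths[chrom]})"
                )
            if strand == "+":
                s = 1
            elif strand == "-":
                s = -1
            else:
                raise FormatError(
                    f"strand {strand!r} at {chrom}:{start}-{end}: an explicit +/- strand "
                    "is required (the strand-balance filter needs it)"
                )
            per_chrom[chrom].append((start, end, s))
        if dropped:
            log.info("dropped %d reads on chromosomes absent from the layout", dropped)
        starts, ends, strands = {}, {}, {}
        for chrom in layout.chrom_names:
            recs = per_chrom[chrom]
            if recs:
                arr = np.asarray(recs, dtype=np.int64)
                order = np.argsort(arr[:, 0], kind="stable")
                arr = arr[order]
                starts[chrom] = arr[:, 0]
                ends[chrom] = arr[:, 1]
                strands[chrom] = arr[:, 2].astype(np.int8)
            else:
                starts[chrom] = np.empty(0, dtype=np.int64)
                ends[chrom] = np.empty(0, dtype=np.int64)
                strands[chrom] = np.empty(0, dtype=np.int8)
        return cls(layout, starts, ends, strands, fragment_length)

    def to_bed(self, path: str | Path, name_prefix: str = "read") -> None:
        """Write the reads as BED6 (score 0)."""
        with open(path, "w") as fh:
            i = 0
            for chrom in self.layout.chrom_names:
                for s, e, st in zip(self.starts[chrom], self.ends[chrom], self.strands[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{name_prefix}{i}\t0\t{'+' if st > 0 else '-'}\n")
                    i += 1


@dataclass(frozen=True)
class PeakRecord:
    """One called peak in narrowPeak terms.

    signal is the NCIS-normalized log2 fold change, pvalue/qvalue are
    -log10 of the Poisson p and BH q, and summit_offset is the summit
    position relative to ``start``.
    """

    chrom: str
    start: int
    end: int
    name: str
    signal: float
    pvalue: float
    qvalue: float
    summit_offset: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty peak {self.chrom}:{self.start}-{self.end}")
        for label, v in (("signal", self.signal), ("pvalue", self.pvalue), ("qvalue", self.qvalue)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{label} must be finite and >= 0, got {v}")
        if not 0 <= self.summit_offset < self.end - self.start:
            raise ValueError("summit offset outside peak")

    @property
    def score(self) -> int:
        """narrowPeak display score: 100x the log2 fold change, capped at 1000."""
        return int(min(1000, round(100 * self.signal)))


def read_chrom_sizes(
    path: str | Path, window_size: int = WINDOW_SIZE, phase_step: int = PHASE_STEP
) -> GenomeLayout:
    """Parse a UCSC chrom.sizes table into a GenomeLayout."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name length', got {line!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable length {fields[1]!r}") from exc
            if name in lengths:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length for {name!r}")
            names.append(name)
            lengths[name] = length
    if not names:
        raise FormatError(f"{path}: empty chromosome sizes file")
    return GenomeLayout(tuple(names), lengths, window_size, phase_step)


def read_alignments(
    path: str | Path, layout: GenomeLayout, fragment_length: int = FRAGMENT_LENGTH
) -> ReadSet:
    """Read aligned reads from a BED6 file into a ReadSet.

    Requires >= 6 columns; strand must be '+' or '-'. Reads on
    chromosomes not in the layout are dropped (logged), so subsetted
    fixtures run cleanly.
    """

    def records():
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: BED6 needs >= 6 columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: unparseable coordinates") from exc
                if end <= start:
                    raise FormatError(f"{path}:{lineno}: end <= start")
                yield fields[0], start, end, fields[5]

    return ReadSet.from_records(layout, records(), fragment_length)


def write_peaks(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    """Write peaks as ENCODE narrowPeak (BED6+4), tab-delimited, LF endings.

    Peaks must be sorted by (chrom, start) and pairwise disjoint within a
    chromosome; the post-merge pipeline output always is.
    """
    prev: PeakRecord | None = None
    for pk in peaks:
        if prev is not None and prev.chrom == pk.chrom:
            if pk.start < prev.start:
                raise ValueError(f"peaks not sorted at {pk.chrom}:{pk.start}")
            if pk.start < prev.end:
                raise ValueError(
                    f"overlapping peaks {prev.chrom}:{prev.start}-{prev.end} and "
                    f"{pk.chrom}:{pk.start}-{pk.end}"
                )
        prev = pk
    with open(path, "w") as fh:
        for pk in peaks:
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.name}\t{pk.score}\t.\t"
                f"{pk.signal:.6g}\t{pk.pvalue:.6g}\t{pk.qvalue:.6g}\t{pk.summit_offset}\n"
            )


def read_peaks(path: str | Path) -> list[PeakRecord]:
    """Read a narrowPeak file written by :func:`write_peaks` (round-trip aid)."""
    out: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 10:
                raise FormatError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            out.append(
                PeakRecord(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), name=f[3],
                    signal=float(f[6]), pvalue=float(f[7]), qvalue=float(f[8]),
                    summit_offset=int(f[9]),
                )
            )
    return out
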
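import numpy as np
import pytest

from phasepeaks.coverage import FragmentIndex, count_windows
from phasepeaks.genome_io import GenomeLayout, ReadSet


@pytest.fixture
def mb_layout():
    """One 1 Mb chromosome on the standard 100/25 bp grid."""
    return GenomeLayout(("chr1",), {"chr1": 1_000_000})


@pytest.fixture
def toy_layout():
    """A 10 kb chromosome: exactly 100 phase-0 windows."""
    return GenomeLayout(("toy",), {"toy": 10_000})


def fragments_at(layout, placed):
    """FragmentIndex from {chrom: [(midpoint, strand), ...]} (strand +1/-1)."""
    mids, strands = {}, {}
    for chrom in layout.chrom_names:
        items = sorted(placed.get(chrom, []))
        mids[chrom] = np.array([m for m, _ in items], dtype=np.int64)
        strands[chrom] = np.array([s for _, s in items], dtype=np.int8)
    return FragmentIndex(layout, mids, strands)


def window_counts(layout, placed, phase=0):
    """WindowCounts built from hand-placed fragment midpoints."""
    return count_windows(fragments_at(layout, placed), layout, phase)


def readset_from(layout, records, fragment_length=150):
    """ReadSet from (chrom, start, end, '+'|'-') tuples."""
    return ReadSet.from_records(layout, records, fragment_length)
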
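import numpy as np
import pytest

from loopdiff.hic_matrix import ContactMatrix, GenomeLayout
from loopdiff.synth import ScenarioSpec


@pytest.fixture
def layout_50():
    """One 2 Mb chromosome at 40 kb bins (50 bins)."""
    return GenomeLayout((("chr1", 2_000_000),), 40_000)


@pytest.fixture
def default_spec():
    return ScenarioSpec(seed=7)


def random_matrix(layout: GenomeLayout, rng, density=0.5, max_count=50) -> ContactMatrix:
    """Random integer upper-triangle matrix on a single-chromosome layout."""
    n = layout.total_bins
    iu, ju = np.triu_indices(n)
    keep = rng.random(len(iu)) < density
    iu, ju = iu[keep], ju[keep]
    counts = rng.integers(1, max_count, size=len(iu)).astype(float)
    return ContactMatrix(layout, iu, ju, counts, float(counts.sum()))


def random_tiling(rng, length=10_000_000, bin_size=40_000, p_tad=0.6):
    """Random bin-quantized TAD intervals (start, end) tiling a chromosome."""
    tads = []
    pos = 0
    while pos < length - 2 * bin_size:
        if rng.random() < p_tad:
            w = int(rng.integers(2, 21)) * bin_size
            end = min(pos + w, length)
            if end - pos >= bin_size:
                tads.append((pos, end))
            pos = end
        else:
            pos += int(rng.integers(1, 9)) * bin_size
    return tads
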
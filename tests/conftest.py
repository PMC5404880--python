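from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from epitype.intervals import GenomicInterval, PeakSet


def random_peakset(rng: np.random.Generator, n: int, chrom_len: int,
                   max_width: int = 400, chrom: str = "chr1") -> PeakSet:
    """Uniform random intervals on a single chromosome (may overlap)."""
    ivs = []
    for _ in range(n):
        width = int(rng.integers(1, max_width))
        start = int(rng.integers(0, chrom_len - width))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return PeakSet(ivs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
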
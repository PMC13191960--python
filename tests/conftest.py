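import numpy as np
import pytest

from hicsv.genome import GenomeBins
from hicsv.intervals import GenomicInterval
from hicsv.variants import AmpliconEvent


@pytest.fixture
def small_bins() -> GenomeBins:
    """One 400 kb chromosome at 10 kb resolution (40 bins)."""
    return GenomeBins({"chr1": 400_000}, bin_size=10_000)


@pytest.fixture
def mid_event() -> AmpliconEvent:
    """A 10-bin single-segment ecDNA in the middle of chr1."""
    return AmpliconEvent(
        "e1", "s1", "ecDNA", [(GenomicInterval("chr1", 150_000, 250_000), 20.0)]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
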
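"""Fixed-width genome binning for Hi-C contact matrices."""
from __future__ import annotations

import numpy as np

from .intervals import GenomicInterval

DEFAULT_BIN_SIZE = 10_000


class GenomeBins:
    """Tiles each chromosome with fixed-width bins (last bin may be short).

    Maps between global bin indices and (chrom, start) coordinates and carries
    a boolean mask of excluded bins (unmappable / zero-coverage regions).

    Parameters
    ----------
    chromsizes
        Ordered mapping chromosome name -> length in bp.
    bin_size
        Bin width in bp; the study resolution is 10 kb.
    """

    def __init__(self, chromsizes: dict[str, int], bin_size: int = DEFAULT_BIN_SIZE):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in chromsizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self.chromsizes = dict(chromsizes)
        self.bin_size = int(bin_size)
        self.chrom_names = list(chromsizes)
        self._n_per_chrom = {
            c: -(-length // bin_size) for c, length in chromsizes.items()
        }
        self._offsets: dict[str, int] = {}
        off = 0
        for c in self.chrom_names:
            self._offsets[c] = off
            off += self._n_per_chrom[c]
        self.n_bins = off
        # chromosome id per global bin, for fast chrom lookups
        self._chrom_id = np.concatenate(
            [np.full(self._n_per_chrom[c], i, dtype=np.int32)
             for i, c in enumerate(self.chrom_names)]
        ) if off else np.empty(0, dtype=np.int32)
        self.mask = np.zeros(self.n_bins, dtype=bool)

    def n_bins_of(self, chrom: str) -> int:
        return self._n_per_chrom[chrom]

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_of(self, bin_id: int) -> str:
        return self.chrom_names[self._chrom_id[bin_id]]

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Global [lo, hi) bin-index range of a chromosome."""
        lo = self._offsets[chrom]
        return lo, lo + self._n_per_chrom[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chromsizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_interval(self, bin_id: int) -> GenomicInterval:
        chrom = self.chrom_of(bin_id)
        local = bin_id - self._offsets[chrom]
        start = local * self.bin_size
        end = min(start + self.bin_size, self.chromsizes[chrom])
        return GenomicInterval(chrom, start, end)

    def bins_overlapping(self, interval: GenomicInterval) -> np.ndarray:
        """Global indices of bins overlapping the interval, in order."""
        lo = self.bin_index(interval.chrom, interval.start)
        hi = self.bin_index(interval.chrom, interval.end - 1)
        return np.arange(lo, hi + 1)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenomeBins)
            and self.chromsizes == other.chromsizes
            and self.bin_size == other.bin_size
        )

    def __repr__(self) -> str:
        return (
            f"GenomeBins({len(self.chrom_names)} chroms, {self.n_bins} bins, "
            f"bin_size={self.bin_size})"
        )
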
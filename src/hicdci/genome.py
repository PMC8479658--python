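"""Fixed-width genomic binning shared by all contact matrices in a run.

Coordinates are 0-based half-open throughout. Bins are non-overlapping
``bin_size``-wide windows tiling each chromosome; the last bin of a
chromosome may be shorter. Every bin has a dense global ordinal obtained
by concatenating chromosomes in their stated order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["GenomeBins"]


@dataclass(frozen=True)
class GenomeBins:
    """Binning scheme: ordered chromosomes, lengths and a bin size.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers in a stable order. Names are matched by
        exact string comparison; no "chr"-prefix normalization is done.
    chrom_lengths
        Chromosome lengths in base pairs, aligned with ``chrom_names``.
    bin_size
        Bin width in base pairs (> 0).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)
    _nbins: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be positive")
        nbins = {
            c: int(-(-l // self.bin_size))
            for c, l in zip(self.chrom_names, self.chrom_lengths)
        }
        offsets, cum = {}, 0
        for c in self.chrom_names:
            offsets[c] = cum
            cum += nbins[c]
        object.__setattr__(self, "_nbins", nbins)
        object.__setattr__(self, "_offsets", offsets)

    @property
    def n_bins(self) -> int:
        """Total number of bins genome-wide."""
        return sum(self._nbins.values())

    def n_bins_chrom(self, chrom: str) -> int:
        return self._nbins[chrom]

    def offset(self, chrom: str) -> int:
        """Global ordinal of the first bin on ``chrom``."""
        return self._offsets[chrom]

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]

    def bin_index(self, chrom: str, start: int) -> int:
        """Global ordinal of the bin starting at ``start`` on ``chrom``."""
        if start % self.bin_size != 0:
            raise ValidationError(
                f"bin start {start} is not a multiple of bin_size {self.bin_size}"
            )
        local = start // self.bin_size
        if not 0 <= local < self._nbins[chrom]:
            raise ValidationError(f"bin start {start} out of range for {chrom}")
        return self._offsets[chrom] + local

    def bin_of_position(self, chrom: str, pos: int) -> int:
        """Global ordinal of the bin containing base position ``pos``."""
        local = pos // self.bin_size
        if not 0 <= local < self._nbins[chrom]:
            raise ValidationError(f"position {pos} out of range for {chrom}")
        return self._offsets[chrom] + local

    def to_frame(self) -> pd.DataFrame:
        """One row per bin: chrom, start, end (end clipped to chrom length)."""
        rows = []
        for chrom, length in zip(self.chrom_names, self.chrom_lengths):
            n = self._nbins[chrom]
            starts = np.arange(n, dtype=np.int64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def same_grid(self, other: "GenomeBins") -> bool:
        return (
            self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_size == other.bin_size
        )
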
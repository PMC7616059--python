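"""Genome assembly: chromosome names, lengths and the bead/bin layout.

All genomic coordinates in this package are 0-based, half-open, in bp.
Bead ``i`` of a chromosome covers ``[i*bin_size, (i+1)*bin_size)``; a bp
position maps to bead ``pos // bin_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosomes with lengths (bp) and a common bin size (bp)."""

    names: tuple
    lengths: dict = field(hash=False)
    bin_size: int = 100_000

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name in names:
            if name not in self.lengths:
                raise ValueError(f"missing length for chromosome {name!r}")
            length = int(self.lengths[name])
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            if length % self.bin_size != 0:
                raise ValueError(
                    f"chromosome {name!r} length {length} is not a multiple "
                    f"of bin_size {self.bin_size}"
                )

    @property
    def n_chromosomes(self) -> int:
        return len(self.names)

    def n_bins(self, chrom: str) -> int:
        return int(self.lengths[chrom]) // self.bin_size

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.names)

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def bin_offsets(self) -> dict:
        """First global bead index of each chromosome."""
        offsets, total = {}, 0
        for c in self.names:
            offsets[c] = total
            total += self.n_bins(c)
        return offsets

    def bead_index(self, chrom: str, pos) -> np.ndarray:
        """Global bead index (or array thereof) for bp positions on ``chrom``."""
        pos = np.asarray(pos)
        if np.any(pos < 0) or np.any(pos >= int(self.lengths[chrom])):
            raise ValueError(f"position outside chromosome {chrom!r}")
        return self.bin_offsets()[chrom] + pos // self.bin_size

    def bead_chromosomes(self) -> np.ndarray:
        """Per-global-bead chromosome index array."""
        return np.concatenate(
            [np.full(self.n_bins(c), i) for i, c in enumerate(self.names)]
        )

    def bead_table(self):
        """(chrom, start) for every global bead, in genome order."""
        rows = []
        for c in self.names:
            for i in range(self.n_bins(c)):
                rows.append((c, i * self.bin_size))
        return rows


def build_genome(n_chroms: int, chrom_length: int, bin_size: int) -> GenomeAssembly:
    """Uniform synthetic assembly: ``n_chroms`` chromosomes of equal length."""
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if chrom_length % bin_size != 0:
        raise ValueError(
            f"chrom_length {chrom_length} is not a multiple of bin_size {bin_size}"
        )
    names = tuple(f"chr{i + 1}" for i in range(n_chroms))
    return GenomeAssembly(names, {n: chrom_length for n in names}, bin_size)
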
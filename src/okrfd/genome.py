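"""Genome binning: fixed-width tiling of chromosomes.

Every downstream quantity (stranded counts, RFD, OEM, HMM windows) lives on
the same fixed binning of the genome, so this small container is the shared
coordinate system of the whole package.  Bins are 0-based, half-open
``[start, start + bin_size)``; the last bin of a chromosome may be shorter.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = ["GenomeBinning", "autosome_names", "read_chrom_sizes"]

_AUTOSOME_RE = re.compile(r"^(chr)?(\d+)$", re.IGNORECASE)


def autosome_names(chroms: Sequence[str]) -> list[str]:
    """Return the chromosomes that look like autosomes (``chrN`` or ``N``).

    If no name matches the convention the input is returned unchanged, so
    genomes with non-standard naming (e.g. yeast roman numerals) are kept
    whole rather than silently emptied.
    """
    auto = [c for c in chroms if _AUTOSOME_RE.match(c)]
    return auto if auto else list(chroms)


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column ``name<TAB>length`` chromosome sizes table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"malformed chrom sizes line: {line!r}")
            sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise ValueError(f"no chromosomes found in {path}")
    return sizes


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width tiling of a genome.

    Parameters
    ----------
    chrom_sizes
        Ordered mapping of chromosome name to length in bp.  Only the
        chromosomes listed here are tiled; apply :func:`autosome_names`
        beforehand to restrict to autosomes.
    bin_size
        Bin width in bp (1000 is the usual choice for mammalian OK-seq,
        50 for yeast).
    """

    chrom_sizes: Mapping[str, int]
    bin_size: int = 1000
    _n_bins: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")
        for name, length in self.chrom_sizes.items():
            if length < 1:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        object.__setattr__(self, "chrom_sizes", dict(self.chrom_sizes))
        object.__setattr__(
            self,
            "_n_bins",
            {c: math.ceil(l / self.bin_size) for c, l in self.chrom_sizes.items()},
        )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    @property
    def total_bins(self) -> int:
        return sum(self._n_bins.values())

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin containing 0-based position ``pos``."""
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise IndexError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def bin_start(self, chrom: str, idx: int) -> int:
        return idx * self.bin_size

    def bin_end(self, chrom: str, idx: int) -> int:
        """End coordinate of bin ``idx`` (clipped at the chromosome end)."""
        return min((idx + 1) * self.bin_size, self.chrom_sizes[chrom])

    def iter_bins(self, chrom: str) -> Iterator[tuple[int, int]]:
        for i in range(self.n_bins(chrom)):
            yield self.bin_start(chrom, i), self.bin_end(chrom, i)

    def subset(self, chroms: Sequence[str]) -> "GenomeBinning":
        missing = [c for c in chroms if c not in self.chrom_sizes]
        if missing:
            raise KeyError(f"chromosomes not in binning: {missing}")
        return GenomeBinning({c: self.chrom_sizes[c] for c in chroms}, self.bin_size)

    def compatible_with(self, other: "GenomeBinning") -> bool:
        return (
            self.bin_size == other.bin_size
            and dict(self.chrom_sizes) == dict(other.chrom_sizes)
        )
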
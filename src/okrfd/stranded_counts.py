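"""Strand-split binned read counting from coordinate-sorted BAM files.

Okazaki fragments mapping to the Crick strand come from rightward-moving
forks and fragments on the Watson strand from leftward-moving forks, so the
per-bin Watson/Crick counts ``(W, C)`` are the primitive from which RFD,
the HMM segmentation and OEM are all derived.

Fragments are assigned to a single bin by the 5'-most aligned coordinate of
the fragment (read 1 for paired data).  A read (or read 1) aligned to the
reference forward strand counts to Watson, reverse strand to Crick;
``flip_strands`` inverts this for library chemistries with the opposite
strand/fork-direction correspondence.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pysam

from .errors import InputError
from .genome import GenomeBinning

__all__ = [
    "StrandedBinCounts",
    "detect_layout",
    "count_stranded_reads",
    "write_counts",
    "read_counts",
]

Layout = Literal["single", "paired"]
PairMode = Literal["all_unique", "paired", "properly_paired"]

_LAYOUT_SAMPLE = 10_000


@dataclass
class StrandedBinCounts:
    """Per-chromosome Watson/Crick read counts on a fixed genome binning."""

    binning: GenomeBinning
    watson: dict[str, np.ndarray]
    crick: dict[str, np.ndarray]
    layout: Layout = "single"
    mode: PairMode = "all_unique"
    n_counted: int = field(default=0)

    def __post_init__(self) -> None:
        for chrom in self.binning.chroms:
            nb = self.binning.n_bins(chrom)
            for arrs in (self.watson, self.crick):
                if chrom not in arrs:
                    arrs[chrom] = np.zeros(nb, dtype=np.int64)
                arrs[chrom] = np.asarray(arrs[chrom], dtype=np.int64)
                if arrs[chrom].shape != (nb,):
                    raise ValueError(
                        f"count array for {chrom} has shape {arrs[chrom].shape}, "
                        f"expected ({nb},)"
                    )
                if (arrs[chrom] < 0).any():
                    raise ValueError(f"negative counts on {chrom}")
        if not self.n_counted:
            self.n_counted = int(self.total_reads)

    @property
    def total_reads(self) -> int:
        return int(
            sum(a.sum() for a in self.watson.values())
            + sum(a.sum() for a in self.crick.values())
        )

    def swapped(self) -> "StrandedBinCounts":
        """Watson/Crick swap; negates RFD and OEM exactly."""
        return StrandedBinCounts(
            binning=self.binning,
            watson={c: a.copy() for c, a in self.crick.items()},
            crick={c: a.copy() for c, a in self.watson.items()},
            layout=self.layout,
            mode=self.mode,
            n_counted=self.n_counted,
        )


def _open_indexed(path: str) -> pysam.AlignmentFile:
    if not os.path.exists(path):
        raise InputError(f"alignment file not found: {path}")
    try:
        af = pysam.AlignmentFile(path, "rb")
    except (ValueError, OSError) as exc:
        raise InputError(f"cannot read alignment file {path}: {exc}") from exc
    if (af.header.to_dict().get("HD") or {}).get("SO") not in (None, "coordinate"):
        raise InputError(f"{path} is not coordinate-sorted")
    if not af.has_index():
        af.close()
        raise InputError(f"{path} has no index (.bai); run samtools index")
    return af


def detect_layout(alignment_file: str) -> Layout:
    """Classify a BAM as single- or paired-end.

    Inspects the first 10,000 primary records; any read with the paired
    flag set classifies the file as paired-end.
    """
    with _open_indexed(alignment_file) as af:
        seen = 0
        for rec in af.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_paired:
                return "paired"
            seen += 1
            if seen >= _LAYOUT_SAMPLE:
                break
    return "single"


def _fragment_keep(rec: pysam.AlignedSegment, layout: Layout, mode: PairMode) -> bool:
    """Does this record represent a countable fragment?

    Paired layout counts each fragment once through read 1.
    """
    if layout == "single" or not rec.is_paired:
        return True
    if not rec.is_read1:
        return False
    if mode == "paired":
        return not rec.mate_is_unmapped
    if mode == "properly_paired":
        return rec.is_proper_pair
    return True  # all_unique


def count_stranded_reads(
    alignment_file: str,
    binning: GenomeBinning,
    mode: PairMode = "all_unique",
    min_mapq: int = 10,
    keep_duplicates: bool = False,
    flip_strands: bool = False,
) -> StrandedBinCounts:
    """Accumulate Watson/Crick fragment counts per genome bin.

    Secondary and supplementary alignments are always excluded; duplicates
    are excluded unless ``keep_duplicates``; alignments below ``min_mapq``
    are excluded.  Chromosomes absent from ``binning`` are skipped.
    """
    layout = detect_layout(alignment_file)
    watson = {c: np.zeros(binning.n_bins(c), dtype=np.int64) for c in binning.chroms}
    crick = {c: np.zeros(binning.n_bins(c), dtype=np.int64) for c in binning.chroms}
    n_counted = 0
    with _open_indexed(alignment_file) as af:
        for chrom in binning.chroms:
            if chrom not in af.references:
                continue
            bam_len = af.get_reference_length(chrom)
            if bam_len != binning.chrom_sizes[chrom]:
                raise InputError(
                    f"contig {chrom}: BAM length {bam_len} != chrom sizes "
                    f"{binning.chrom_sizes[chrom]}"
                )
            w, c = watson[chrom], crick[chrom]
            for rec in af.fetch(chrom):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.is_duplicate and not keep_duplicates:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                if not _fragment_keep(rec, layout, mode):
                    continue
                # 5'-most aligned coordinate of the fragment
                pos = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
                if not 0 <= pos < binning.chrom_sizes[chrom]:
                    continue
                is_watson = not rec.is_reverse
                if flip_strands:
                    is_watson = not is_watson
                (w if is_watson else c)[pos // binning.bin_size] += 1
                n_counted += 1
    if n_counted == 0:
        warnings.warn(f"no reads passed filters in {alignment_file}", stacklevel=2)
    return StrandedBinCounts(
        binning=binning,
        watson=watson,
        crick=crick,
        layout=layout,
        mode=mode,
        n_counted=n_counted,
    )


def _write_bedgraph(path: str, binning: GenomeBinning, arrays: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tcount\n")
        for chrom in binning.chroms:
            arr = arrays[chrom]
            for idx in np.flatnonzero(arr):
                fh.write(
                    f"{chrom}\t{binning.bin_start(chrom, idx)}\t"
                    f"{binning.bin_end(chrom, idx)}\t{arr[idx]}\n"
                )


def write_counts(counts: StrandedBinCounts, out_prefix: str) -> tuple[str, str]:
    """Persist counts as one bedGraph per strand plus a sizes sidecar.

    Returns the two bedGraph paths.  ``read_counts`` inverts this exactly.
    """
    os.makedirs(os.path.dirname(os.path.abspath(out_prefix)), exist_ok=True)
    w_path = f"{out_prefix}.watson.bedgraph"
    c_path = f"{out_prefix}.crick.bedgraph"
    _write_bedgraph(w_path, counts.binning, counts.watson)
    _write_bedgraph(c_path, counts.binning, counts.crick)
    with open(f"{out_prefix}.chrom.sizes", "w") as fh:
        for chrom, length in counts.binning.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
        fh.write(f"#bin_size\t{counts.binning.bin_size}\n")
    return w_path, c_path


def read_counts(prefix: str, binning: GenomeBinning | None = None) -> StrandedBinCounts:
    """Load counts written by :func:`write_counts`."""
    if binning is None:
        sizes: dict[str, int] = {}
        bin_size = None
        sizes_path = f"{prefix}.chrom.sizes"
        if not os.path.exists(sizes_path):
            raise InputError(f"missing sizes sidecar {sizes_path}; pass a binning")
        with open(sizes_path) as fh:
            for line in fh:
                name, value = line.split("\t")
                if name == "#bin_size":
                    bin_size = int(value)
                else:
                    sizes[name] = int(value)
        if bin_size is None:
            raise InputError(f"{sizes_path} lacks a #bin_size record")
        binning = GenomeBinning(sizes, bin_size)
    watson = {c: np.zeros(binning.n_bins(c), dtype=np.int64) for c in binning.chroms}
    crick = {c: np.zeros(binning.n_bins(c), dtype=np.int64) for c in binning.chroms}
    for arrays, suffix in ((watson, "watson"), (crick, "crick")):
        path = f"{prefix}.{suffix}.bedgraph"
        if not os.path.exists(path):
            raise InputError(f"missing counts file {path}")
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                chrom, start, _end, count = line.split("\t")
                if chrom in arrays:
                    arrays[chrom][int(start) // binning.bin_size] = int(count)
    return StrandedBinCounts(binning=binning, watson=watson, crick=crick)
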
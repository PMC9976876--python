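"""Replication fork directionality (RFD) tracks.

RFD = (C - W) / (C + W) per window, where C and W are the Crick- and
Watson-strand read counts.  RFD ranges from -1 (all leftward-moving forks)
to +1 (all rightward-moving forks); 0 means equal proportions.  Smoothing
aggregates counts over ``span_bins`` adjacent bins centred on each bin and
takes the ratio of the sums, so deeper bins weigh more and the read-count
masking rule downstream applies to the same aggregated totals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError, UndefinedResultError
from .genome import GenomeBinning
from .stranded_counts import StrandedBinCounts

__all__ = ["RFDTrack", "compute_rfd", "correlate_tracks", "export_track", "load_bedgraph_track"]


@dataclass
class RFDTrack:
    """Per-window RFD values in [-1, +1], NaN where the window has no reads.

    ``window_watson``/``window_crick`` keep the aggregated per-window counts
    for the downstream low-coverage masking rule.  Windows are centred on
    their index bin and stepped by one bin; chromosome-edge windows are
    truncated to the available bins.
    """

    binning: GenomeBinning
    values: dict[str, np.ndarray]
    span_bins: int
    window_watson: dict[str, np.ndarray]
    window_crick: dict[str, np.ndarray]

    def window_totals(self, chrom: str) -> np.ndarray:
        return self.window_watson[chrom] + self.window_crick[chrom]

    def negated(self) -> "RFDTrack":
        """Strand-swapped track: W and C exchanged, every value negated."""
        return RFDTrack(
            binning=self.binning,
            values={c: -v for c, v in self.values.items()},
            span_bins=self.span_bins,
            window_watson={c: a.copy() for c, a in self.window_crick.items()},
            window_crick={c: a.copy() for c, a in self.window_watson.items()},
        )


def _sliding_sum(arr: np.ndarray, span: int) -> np.ndarray:
    """Sum of ``span`` bins centred on each index, truncated at the edges."""
    if span == 1:
        return arr.astype(np.int64)
    return np.convolve(arr, np.ones(span, dtype=np.int64), mode="same")


def compute_rfd(counts: StrandedBinCounts, span_bins: int = 15) -> RFDTrack:
    """Compute the RFD track at the given smoothing span.

    ``span_bins`` must be odd so windows centre on a bin; span 1 is the raw
    per-bin track.  RFD is missing (NaN) exactly where the aggregated
    window has zero reads on both strands.
    """
    if span_bins < 1 or span_bins % 2 == 0:
        raise ParameterError(f"span_bins must be odd and >= 1, got {span_bins}")
    values: dict[str, np.ndarray] = {}
    win_w: dict[str, np.ndarray] = {}
    win_c: dict[str, np.ndarray] = {}
    for chrom in counts.binning.chroms:
        w = _sliding_sum(counts.watson[chrom], span_bins)
        c = _sliding_sum(counts.crick[chrom], span_bins)
        total = w + c
        with np.errstate(invalid="ignore", divide="ignore"):
            rfd = (c - w) / total
        rfd[total == 0] = np.nan
        values[chrom] = rfd
        win_w[chrom] = w
        win_c[chrom] = c
    return RFDTrack(
        binning=counts.binning,
        values=values,
        span_bins=span_bins,
        window_watson=win_w,
        window_crick=win_c,
    )


def correlate_tracks(a: RFDTrack, b: RFDTrack) -> tuple[float, int]:
    """Pearson correlation over positions non-missing in both tracks.

    Returns ``(r, n)`` where n is the number of paired positions.
    """
    if not a.binning.compatible_with(b.binning) or a.span_bins != b.span_bins:
        raise ParameterError("tracks have different binning or span")
    xs, ys = [], []
    for chrom in a.binning.chroms:
        va, vb = a.values[chrom], b.values[chrom]
        ok = ~np.isnan(va) & ~np.isnan(vb)
        xs.append(va[ok])
        ys.append(vb[ok])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 2:
        raise UndefinedResultError(
            f"correlation needs >= 2 shared non-missing positions, got {x.size}"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return r, int(x.size)


def _iter_records(track: RFDTrack):
    for chrom in track.binning.chroms:
        vals = track.values[chrom]
        for idx in np.flatnonzero(~np.isnan(vals)):
            yield (
                chrom,
                track.binning.bin_start(chrom, idx),
                track.binning.bin_end(chrom, idx),
                float(vals[idx]),
            )


def export_track(track: RFDTrack, fmt: str, path: str) -> str:
    """Write the track as bedGraph or bigWig (one record per defined window)."""
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
    if fmt == "bedGraph":
        try:
            fh = open(path, "w")
        except OSError as exc:
            raise InputError(f"cannot write {path}: {exc}") from exc
        with fh:
            fh.write(f"#span_bins={track.span_bins} bin_size={track.binning.bin_size}\n")
            for chrom, start, end, value in _iter_records(track):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")
    elif fmt == "bigWig":
        import pyBigWig

        bw = pyBigWig.open(path, "w")
        bw.addHeader(
            [(c, int(l)) for c, l in track.binning.chrom_sizes.items()]
        )
        for chrom in track.binning.chroms:
            vals = track.values[chrom]
            idx = np.flatnonzero(~np.isnan(vals))
            if idx.size == 0:
                continue
            bw.addEntries(
                [chrom] * idx.size,
                [track.binning.bin_start(chrom, i) for i in idx],
                ends=[track.binning.bin_end(chrom, i) for i in idx],
                values=[float(vals[i]) for i in idx],
            )
        bw.close()
    else:
        raise ParameterError(f"unknown track format {fmt!r}")
    return path


def load_bedgraph_track(path: str, binning: GenomeBinning, span_bins: int = 1) -> RFDTrack:
    """Reload a bedGraph written by :func:`export_track`.

    Window counts are not recoverable from a value track and are set to a
    nominal 1 read wherever a value is present (0 where missing), so that
    presence/absence survives the round trip.
    """
    values = {c: np.full(binning.n_bins(c), np.nan) for c in binning.chroms}
    if not os.path.exists(path):
        raise InputError(f"track file not found: {path}")
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("track") or not line.strip():
                continue
            chrom, start, _end, value = line.split("\t")
            if chrom in values:
                values[chrom][int(start) // binning.bin_size] = float(value)
    present = {
        c: (~np.isnan(v)).astype(np.int64) for c, v in values.items()
    }
    return RFDTrack(
        binning=binning,
        values=values,
        span_bins=span_bins,
        window_watson={c: np.zeros_like(p) for c, p in present.items()},
        window_crick=present,
    )
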
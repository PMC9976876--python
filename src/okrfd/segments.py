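"""Segments from the decoded HMM path: initiation zones, termination zones
and flat (high fork-polarity) regions, with efficiency and confidence.

A segment is a maximal run of one HMM state on the window grid.  Its
efficiency is half the RFD rise across it, ΔRFD_segment =
(RFD_end − RFD_start)/2, with the flanking RFD values computed from read
counts in 5 kb windows around the segment extremities; for an initiation
zone this estimates the zone's firing efficiency.  Confidence is the mean
posterior probability of the assigned state over member windows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .genome import GenomeBinning
from .hmm import MISSING, STATES, DeltaRFDTrack
from .rfd import RFDTrack
from .stranded_counts import StrandedBinCounts

__all__ = [
    "Segment",
    "SegmentSet",
    "extract_segments",
    "segment_efficiency",
    "annotate_efficiency",
    "retain_reproducible",
    "nearest_feature_distance",
    "high_rfd_regions",
    "filter_segments",
    "call_zones",
    "read_bed",
    "write_segments",
]


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # bp, 0-based half-open
    end: int
    state: str  # Up | Down | Flat1 | Flat2
    efficiency: float = float("nan")
    confidence: float = float("nan")
    n_windows: int = 0

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentSet:
    """Sorted, non-overlapping state segments of one decoding run."""

    binning: GenomeBinning
    segments: list[Segment]
    quantile_boundaries: np.ndarray | None = None

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def by_state(self, state: str) -> "SegmentSet":
        if state not in STATES:
            raise ParameterError(f"unknown state {state!r}")
        return SegmentSet(
            self.binning,
            [s for s in self.segments if s.state == state],
            self.quantile_boundaries,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "state": s.state,
                    "efficiency": s.efficiency,
                    "confidence": s.confidence,
                    "n_windows": s.n_windows,
                }
                for s in self.segments
            ]
        )


def extract_segments(
    paths: dict[str, np.ndarray],
    posteriors: dict[str, np.ndarray],
    delta: DeltaRFDTrack,
    symbols: dict[str, np.ndarray] | None = None,
) -> SegmentSet:
    """Collapse the decoded path into maximal same-state segments.

    Segment coordinates span from the start of the first member window's
    centre bin to the end of the last one.  Runs consisting entirely of
    MISSING windows are dropped (nothing was observed there).
    """
    binning = delta.binning
    segments: list[Segment] = []
    for chrom in binning.chroms:
        path = paths[chrom]
        if path.size == 0:
            continue
        post = posteriors[chrom]
        observed = (
            symbols[chrom] != MISSING if symbols is not None else ~delta.mask[chrom]
        )
        # boundaries of maximal runs
        change = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [path.size]])
        for a, b in zip(starts, ends):
            if not observed[a:b].any():
                continue
            state_idx = int(path[a])
            segments.append(
                Segment(
                    chrom=chrom,
                    start=binning.bin_start(chrom, int(a)),
                    end=binning.bin_end(chrom, int(b - 1)),
                    state=STATES[state_idx],
                    confidence=float(np.mean(post[a:b, state_idx])),
                    n_windows=int(b - a),
                )
            )
    return SegmentSet(binning=binning, segments=segments)


def _flank_rfd(counts: StrandedBinCounts, chrom: str, pos: int, flank_bp: int) -> float:
    """RFD of the flank_bp window centred on ``pos`` (NaN if no reads)."""
    binning = counts.binning
    lo = max(0, pos - flank_bp // 2)
    hi = min(binning.chrom_sizes[chrom], pos + flank_bp // 2)
    b0 = lo // binning.bin_size
    b1 = (hi - 1) // binning.bin_size + 1 if hi > lo else b0
    w = int(counts.watson[chrom][b0:b1].sum())
    c = int(counts.crick[chrom][b0:b1].sum())
    if w + c == 0:
        return float("nan")
    return (c - w) / (c + w)


def segment_efficiency(
    segment: Segment, counts: StrandedBinCounts, flank_bp: int = 5000
) -> float:
    """ΔRFD_segment = (RFD_end − RFD_start)/2 from 5 kb flanks.

    Missing (NaN) when either flank window contains no reads.
    """
    rfd_start = _flank_rfd(counts, segment.chrom, segment.start, flank_bp)
    rfd_end = _flank_rfd(counts, segment.chrom, segment.end, flank_bp)
    return (rfd_end - rfd_start) / 2.0


def annotate_efficiency(
    segset: SegmentSet, counts: StrandedBinCounts, flank_bp: int = 5000
) -> SegmentSet:
    """Return a copy of the set with per-segment efficiencies filled in."""
    return SegmentSet(
        segset.binning,
        [
            replace(s, efficiency=segment_efficiency(s, counts, flank_bp))
            for s in segset.segments
        ],
        segset.quantile_boundaries,
    )


def retain_reproducible(
    set_a: SegmentSet,
    set_b: SegmentSet,
    state: str,
    criterion: Literal["overlap", "center_distance"] = "overlap",
    max_center_distance: int = 30_000,
) -> SegmentSet:
    """Segments of the reference replicate supported by the second one.

    Keeps segments of ``set_a`` with >= 1 bp overlap (or centre distance
    <= ``max_center_distance``) with a same-state segment of ``set_b``.
    """
    a = set_a.by_state(state)
    b = set_b.by_state(state)
    b_by_chrom: dict[str, list[Segment]] = {}
    for s in b:
        b_by_chrom.setdefault(s.chrom, []).append(s)
    kept = []
    for s in a:
        for t in b_by_chrom.get(s.chrom, []):
            if criterion == "overlap":
                if min(s.end, t.end) > max(s.start, t.start):
                    kept.append(s)
                    break
            else:
                if abs(s.center - t.center) <= max_center_distance:
                    kept.append(s)
                    break
    return SegmentSet(set_a.binning, kept, set_a.quantile_boundaries)


def nearest_feature_distance(
    segments: SegmentSet | Iterable[Segment],
    features: pd.DataFrame,
    overlap_threshold: int = 2000,
) -> pd.DataFrame:
    """Centre-to-centre distance from each segment to its nearest feature.

    ``features`` is a BED-like frame (chrom/start/end).  Returns a frame
    with the segment coordinates, the distance in bp (NaN when the
    chromosome carries no feature) and an ``overlap`` flag true when the
    distance is below ``overlap_threshold``.
    """
    segs = list(segments)
    centers_by_chrom = {
        chrom: np.sort((grp["start"].to_numpy() + grp["end"].to_numpy()) / 2.0)
        for chrom, grp in features.groupby("chrom")
    }
    rows = []
    for s in segs:
        centers = centers_by_chrom.get(s.chrom)
        if centers is None or centers.size == 0:
            dist = float("nan")
        else:
            i = np.searchsorted(centers, s.center)
            cand = centers[max(0, i - 1): i + 1]
            dist = float(np.min(np.abs(cand - s.center)))
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "state": s.state,
                "distance": dist,
                "overlap": bool(dist <= overlap_threshold) if np.isfinite(dist) else False,
            }
        )
    return pd.DataFrame(rows)


def high_rfd_regions(
    segset: SegmentSet, track: RFDTrack, min_abs_rfd: float = 0.5
) -> SegmentSet:
    """Flat-state runs with high fork polarity.

    Flat1/Flat2 segments whose mean |RFD| over member windows exceeds
    ``min_abs_rfd`` are candidate regions replicated by long-travelling
    unidirectional forks.
    """
    kept = []
    for s in segset:
        if s.state not in ("Flat1", "Flat2"):
            continue
        b0 = s.start // track.binning.bin_size
        b1 = (s.end - 1) // track.binning.bin_size + 1
        vals = track.values[s.chrom][b0:b1]
        vals = vals[~np.isnan(vals)]
        if vals.size and float(np.mean(np.abs(vals))) > min_abs_rfd:
            kept.append(s)
    return SegmentSet(segset.binning, kept, segset.quantile_boundaries)


def filter_segments(
    segset: SegmentSet,
    min_abs_efficiency: float = 0.1,
    min_length_bp: int = 0,
    states: tuple[str, ...] = ("Up", "Down"),
) -> SegmentSet:
    """Drop Up/Down segments whose |ΔRFD_segment| is within counting noise.

    A real initiation or termination zone carries an RFD step bounded below
    by its firing (or termination) efficiency, while the HMM also emits
    occasional short runs whose rise is pure shot noise (|ΔRFD_segment| of
    order 1/sqrt(flank reads)).  The default floor of 0.1 is about twice
    the flank noise at typical OK-seq depth.  Flat segments pass through
    untouched; segments with missing efficiency are dropped for the
    filtered states.
    """
    kept = []
    for s in segset:
        if s.state not in states:
            kept.append(s)
            continue
        if s.length < min_length_bp:
            continue
        if not np.isfinite(s.efficiency) or abs(s.efficiency) < min_abs_efficiency:
            continue
        kept.append(s)
    return SegmentSet(segset.binning, kept, segset.quantile_boundaries)


def call_zones(
    counts: StrandedBinCounts,
    span_bins: int = 15,
    min_reads: int = 30,
    k: int = 5,
    params=None,
    flank_bp: int = 5000,
    min_abs_efficiency: float = 0.1,
):
    """Full zone-calling chain: RFD -> ΔRFD -> quantile symbols -> HMM ->
    efficiency-annotated, noise-filtered segments.

    Returns ``(SegmentSet, RFDTrack)``; the track is the smoothed RFD the
    HMM ran on.  ``min_abs_efficiency=0`` disables the noise filter.
    """
    from .hmm import HMMParameters, compute_delta_rfd, decode_states, symbolize_quantiles
    from .rfd import compute_rfd

    track = compute_rfd(counts, span_bins)
    delta = compute_delta_rfd(track, min_reads=min_reads)
    symbols = symbolize_quantiles(delta, k=k)
    if params is None:
        params = HMMParameters.default()
    paths, posteriors, _ = decode_states(symbols, params)
    segset = extract_segments(paths, posteriors, delta, symbols.symbols)
    segset.quantile_boundaries = symbols.quantile_boundaries
    segset = annotate_efficiency(segset, counts, flank_bp)
    if min_abs_efficiency > 0:
        segset = filter_segments(segset, min_abs_efficiency)
    return segset, track


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED file (>= 3 columns) into chrom/start/end[/name/score/strand]."""
    if not os.path.exists(path):
        raise InputError(f"BED file not found: {path}")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    )
    if df.shape[1] < 3:
        raise InputError(f"{path}: BED needs >= 3 columns")
    df = df.iloc[:, :6]
    df.columns = names[: df.shape[1]]
    return df


def write_segments(segset: SegmentSet, out_prefix: str) -> dict[str, str]:
    """Export BEDs per state class plus a full TSV.

    BED score = round(1000 * |efficiency|) clipped to [0, 1000]; strand ".".
    The TSV carries efficiency, confidence, n_windows and the ΔRFD quantile
    boundaries in its header.
    """
    os.makedirs(os.path.dirname(os.path.abspath(out_prefix)), exist_ok=True)
    paths: dict[str, str] = {}
    classes = {"IZ": ("Up",), "TZ": ("Down",), "flats": ("Flat1", "Flat2")}
    for label, states in classes.items():
        path = f"{out_prefix}.{label}.bed"
        with open(path, "w") as fh:
            for i, s in enumerate(x for x in segset if x.state in states):
                eff = 0.0 if not np.isfinite(s.efficiency) else abs(s.efficiency)
                score = int(min(1000, round(1000 * eff)))
                fh.write(
                    f"{s.chrom}\t{s.start}\t{s.end}\t{label}_{i + 1}\t{score}\t.\n"
                )
        paths[label] = path
    tsv = f"{out_prefix}.segments.tsv"
    with open(tsv, "w") as fh:
        if segset.quantile_boundaries is not None:
            bounds = ",".join(f"{b:.6g}" for b in segset.quantile_boundaries)
            fh.write(f"#quantile_boundaries={bounds}\n")
        segset.to_frame().to_csv(fh, sep="\t", index=False)
    paths["tsv"] = tsv
    return paths
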
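"""Metagene matrices: a genomic signal sampled around many anchors.

Rows are input regions (order preserved), columns are positions relative to
the anchor — fixed bp offsets in ``reference_point`` mode, or scaled body
fractions flanked by native-resolution margins in ``scale_regions`` mode.
Regions on the minus strand are reversed so columns always run 5'→3'
relative to the region.  Values are sampled from the exported track windows
at the track's bin size; missing track data propagates as NaN and is never
fabricated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ParameterError
from .rfd import RFDTrack

__all__ = ["MetageneMatrix", "build_matrix", "mean_profile", "sort_rows", "write_matrix"]

Mode = Literal["reference_point", "scale_regions"]
Anchor = Literal["center", "start", "end"]


@dataclass
class MetageneMatrix:
    values: np.ndarray  # (n_regions, n_cols)
    columns: np.ndarray  # bp offsets (reference_point) or column labels
    regions: pd.DataFrame  # the input regions, row-aligned
    mode: Mode
    anchor: Anchor
    upstream_bp: int
    downstream_bp: int
    bin_size: int
    body_bins: int = 0

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def _anchor_position(row: pd.Series, anchor: Anchor, minus: bool) -> float:
    # anchors are strand-aware: "start" is the 5' end of the region
    if anchor == "center":
        return (row["start"] + row["end"]) / 2
    if anchor == "start":
        return row["end"] if minus else row["start"]
    return row["start"] if minus else row["end"]


def _sample(track: RFDTrack, chrom: str, positions: np.ndarray) -> np.ndarray:
    vals = track.values[chrom]
    size = track.binning.chrom_sizes[chrom]
    out = np.full(positions.size, np.nan)
    ok = (positions >= 0) & (positions < size)
    idx = (positions[ok] // track.binning.bin_size).astype(np.int64)
    out[ok] = vals[idx]
    return out


def build_matrix(
    track: RFDTrack,
    regions: pd.DataFrame,
    mode: Mode = "reference_point",
    anchor: Anchor = "center",
    upstream_bp: int = 50_000,
    downstream_bp: int = 50_000,
    body_bins: int = 100,
) -> MetageneMatrix:
    """Sample a track around (or across) each region.

    ``regions`` is a BED-like frame (chrom/start/end, optional strand in
    column 6; missing strand means "+").
    """
    if mode not in ("reference_point", "scale_regions"):
        raise ParameterError(f"unknown mode {mode!r}")
    bs = track.binning.bin_size
    n_up = upstream_bp // bs
    n_down = downstream_bp // bs
    if mode == "reference_point":
        offsets = np.arange(-n_up, n_down + 1) * bs
        columns = offsets
        n_cols = offsets.size
    else:
        columns = np.concatenate(
            [
                np.arange(-n_up, 0) * bs,
                np.arange(body_bins),  # body fraction slots
                np.arange(1, n_down + 1) * bs,
            ]
        )
        n_cols = n_up + body_bins + n_down
    values = np.full((len(regions), n_cols), np.nan)
    strands = (
        regions["strand"] if "strand" in regions.columns else pd.Series("+", index=regions.index)
    )
    for i, (_, row) in enumerate(regions.iterrows()):
        chrom = row["chrom"]
        if chrom not in track.values:
            warnings.warn(f"region on {chrom} absent from track; row is missing", stacklevel=2)
            continue
        minus = strands.iloc[i] == "-"
        if mode == "reference_point":
            a = _anchor_position(row, anchor, minus)
            positions = a - offsets if minus else a + offsets
            values[i] = _sample(track, chrom, positions.astype(np.int64))
        else:
            start, end = int(row["start"]), int(row["end"])
            up_pos = np.arange(start - n_up * bs, start, bs)
            down_pos = np.arange(end, end + n_down * bs, bs)
            body = np.full(body_bins, np.nan)
            b0, b1 = start // bs, max(start // bs + 1, -(-end // bs))
            track_vals = track.values[chrom][b0:b1]
            edges = np.linspace(0, b1 - b0, body_bins + 1)
            for j in range(body_bins):
                lo, hi = int(np.floor(edges[j])), int(np.ceil(edges[j + 1]))
                chunk = track_vals[lo:hi]
                chunk = chunk[~np.isnan(chunk)]
                if chunk.size:
                    body[j] = float(chunk.mean())
            row_vals = np.concatenate(
                [
                    _sample(track, chrom, up_pos),
                    body,
                    _sample(track, chrom, down_pos),
                ]
            )
            values[i] = row_vals[::-1] if minus else row_vals
    return MetageneMatrix(
        values=values,
        columns=columns,
        regions=regions.reset_index(drop=True),
        mode=mode,
        anchor=anchor,
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        bin_size=bs,
        body_bins=body_bins if mode == "scale_regions" else 0,
    )


def mean_profile(matrix: MetageneMatrix) -> pd.DataFrame:
    """Per-column mean, standard error and non-missing count.

    Columns with no data get NaN mean/SE; single observations get NaN SE.
    """
    if matrix.n_regions < 1:
        raise ParameterError("matrix has no rows")
    vals = matrix.values
    n = np.sum(~np.isnan(vals), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
    mean[n == 0] = np.nan
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame({"position": matrix.columns, "mean": mean, "se": se, "n": n})


def sort_rows(
    matrix: MetageneMatrix,
    key: Literal["region_length", "region_score", "mean_signal"] = "region_length",
    descending: bool = True,
) -> MetageneMatrix:
    """Stable sort of rows by region length, BED score or row mean signal."""
    if key == "region_length":
        keys = (matrix.regions["end"] - matrix.regions["start"]).to_numpy(float)
    elif key == "region_score":
        if "score" not in matrix.regions.columns:
            raise ParameterError("regions carry no score column")
        keys = matrix.regions["score"].to_numpy(float)
    elif key == "mean_signal":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            keys = np.nanmean(matrix.values, axis=1)
        keys = np.where(np.isnan(keys), -np.inf, keys)
    else:
        raise ParameterError(f"unknown sort key {key!r}")
    order = np.argsort(-keys if descending else keys, kind="stable")
    return MetageneMatrix(
        values=matrix.values[order],
        columns=matrix.columns,
        regions=matrix.regions.iloc[order].reset_index(drop=True),
        mode=matrix.mode,
        anchor=matrix.anchor,
        upstream_bp=matrix.upstream_bp,
        downstream_bp=matrix.downstream_bp,
        bin_size=matrix.bin_size,
        body_bins=matrix.body_bins,
    )


def write_matrix(matrix: MetageneMatrix, path: str) -> str:
    """TSV with a JSON header line carrying mode/anchor/bounds, so any
    plotting layer can reproduce the heatmap."""
    header = {
        "mode": matrix.mode,
        "anchor": matrix.anchor,
        "upstream_bp": matrix.upstream_bp,
        "downstream_bp": matrix.downstream_bp,
        "bin_size": matrix.bin_size,
        "body_bins": matrix.body_bins,
        "n_regions": matrix.n_regions,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        cols = "\t".join(str(c) for c in matrix.columns)
        fh.write(f"region\t{cols}\n")
        names = (
            matrix.regions["name"]
            if "name" in matrix.regions.columns
            else pd.Series(
                [f"region_{i + 1}" for i in range(matrix.n_regions)]
            )
        )
        for i in range(matrix.n_regions):
            row = "\t".join(
                "nan" if np.isnan(v) else f"{v:.4f}" for v in matrix.values[i]
            )
            fh.write(f"{names.iloc[i]}\t{row}\n")
    return path
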
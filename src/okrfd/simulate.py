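"""Synthetic replication programs with known ground truth.

A replication program is a set of origins, each with a position, a firing
efficiency e ∈ (0, 1] and a transition half-width.  Okazaki fragments from
rightward-moving forks map to the Crick strand, so the true RFD rises by
2e across an origin's initiation zone (from −e to +e for an isolated
origin) and falls back between origins where converging forks terminate.

Two truth models are provided.  ``piecewise_linear`` is a stylized analytic
profile: RFD ramps linearly from −e to +e across each origin's transition
width and relaxes linearly towards the inter-origin midpoint — exact and
fast, the workhorse for unit tests.  ``cell_simulation`` draws individual
cells in which each origin fires independently with probability e and a
position is replicated rightward iff its nearest fired origin lies to its
left; averaging over cells gives an RFD estimate with realistic shape
(plateaus between origins and steps at midpoints) that shares the 2e rise
across each zone with the analytic model but differs inside termination
regions.

Sampling inverts the RFD definition: a bin with true RFD r receives
Poisson-distributed total depth split Binomial(total, (1 + r)/2) onto the
Crick strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pysam

from .errors import ParameterError
from .genome import GenomeBinning
from .rfd import RFDTrack
from .stranded_counts import StrandedBinCounts

__all__ = [
    "Origin",
    "ReplicationProgram",
    "GroundTruth",
    "make_program",
    "true_rfd",
    "sample_counts",
    "write_synthetic_bam",
]


@dataclass(frozen=True)
class Origin:
    position: int  # bp
    efficiency: float  # e in (0, 1]
    half_width: int  # transition half-width in bp


@dataclass
class ReplicationProgram:
    genome: GenomeBinning
    origins: dict[str, list[Origin]]
    baseline_rfd: float = 0.0

    def __post_init__(self) -> None:
        for chrom, origs in self.origins.items():
            positions = [o.position for o in origs]
            if positions != sorted(positions) or len(set(positions)) != len(positions):
                raise ParameterError(f"origins on {chrom} must be strictly increasing")
            for o in origs:
                if not 0 < o.efficiency <= 1:
                    raise ParameterError(f"efficiency {o.efficiency} outside (0, 1]")

    @property
    def n_origins(self) -> int:
        return sum(len(v) for v in self.origins.values())


@dataclass
class GroundTruth:
    program: ReplicationProgram
    rfd: RFDTrack  # true per-bin RFD, span 1
    iz_intervals: list[tuple[str, int, int, float]] = field(default_factory=list)
    tz_intervals: list[tuple[str, int, int]] = field(default_factory=list)


def make_program(
    n_origins: int,
    genome: GenomeBinning,
    efficiency_range: tuple[float, float] = (0.5, 1.0),
    seed: int = 0,
    transition_half_width: int = 15_000,
    baseline_rfd: float = 0.0,
) -> ReplicationProgram:
    """Place origins uniformly with guaranteed minimum spacing.

    Origins are allocated to chromosomes proportionally to length, then
    placed by the standard order-statistics construction: draw uniforms on
    the length minus the total reserved spacing, sort, and re-add the
    spacing — deterministic for a given seed and guaranteeing pairwise
    distance >= 4 x half-width with a 2 x half-width margin at the ends.
    """
    if n_origins < 1:
        raise ParameterError("need n_origins >= 1")
    rng = np.random.default_rng(seed)
    spacing = 4 * transition_half_width
    margin = 2 * transition_half_width
    lengths = np.array([genome.chrom_sizes[c] for c in genome.chroms], dtype=float)
    # largest-remainder allocation proportional to length
    quota = n_origins * lengths / lengths.sum()
    alloc = np.floor(quota).astype(int)
    remainder = n_origins - alloc.sum()
    for i in np.argsort(-(quota - alloc))[:remainder]:
        alloc[i] += 1
    origins: dict[str, list[Origin]] = {}
    for chrom, m in zip(genome.chroms, alloc):
        if m == 0:
            origins[chrom] = []
            continue
        length = genome.chrom_sizes[chrom]
        free = length - 2 * margin - (m - 1) * spacing
        if free <= 0:
            raise ParameterError(
                f"{chrom} ({length} bp) too small for {m} origins at spacing "
                f"{spacing} bp"
            )
        offsets = np.sort(rng.uniform(0, free, size=m))
        positions = (margin + offsets + np.arange(m) * spacing).astype(int)
        effs = rng.uniform(*efficiency_range, size=m)
        origins[chrom] = [
            Origin(int(p), float(e), transition_half_width)
            for p, e in zip(positions, effs)
        ]
    return ReplicationProgram(genome=genome, origins=origins, baseline_rfd=baseline_rfd)


def _piecewise_knots(origins: list[Origin], length: int) -> tuple[np.ndarray, np.ndarray]:
    """Knot points of the analytic RFD profile on one chromosome."""
    xs: list[float] = [0.0]
    ys: list[float] = [-origins[0].efficiency]
    for i, o in enumerate(origins):
        xs += [o.position - o.half_width, o.position + o.half_width]
        ys += [-o.efficiency, o.efficiency]
        if i + 1 < len(origins):
            nxt = origins[i + 1]
            mid = (o.position + nxt.position) / 2
            xs.append(mid)
            ys.append((o.efficiency - nxt.efficiency) / 2)
    xs.append(float(length))
    ys.append(origins[-1].efficiency)
    return np.array(xs), np.array(ys)


def _bin_centers(binning: GenomeBinning, chrom: str) -> np.ndarray:
    starts = np.arange(binning.n_bins(chrom)) * binning.bin_size
    ends = np.minimum(starts + binning.bin_size, binning.chrom_sizes[chrom])
    return (starts + ends) / 2.0


def _cell_sim_rfd(
    origins: list[Origin], centers: np.ndarray, cells: int, rng: np.random.Generator
) -> np.ndarray:
    pos = np.array([o.position for o in origins], dtype=float)
    eff = np.array([o.efficiency for o in origins])
    net = np.zeros(centers.size)
    informative = 0
    for _ in range(cells):
        fired = pos[rng.random(eff.size) < eff]
        if fired.size == 0:
            continue
        informative += 1
        idx = np.searchsorted(fired, centers)
        dist_left = np.where(idx > 0, centers - fired[np.maximum(idx - 1, 0)], np.inf)
        dist_right = np.where(
            idx < fired.size, fired[np.minimum(idx, fired.size - 1)] - centers, np.inf
        )
        net += np.where(dist_left <= dist_right, 1.0, -1.0)
    if informative == 0:
        return np.zeros(centers.size)
    return net / informative


def true_rfd(
    program: ReplicationProgram,
    model: Literal["piecewise_linear", "cell_simulation"] = "piecewise_linear",
    cells: int = 10_000,
    seed: int = 0,
) -> GroundTruth:
    """Evaluate the true RFD at every bin centre plus IZ/TZ truth intervals."""
    binning = program.genome
    values: dict[str, np.ndarray] = {}
    iz: list[tuple[str, int, int, float]] = []
    tz: list[tuple[str, int, int]] = []
    rng = np.random.default_rng(seed)
    for chrom in binning.chroms:
        centers = _bin_centers(binning, chrom)
        origins = program.origins.get(chrom, [])
        if not origins:
            values[chrom] = np.full(centers.size, np.clip(program.baseline_rfd, -1, 1))
            continue
        if model == "piecewise_linear":
            xs, ys = _piecewise_knots(origins, binning.chrom_sizes[chrom])
            rfd = np.interp(centers, xs, ys)
        elif model == "cell_simulation":
            rfd = _cell_sim_rfd(origins, centers, cells, rng)
        else:
            raise ParameterError(f"unknown truth model {model!r}")
        values[chrom] = np.clip(rfd + program.baseline_rfd, -1.0, 1.0)
        for i, o in enumerate(origins):
            iz.append(
                (chrom, o.position - o.half_width, o.position + o.half_width, o.efficiency)
            )
            if i + 1 < len(origins):
                nxt = origins[i + 1]
                tz.append((chrom, o.position + o.half_width, nxt.position - nxt.half_width))
    ones = {c: np.ones(binning.n_bins(c), dtype=np.int64) for c in binning.chroms}
    track = RFDTrack(
        binning=binning,
        values=values,
        span_bins=1,
        window_watson={c: a.copy() for c, a in ones.items()},
        window_crick={c: a.copy() for c, a in ones.items()},
    )
    return GroundTruth(program=program, rfd=track, iz_intervals=iz, tz_intervals=tz)


def sample_counts(
    truth: GroundTruth, mean_depth_per_bin: float, seed: int = 0
) -> StrandedBinCounts:
    """Poisson depth per bin, binomially split onto Crick with p = (1+RFD)/2."""
    if mean_depth_per_bin <= 0:
        raise ParameterError("mean_depth_per_bin must be > 0")
    rng = np.random.default_rng(seed)
    binning = truth.rfd.binning
    watson: dict[str, np.ndarray] = {}
    crick: dict[str, np.ndarray] = {}
    for chrom in binning.chroms:
        rfd = truth.rfd.values[chrom]
        total = rng.poisson(mean_depth_per_bin, size=rfd.size)
        p_crick = np.clip((1.0 + rfd) / 2.0, 0.0, 1.0)
        c = rng.binomial(total, p_crick)
        crick[chrom] = c.astype(np.int64)
        watson[chrom] = (total - c).astype(np.int64)
    return StrandedBinCounts(binning=binning, watson=watson, crick=crick)


def write_synthetic_bam(
    counts: StrandedBinCounts,
    path: str,
    read_length: int = 100,
    paired: bool = False,
    seed: int = 0,
) -> str:
    """Emit a sorted, indexed BAM realizing the given per-bin counts.

    Watson reads are forward-strand with 5' end at the bin start; Crick
    reads are reverse-strand with 5' end at the bin's last base, and read
    lengths are clipped to the bin so every 5' end stays inside its bin —
    counting the file back through the default filters reproduces the
    input counts exactly.  With ``paired=True`` each fragment is written as
    a proper pair (read 1 carries the fragment coordinate).
    """
    binning = counts.binning
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": int(binning.chrom_sizes[c])} for c in binning.chroms
        ],
    }
    tmp = path + ".unsorted.bam"
    serial = 0
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for tid, chrom in enumerate(binning.chroms):
            for idx in range(binning.n_bins(chrom)):
                bs = binning.bin_start(chrom, idx)
                be = binning.bin_end(chrom, idx)
                rl = min(read_length, be - bs)
                for strand, n in (
                    ("w", int(counts.watson[chrom][idx])),
                    ("c", int(counts.crick[chrom][idx])),
                ):
                    for _ in range(n):
                        serial += 1
                        rec = pysam.AlignedSegment()
                        rec.query_name = f"syn{serial}"
                        rec.reference_id = tid
                        rec.mapping_quality = 60
                        rec.query_sequence = "A" * rl
                        rec.cigarstring = f"{rl}M"
                        if strand == "w":
                            rec.reference_start = bs
                            rec.is_reverse = False
                        else:
                            rec.reference_start = be - rl
                            rec.is_reverse = True
                        if paired:
                            rec.is_paired = True
                            rec.is_read1 = True
                            rec.is_proper_pair = True
                            rec.next_reference_id = tid
                            rec.next_reference_start = rec.reference_start
                            rec.mate_is_reverse = not rec.is_reverse
                            mate = pysam.AlignedSegment()
                            mate.query_name = rec.query_name
                            mate.reference_id = tid
                            mate.reference_start = rec.reference_start
                            mate.mapping_quality = 60
                            mate.query_sequence = "A" * rl
                            mate.cigarstring = f"{rl}M"
                            mate.is_paired = True
                            mate.is_read2 = True
                            mate.is_proper_pair = True
                            mate.is_reverse = not rec.is_reverse
                            mate.next_reference_id = tid
                            mate.next_reference_start = rec.reference_start
                            mate.mate_is_reverse = rec.is_reverse
                            bam.write(rec)
                            bam.write(mate)
                        else:
                            bam.write(rec)
    pysam.sort("-o", path, tmp)
    import os

    os.remove(tmp)
    pysam.index(path)
    return path
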
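import numpy as np
import pandas as pd
import pytest

import okrfd as ok
from okrfd.segments import Segment, SegmentSet


def _delta(n=5, bin_size=1000, mask=None):
    binning = ok.GenomeBinning({"chr1": n * bin_size}, bin_size)
    if mask is None:
        mask = np.zeros(n, bool)
    return ok.DeltaRFDTrack(
        binning=binning,
        span_bins=15,
        delta={"chr1": np.zeros(n)},
        mask={"chr1": mask},
    )


def _post(path, p=0.9):
    post = np.full((len(path), 4), (1 - p) / 3)
    post[np.arange(len(path)), path] = p
    return post


def test_run_length_segmentation_coordinates():
    path = np.array([0, 0, 0, 1, 1])  # U,U,U,D,D on a 1 kb grid
    segs = ok.extract_segments({"chr1": path}, {"chr1": _post(path)}, _delta())
    assert [(s.state, s.start, s.end) for s in segs] == [
        ("Up", 0, 3000),
        ("Down", 3000, 5000),
    ]
    assert [s.n_windows for s in segs] == [3, 2]


def test_single_window_segment():
    path = np.array([2, 0, 2])
    segs = ok.extract_segments({"chr1": path}, {"chr1": _post(path)}, _delta(3))
    assert [(s.state, s.start, s.end) for s in segs] == [
        ("Flat1", 0, 1000),
        ("Up", 1000, 2000),
        ("Flat1", 2000, 3000),
    ]


def test_confidence_is_mean_assigned_posterior():
    path = np.array([0, 0])
    post = np.array([[1.0, 0, 0, 0], [0.8, 0.2, 0, 0]])
    segs = ok.extract_segments({"chr1": path}, {"chr1": post}, _delta(2))
    assert segs.segments[0].confidence == pytest.approx(0.9)


def test_fully_masked_runs_are_dropped():
    path = np.array([0, 0, 1, 1])
    mask = np.array([False, False, True, True])
    segs = ok.extract_segments({"chr1": path}, {"chr1": _post(path)}, _delta(4, mask=mask))
    assert [s.state for s in segs] == ["Up"]


def test_segments_tile_decoded_windows_without_overlap():
    rng = np.random.default_rng(7)
    path = rng.integers(0, 4, 200)
    segs = ok.extract_segments({"chr1": path}, {"chr1": _post(path)}, _delta(200))
    covered = 0
    prev_end = 0
    for s in segs.segments:
        assert s.start == prev_end
        prev_end = s.end
        covered += s.n_windows
    assert covered == 200


# --- efficiency -------------------------------------------------------------


def _step_counts(n=10, bin_size=1000):
    """All-Watson left half, all-Crick right half: RFD steps -1 -> +1."""
    binning = ok.GenomeBinning({"chr1": n * bin_size}, bin_size)
    w = np.zeros(n, np.int64)
    c = np.zeros(n, np.int64)
    w[: n // 2] = 10
    c[n // 2:] = 10
    return ok.StrandedBinCounts(binning, {"chr1": w}, {"chr1": c})


def test_clean_step_has_unit_efficiency():
    seg = Segment("chr1", 2500, 7500, "Up")
    eff = ok.segment_efficiency(seg, _step_counts(), flank_bp=5000)
    assert eff == pytest.approx(1.0)


def test_flat_profile_has_zero_efficiency():
    binning = ok.GenomeBinning({"chr1": 10_000}, 1000)
    counts = ok.StrandedBinCounts(
        binning, {"chr1": np.full(10, 5, np.int64)}, {"chr1": np.full(10, 5, np.int64)}
    )
    seg = Segment("chr1", 2500, 7500, "Up")
    assert ok.segment_efficiency(seg, counts) == pytest.approx(0.0)


def test_empty_flank_gives_missing_efficiency():
    binning = ok.GenomeBinning({"chr1": 10_000}, 1000)
    counts = ok.StrandedBinCounts(binning, {}, {})
    seg = Segment("chr1", 2500, 7500, "Up")
    assert np.isnan(ok.segment_efficiency(seg, counts))


def test_planted_efficiency_recovered(planted_dataset):
    """Measured ΔRFD_segment of each called zone tracks the planted firing
    efficiency within sampling error."""
    _, program, _, counts = planted_dataset
    segs, _ = ok.call_zones(counts)
    ups = list(segs.by_state("Up"))
    errors = []
    for o in program.origins["chr1"]:
        nearest = min(ups, key=lambda s: abs(s.center - o.position))
        assert abs(nearest.center - o.position) <= 10_000
        errors.append(abs(nearest.efficiency - o.efficiency))
    assert np.mean(errors) <= 0.1


# --- replicate retention and feature distance -------------------------------


def _segset(intervals, state="Up", bin_size=1000, length=1_000_000):
    binning = ok.GenomeBinning({"chr1": length}, bin_size)
    return SegmentSet(
        binning,
        [Segment("chr1", a, b, state) for a, b in intervals],
    )


def test_identical_sets_fully_retained():
    s = _segset([(0, 1000), (5000, 8000)])
    kept = ok.retain_reproducible(s, s, "Up")
    assert [(x.start, x.end) for x in kept] == [(0, 1000), (5000, 8000)]


def test_disjoint_sets_retain_nothing():
    a = _segset([(0, 1000)])
    b = _segset([(2000, 3000)])
    assert len(ok.retain_reproducible(a, b, "Up")) == 0


def test_overlap_retention_matches_quadratic_scan():
    rng = np.random.default_rng(19)

    def random_set(seed_shift):
        starts = np.sort(rng.integers(0, 900_000, 30))
        return _segset([(int(s), int(s + rng.integers(1000, 20_000))) for s in starts])

    a, b = random_set(0), random_set(1)
    kept = ok.retain_reproducible(a, b, "Up")
    expected = [
        s
        for s in a.segments
        if any(min(s.end, t.end) > max(s.start, t.start) for t in b.segments)
    ]
    assert [(s.start, s.end) for s in kept] == [(s.start, s.end) for s in expected]


def test_cross_state_overlap_does_not_count():
    a = _segset([(0, 1000)], state="Up")
    b = _segset([(0, 1000)], state="Down")
    assert len(ok.retain_reproducible(a, b, "Up")) == 0


def test_center_distance_to_features():
    segs = _segset([(9000, 11_000)])  # centre 10,000
    features = pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "start": [10_200, 0], "end": [10_340, 100]}
    )
    out = ok.nearest_feature_distance(segs, features, overlap_threshold=2000)
    assert out["distance"].iloc[0] == pytest.approx(270)
    assert bool(out["overlap"].iloc[0])


def test_feature_at_center_gives_zero_distance():
    segs = _segset([(9000, 11_000)])
    features = pd.DataFrame({"chrom": ["chr1"], "start": [9500], "end": [10_500]})
    out = ok.nearest_feature_distance(segs, features)
    assert out["distance"].iloc[0] == 0


def test_chromosome_without_features_reports_missing():
    segs = _segset([(0, 1000)])
    features = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [10]})
    out = ok.nearest_feature_distance(segs, features)
    assert np.isnan(out["distance"].iloc[0])
    assert not bool(out["overlap"].iloc[0])


def test_nearest_distance_matches_brute_force():
    rng = np.random.default_rng(23)
    segs = _segset([(int(s), int(s) + 2000) for s in rng.integers(0, 900_000, 25)])
    fstart = rng.integers(0, 900_000, 40)
    features = pd.DataFrame(
        {"chrom": "chr1", "start": fstart, "end": fstart + rng.integers(1, 5000, 40)}
    )
    out = ok.nearest_feature_distance(segs, features)
    centers = (features["start"] + features["end"]) / 2
    for i, s in enumerate(segs.segments):
        assert out["distance"].iloc[i] == pytest.approx(
            np.min(np.abs(centers - s.center))
        )


# --- noise filter and high-RFD regions --------------------------------------


def test_noise_filter_drops_low_efficiency_zone_calls():
    segs = SegmentSet(
        ok.GenomeBinning({"chr1": 100_000}, 1000),
        [
            Segment("chr1", 0, 10_000, "Up", efficiency=0.6),
            Segment("chr1", 20_000, 25_000, "Up", efficiency=0.03),
            Segment("chr1", 30_000, 40_000, "Flat1", efficiency=float("nan")),
        ],
    )
    kept = ok.filter_segments(segs, min_abs_efficiency=0.1)
    assert [(s.state, s.start) for s in kept] == [("Up", 0), ("Flat1", 30_000)]


def test_high_rfd_regions_need_flat_state_and_high_polarity():
    binning = ok.GenomeBinning({"chr1": 20_000}, 1000)
    values = np.concatenate([np.full(10, 0.9), np.full(10, 0.1)])
    track = ok.RFDTrack(
        binning=binning,
        values={"chr1": values},
        span_bins=1,
        window_watson={"chr1": np.ones(20, np.int64)},
        window_crick={"chr1": np.ones(20, np.int64)},
    )
    segs = SegmentSet(
        binning,
        [
            Segment("chr1", 0, 10_000, "Flat1"),
            Segment("chr1", 10_000, 20_000, "Flat2"),
        ],
    )
    high = ok.high_rfd_regions(segs, track, min_abs_rfd=0.5)
    assert [(s.start, s.end) for s in high] == [(0, 10_000)]
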
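import numpy as np
import pytest

import okrfd as ok
from okrfd.errors import DegenerateInputError, ParameterError, UndefinedResultError
from okrfd.hmm import MISSING, _viterbi, log_likelihood


def _delta_track(deltas, mask=None, bin_size=1000):
    deltas = np.asarray(deltas, dtype=float)
    binning = ok.GenomeBinning({"chr1": bin_size * len(deltas)}, bin_size)
    if mask is None:
        mask = np.isnan(deltas)
    return ok.DeltaRFDTrack(
        binning=binning,
        span_bins=15,
        delta={"chr1": deltas.copy()},
        mask={"chr1": np.asarray(mask, bool)},
    )


def _track_from_rfd(rfd_values, totals=None, bin_size=1000):
    rfd_values = np.asarray(rfd_values, dtype=float)
    n = rfd_values.size
    binning = ok.GenomeBinning({"chr1": bin_size * n}, bin_size)
    if totals is None:
        totals = np.full(n, 100, dtype=np.int64)
    totals = np.asarray(totals, dtype=np.int64)
    crick = np.round(totals * (1 + np.nan_to_num(rfd_values)) / 2).astype(np.int64)
    return ok.RFDTrack(
        binning=binning,
        values={"chr1": rfd_values},
        span_bins=15,
        window_watson={"chr1": totals - crick},
        window_crick={"chr1": crick},
    )


# --- ΔRFD and masking -------------------------------------------------------


def test_delta_rfd_formula():
    track = _track_from_rfd([-0.4, 0.6, 0.6])
    delta = ok.compute_delta_rfd(track, min_reads=0)
    assert delta.delta["chr1"][0] == pytest.approx(0.5)  # (0.6 - (-0.4)) / 2
    assert delta.delta["chr1"][1] == pytest.approx(0.0)
    assert np.isnan(delta.delta["chr1"][2])  # last window has no successor
    assert delta.mask["chr1"][2]


def test_low_coverage_window_is_masked():
    totals = np.array([100, 29, 100, 100])
    track = _track_from_rfd([0.0, 0.0, 0.0, 0.0], totals)
    delta = ok.compute_delta_rfd(track, min_reads=30)
    assert delta.mask["chr1"][1]
    assert not delta.mask["chr1"][0]
    assert not delta.mask["chr1"][2]


def test_mask_is_exactly_the_low_read_set():
    """Wherever ΔRFD is defined, the mask equals {window total < 30}."""
    rng = np.random.default_rng(11)
    totals = rng.integers(0, 60, size=500)
    rfd = np.where(totals > 0, rng.uniform(-1, 1, 500), np.nan)
    track = _track_from_rfd(rfd, totals)
    delta = ok.compute_delta_rfd(track, min_reads=30)
    defined = ~np.isnan(track.values["chr1"])
    defined = defined & np.roll(defined, -1)
    defined[-1] = False
    low = totals < 30
    np.testing.assert_array_equal(delta.mask["chr1"][defined], low[defined])
    # and every window where ΔRFD is undefined is masked too
    assert delta.mask["chr1"][~defined].all()


def test_constant_rfd_gives_zero_delta():
    track = _track_from_rfd(np.full(50, 0.3))
    delta = ok.compute_delta_rfd(track, min_reads=0)
    np.testing.assert_allclose(delta.delta["chr1"][:-1], 0.0, atol=1e-15)


# --- quantile discretization ------------------------------------------------


def test_quantile_symbols_on_known_list():
    # ten evenly spread values -> two per quantile
    vals = np.linspace(-0.9, 0.9, 10)
    delta = _delta_track(vals)
    seq = ok.symbolize_quantiles(delta, k=5)
    np.testing.assert_array_equal(seq.symbols["chr1"], [1, 1, 2, 2, 3, 3, 4, 4, 5, 5])
    assert np.all(np.diff(seq.quantile_boundaries) >= 0)


def test_constant_deltas_are_degenerate():
    with pytest.raises(DegenerateInputError):
        ok.symbolize_quantiles(_delta_track(np.zeros(100)), k=5)


def test_symmetric_deltas_balance_extreme_symbols():
    rng = np.random.default_rng(5)
    half = rng.uniform(0.01, 1, 500)
    vals = np.concatenate([half, -half])  # exactly symmetric distribution
    seq = ok.symbolize_quantiles(_delta_track(vals), k=5)
    sym = seq.symbols["chr1"]
    assert np.count_nonzero(sym == 1) == np.count_nonzero(sym == 5)


def test_masked_windows_get_missing_symbol():
    vals = np.linspace(-1, 1, 20)
    mask = np.zeros(20, bool)
    mask[3] = True
    seq = ok.symbolize_quantiles(_delta_track(vals, mask), k=5)
    assert seq.symbols["chr1"][3] == MISSING
    assert (seq.symbols["chr1"][~mask] != MISSING).all()


# --- HMM decoding -----------------------------------------------------------


def _random_params(rng, zero_emissions=False):
    initial = rng.dirichlet(np.ones(4))
    transition = rng.dirichlet(np.ones(4), size=4)
    emission = rng.dirichlet(np.ones(5), size=4)
    if zero_emissions:
        emission[rng.integers(4), rng.integers(5)] = 0.0
        emission /= emission.sum(axis=1, keepdims=True)
    return ok.HMMParameters(initial=initial, transition=transition, emission=emission)


def _enumerate_max_logprob(obs, params):
    """Brute-force maximum path log-probability over all 4^L paths."""
    L = obs.size
    with np.errstate(divide="ignore"):
        li = np.log(params.initial)
        lt = np.log(params.transition)
        le = np.log(params.emission)
    powers = 4 ** np.arange(L - 1, -1, -1)
    paths = (np.arange(4**L)[:, None] // powers) % 4
    lp = li[paths[:, 0]].astype(float)
    for t in range(L):
        if obs[t] != MISSING:
            lp += le[paths[:, t], obs[t] - 1]
        if t > 0:
            lp += lt[paths[:, t - 1], paths[:, t]]
    return float(np.max(lp))


@pytest.mark.parametrize("zero_emissions", [False, True])
def test_viterbi_matches_exhaustive_enumeration(zero_emissions):
    rng = np.random.default_rng(17 if zero_emissions else 13)
    for _ in range(60):
        params = _random_params(rng, zero_emissions)
        L = int(rng.integers(1, 9))
        obs = rng.integers(0, 6, size=L)  # includes MISSING symbols
        try:
            path, score = _viterbi(obs, params)
        except UndefinedResultError:
            assert np.isneginf(_enumerate_max_logprob(obs, params))
            continue
        assert score == pytest.approx(_enumerate_max_logprob(obs, params), abs=1e-9)


def test_forward_and_backward_likelihood_agree():
    rng = np.random.default_rng(23)
    for _ in range(50):
        params = _random_params(rng)
        obs = rng.integers(0, 6, size=int(rng.integers(2, 40)))
        f = log_likelihood(obs, params, "forward")
        b = log_likelihood(obs, params, "backward")
        assert f == pytest.approx(b, rel=1e-9, abs=1e-9)


def test_posteriors_normalize_on_long_sequence():
    rng = np.random.default_rng(29)
    params = _random_params(rng)
    n = 100_000
    binning = ok.GenomeBinning({"chr1": n * 1000}, 1000)
    seq = ok.SymbolSequence(
        binning=binning,
        symbols={"chr1": rng.integers(1, 6, size=n)},
        quantile_boundaries=np.linspace(-0.5, 0.5, 4),
    )
    _, posteriors, _ = ok.decode_states(seq, params)
    sums = posteriors["chr1"].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_absorbing_chain_stays_in_up():
    params = ok.HMMParameters(
        initial=[1.0, 0.0, 0.0, 0.0],
        transition=np.eye(4),
        emission=np.full((4, 5), 0.2),
    )
    binning = ok.GenomeBinning({"chr1": 20_000}, 1000)
    seq = ok.SymbolSequence(
        binning=binning,
        symbols={"chr1": np.array([5, 1, 3, 2, 4] * 4)},
        quantile_boundaries=np.zeros(4),
    )
    paths, _, _ = ok.decode_states(seq, params)
    assert (paths["chr1"] == 0).all()  # Up regardless of symbols


def test_all_missing_sequence_follows_chain_marginals():
    """With no observations the posteriors are the analytic Markov-chain
    marginals mu_t = mu_0 T^t."""
    rng = np.random.default_rng(31)
    params = _random_params(rng)
    T = 12
    binning = ok.GenomeBinning({"chr1": T * 1000}, 1000)
    seq = ok.SymbolSequence(
        binning=binning,
        symbols={"chr1": np.full(T, MISSING)},
        quantile_boundaries=np.zeros(4),
    )
    _, posteriors, ll = ok.decode_states(seq, params)
    mu = params.initial.copy()
    for t in range(T):
        np.testing.assert_allclose(posteriors["chr1"][t], mu, atol=1e-9)
        mu = mu @ params.transition
    assert ll == pytest.approx(0.0, abs=1e-12)  # likelihood 1


def test_invalid_parameters_rejected():
    with pytest.raises(ParameterError):
        ok.HMMParameters(
            initial=[0.5, 0.5, 0.5, 0.5],
            transition=np.eye(4),
            emission=np.full((4, 5), 0.2),
        )
    with pytest.raises(ParameterError):
        ok.HMMParameters(
            initial=[0.25] * 4,
            transition=np.full((4, 4), 0.3),
            emission=np.full((4, 5), 0.2),
        )


def test_parameters_json_round_trip(tmp_path):
    params = ok.HMMParameters.default()
    path = str(tmp_path / "params.json")
    params.to_json(path)
    back = ok.HMMParameters.from_json(path)
    np.testing.assert_allclose(back.initial, params.initial)
    np.testing.assert_allclose(back.transition, params.transition)
    np.testing.assert_allclose(back.emission, params.emission)
    assert back.states == params.states


def test_default_parameters_have_mirror_symmetry():
    """Up emissions reversed equal Down emissions; the two Flats match: the
    structure that makes strand swap map Up segments onto Down segments."""
    p = ok.HMMParameters.default()
    np.testing.assert_allclose(p.emission[0][::-1], p.emission[1])
    np.testing.assert_allclose(p.emission[2], p.emission[3])
    np.testing.assert_allclose(p.transition, p.transition.T)
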
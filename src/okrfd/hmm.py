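"""Four-state HMM over quantile-discretized ΔRFD.

The observed quantity is ΔRFD_n = (RFD_{n+1} − RFD_n)/2 between adjacent
sliding windows: positive steps mark predominant initiation, negative steps
predominant termination.  ΔRFD values are pooled genome-wide, divided into
five quantiles, and the resulting symbol sequence is decoded per chromosome
with a 4-state HMM — Up (initiation zones), Down (termination zones), and
two Flat states for constant-RFD stretches.  The reported path is the
Viterbi path; forward–backward posteriors provide a per-window confidence.

Transition and emission probabilities are fixed, not trained.  The shipped
defaults load the Up state on the high ΔRFD quantiles, Down on the low
ones, and both Flats on the central quantiles, with strong (0.99) state
persistence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError, UndefinedResultError
from .genome import GenomeBinning
from .rfd import RFDTrack

__all__ = [
    "STATES",
    "MISSING",
    "DeltaRFDTrack",
    "SymbolSequence",
    "HMMParameters",
    "compute_delta_rfd",
    "symbolize_quantiles",
    "decode_states",
    "log_likelihood",
]

STATES = ("Up", "Down", "Flat1", "Flat2")
MISSING = 0  # symbol code for masked/undefined windows; real symbols are 1..k


@dataclass
class DeltaRFDTrack:
    """Per-window ΔRFD with the low-coverage mask.

    ``mask[chrom][n]`` is True where the window is unusable: aggregated
    read total below ``min_reads`` or ΔRFD undefined (either flanking RFD
    missing, or last window of the chromosome).
    """

    binning: GenomeBinning
    span_bins: int
    delta: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    min_reads: int = 30


@dataclass
class SymbolSequence:
    """Quantile symbols per chromosome: 1..k ascending ΔRFD, 0 = missing."""

    binning: GenomeBinning
    symbols: dict[str, np.ndarray]
    quantile_boundaries: np.ndarray
    k: int = 5


@dataclass
class HMMParameters:
    """Initial/transition probabilities over (Up, Down, Flat1, Flat2) and
    emission probabilities over the k ΔRFD quantile symbols."""

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    states: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        n = len(self.states)
        if self.initial.shape != (n,):
            raise ParameterError(f"initial must have shape ({n},)")
        if self.transition.shape != (n, n):
            raise ParameterError(f"transition must have shape ({n},{n})")
        if self.emission.ndim != 2 or self.emission.shape[0] != n:
            raise ParameterError(f"emission must have {n} rows")
        for name, arr, axis_sums in (
            ("initial", self.initial, self.initial.sum(keepdims=True)),
            ("transition", self.transition, self.transition.sum(axis=1)),
            ("emission", self.emission, self.emission.sum(axis=1)),
        ):
            if (arr < 0).any() or (arr > 1).any():
                raise ParameterError(f"{name} probabilities outside [0,1]")
            if not np.allclose(axis_sums, 1.0, atol=1e-9):
                raise ParameterError(f"{name} rows must sum to 1")

    @property
    def n_symbols(self) -> int:
        return self.emission.shape[1]

    @classmethod
    def default(cls) -> "HMMParameters":
        """Shipped defaults: uniform start, 0.99 self-transition, Up loading
        the high quantiles, Down the low ones, Flats the centre."""
        up = np.array([0.02, 0.03, 0.10, 0.35, 0.50])
        flat = np.array([0.10, 0.20, 0.40, 0.20, 0.10])
        off = 0.01 / 3
        transition = np.full((4, 4), off)
        np.fill_diagonal(transition, 0.99)
        return cls(
            initial=np.full(4, 0.25),
            transition=transition,
            emission=np.vstack([up, up[::-1], flat, flat]),
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "states": list(self.states),
                    "initial": self.initial.tolist(),
                    "transition": self.transition.tolist(),
                    "emission": self.emission.tolist(),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "HMMParameters":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            initial=obj["initial"],
            transition=obj["transition"],
            emission=obj["emission"],
            states=tuple(obj.get("states", STATES)),
        )


def compute_delta_rfd(
    track: RFDTrack, min_reads: int = 30, per_strand: bool = False
) -> DeltaRFDTrack:
    """ΔRFD between adjacent windows with the low-coverage mask.

    A window is masked when its aggregated two-strand read total is below
    ``min_reads`` (``per_strand=True`` instead requires each strand alone
    to reach ``min_reads``), and wherever ΔRFD is undefined.
    """
    delta: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for chrom in track.binning.chroms:
        rfd = track.values[chrom]
        d = np.full(rfd.shape, np.nan)
        if rfd.size > 1:
            d[:-1] = (rfd[1:] - rfd[:-1]) / 2.0
        if per_strand:
            low = (
                np.minimum(track.window_watson[chrom], track.window_crick[chrom])
                < min_reads
            )
        else:
            low = track.window_totals(chrom) < min_reads
        m = low | np.isnan(d)
        d[m] = np.nan
        delta[chrom] = d
        mask[chrom] = m
    return DeltaRFDTrack(
        binning=track.binning,
        span_bins=track.span_bins,
        delta=delta,
        mask=mask,
        min_reads=min_reads,
    )


def symbolize_quantiles(delta: DeltaRFDTrack, k: int = 5) -> SymbolSequence:
    """Discretize ΔRFD into k genome-wide quantile symbols.

    Boundaries are the empirical i/k quantiles (i = 1..k−1) of all unmasked
    ΔRFD values pooled across chromosomes.  A value maps to symbol
    ``1 + #{boundaries strictly below it}``, so ties fall to the lower
    symbol.  Masked windows map to the MISSING code 0.
    """
    pool = np.concatenate(
        [delta.delta[c][~delta.mask[c]] for c in delta.binning.chroms]
    )
    if pool.size < k:
        raise DegenerateInputError(
            f"need >= {k} unmasked windows genome-wide, got {pool.size}"
        )
    if np.unique(pool).size < k:
        raise DegenerateInputError(
            f"fewer than {k} distinct ΔRFD values; consider larger bins"
        )
    boundaries = np.quantile(pool, np.arange(1, k) / k)
    symbols: dict[str, np.ndarray] = {}
    for chrom in delta.binning.chroms:
        d = delta.delta[chrom]
        sym = np.zeros(d.size, dtype=np.int64)
        ok = ~delta.mask[chrom]
        sym[ok] = 1 + np.searchsorted(boundaries, d[ok], side="left")
        symbols[chrom] = sym
    return SymbolSequence(
        binning=delta.binning, symbols=symbols, quantile_boundaries=boundaries, k=k
    )


def _log_emissions(obs: np.ndarray, params: HMMParameters) -> np.ndarray:
    """(T, n_states) log emission likelihoods; MISSING rows are all zero
    (likelihood 1 for every state) so the chain stays connected across
    masked gaps."""
    with np.errstate(divide="ignore"):
        log_emit = np.log(params.emission)
    out = np.zeros((obs.size, params.initial.size))
    observed = obs != MISSING
    out[observed] = log_emit[:, obs[observed] - 1].T
    return out


def _viterbi(obs: np.ndarray, params: HMMParameters) -> tuple[np.ndarray, float]:
    """Max-probability state path in log space.

    Ties break to the lowest state index in (Up, Down, Flat1, Flat2) order,
    making the output deterministic.
    """
    n = params.initial.size
    logb = _log_emissions(obs, params)
    with np.errstate(divide="ignore"):
        log_init = np.log(params.initial)
        log_trans = np.log(params.transition)
    T = obs.size
    score = log_init + logb[0]
    back = np.zeros((T, n), dtype=np.int64)
    for t in range(1, T):
        cand = score[:, None] + log_trans  # cand[i, j]: come from i into j
        back[t] = np.argmax(cand, axis=0)  # argmax takes the lowest index on ties
        score = cand[back[t], np.arange(n)] + logb[t]
    if np.all(np.isneginf(score)):
        first_bad = _first_impossible(obs, params)
        raise UndefinedResultError(
            f"sequence has zero likelihood under the model (first impossible "
            f"position: {first_bad})"
        )
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(np.max(score))


def _first_impossible(obs: np.ndarray, params: HMMParameters) -> int:
    logb = _log_emissions(obs, params)
    alive = params.initial > 0
    for t in range(obs.size):
        alive = alive & np.isfinite(logb[t])
        if not alive.any():
            return t
        if t + 1 < obs.size:
            alive = (params.transition[alive].sum(axis=0) > 0)
    return obs.size - 1


def _forward(obs: np.ndarray, params: HMMParameters) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward pass; returns (alpha_hat, per-step scale factors)."""
    b = np.exp(_log_emissions(obs, params))
    T, n = obs.size, params.initial.size
    alpha = np.empty((T, n))
    scale = np.empty(T)
    a = params.initial * b[0]
    scale[0] = a.sum()
    if scale[0] == 0:
        raise UndefinedResultError(
            f"sequence has zero likelihood (first impossible position: "
            f"{_first_impossible(obs, params)})"
        )
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ params.transition) * b[t]
        scale[t] = a.sum()
        if scale[t] == 0:
            raise UndefinedResultError(
                f"sequence has zero likelihood (first impossible position: "
                f"{_first_impossible(obs, params)})"
            )
        alpha[t] = a / scale[t]
    return alpha, scale


def _backward(obs: np.ndarray, params: HMMParameters, scale: np.ndarray) -> np.ndarray:
    b = np.exp(_log_emissions(obs, params))
    T, n = obs.size, params.initial.size
    beta = np.empty((T, n))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (params.transition @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    return beta


def log_likelihood(
    obs: np.ndarray, params: HMMParameters, method: str = "forward"
) -> float:
    """Sequence log-likelihood via the forward or the backward recursion.

    The two recursions are independent computations of the same quantity
    and agreeing values are a standard implementation check.
    """
    if method == "forward":
        _, scale = _forward(obs, params)
        return float(np.log(scale).sum())
    if method == "backward":
        b = np.exp(_log_emissions(obs, params))
        T = obs.size
        beta = np.ones(params.initial.size)
        log_l = 0.0
        for t in range(T - 2, -1, -1):
            beta = params.transition @ (b[t + 1] * beta)
            s = beta.sum()
            if s == 0:
                raise UndefinedResultError("sequence has zero likelihood")
            log_l += np.log(s)
            beta = beta / s
        final = float(np.sum(params.initial * b[0] * beta))
        if final == 0:
            raise UndefinedResultError("sequence has zero likelihood")
        return log_l + float(np.log(final))
    raise ParameterError(f"unknown method {method!r}")


def decode_states(
    symbols: SymbolSequence, params: HMMParameters
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], float]:
    """Viterbi path, forward–backward posteriors and total log-likelihood.

    Chromosomes are decoded independently, each restarting from the initial
    distribution.  MISSING symbols contribute emission likelihood 1 for
    every state, so short masked gaps do not break segment continuity.
    Returns (path per chromosome as state indices, (T, 4) posterior arrays,
    summed log-likelihood).
    """
    if params.n_symbols < symbols.k:
        raise ParameterError(
            f"emission matrix has {params.n_symbols} symbols, need {symbols.k}"
        )
    paths: dict[str, np.ndarray] = {}
    posteriors: dict[str, np.ndarray] = {}
    total_ll = 0.0
    for chrom in symbols.binning.chroms:
        obs = symbols.symbols[chrom]
        if obs.size == 0:
            paths[chrom] = np.empty(0, dtype=np.int64)
            posteriors[chrom] = np.empty((0, params.initial.size))
            continue
        path, _ = _viterbi(obs, params)
        alpha, scale = _forward(obs, params)
        beta = _backward(obs, params, scale)
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        paths[chrom] = path
        posteriors[chrom] = post
        total_ll += float(np.log(scale).sum())
    return paths, posteriors, total_ll
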
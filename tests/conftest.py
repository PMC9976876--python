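import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import okrfd as ok

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_binning():
    return ok.GenomeBinning({"chr1": 100_000}, 1000)


@pytest.fixture
def random_counts(small_binning):
    rng = np.random.default_rng(42)
    nb = small_binning.n_bins("chr1")
    return ok.StrandedBinCounts(
        small_binning,
        {"chr1": rng.poisson(20, nb)},
        {"chr1": rng.poisson(20, nb)},
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """The standard simulation conditions: 10 Mb genome, 1 kb bins, 20
    origins with 30 kb transitions and efficiencies in [0.5, 1], mean
    depth 40 reads per bin."""
    genome = ok.GenomeBinning({"chr1": 10_000_000}, 1000)
    program = ok.make_program(
        20, genome, (0.5, 1.0), seed=7, transition_half_width=15_000
    )
    truth = ok.true_rfd(program)
    counts = ok.sample_counts(truth, 40, seed=8)
    return genome, program, truth, counts


def match_zones_to_origins(zones, origins, max_center_error=10_000):
    """Greedy one-to-one matching of called zones to planted origins by
    centre distance.  Returns (matched origin->zone pairs, unmatched zone
    indices)."""
    used: set[int] = set()
    pairs = []
    for o in origins:
        best = None
        for j, s in enumerate(zones):
            if j in used:
                continue
            d = abs(s.center - o.position)
            if d <= max_center_error and (best is None or d < best[1]):
                best = (j, d)
        if best is not None:
            used.add(best[0])
            pairs.append((o, zones[best[0]]))
    unmatched = [j for j in range(len(zones)) if j not in used]
    return pairs, unmatched
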
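import itertools

import numpy as np
import pytest

from bifidopanel import mockmix as mm


@pytest.fixture
def strain_panel():
    return mm.default_strain_panel()


@pytest.fixture
def potencies(strain_panel):
    return {s.species_label: s.potency for s in strain_panel}


def exact_rank_sum_p(x, y) -> float:
    """Full-enumeration two-sided Mann-Whitney p-value (tie-free only).

    Enumerates every assignment of the pooled observations to the two
    groups and counts assignments at least as extreme (in the
    symmetric-distance sense min(U, nx*ny - U)) as the observed one.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    nx, ny = len(x), len(y)
    m = nx * ny

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    extreme_obs = min(u_obs, m - u_obs)
    count = 0
    total = 0
    for xs_idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in xs_idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in xs_idx]
        u = u_stat(xs, ys)
        if min(u, m - u) <= extreme_obs:
            count += 1
        total += 1
    return count / total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240503)
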
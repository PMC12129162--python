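import numpy as np
import pytest

from latticepd import Params, Population, Strategy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_population(L: int, seed: int) -> Population:
    g = np.random.default_rng(seed).integers(0, 4, size=(L, L)).astype(np.int8)
    return Population.from_grid(g)


@pytest.fixture
def small_params():
    return Params(r=0.2, beta=0.2, gamma=0.05, mode="direct", L=6,
                  steps_total=10, steps_average=5, seed=7)


def brute_force_total_payoff(site, grid, params) -> float:
    """Independent oracle: enumerate ordered pairs from first principles.

    Walks the offset stencils directly on the 2-D grid and scores each
    pair with explicit cooperate/defect and punish/defect logic, without
    using the package's payoff tables or neighbor index arrays.
    """
    L = grid.shape[0]
    i, j = site
    s_focal = Strategy(int(grid[i, j]))
    total = 0.0
    # stage 1: prisoner's dilemma with the 8 Chebyshev-distance-1 sites
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            s_other = Strategy(int(grid[(i + di) % L, (j + dj) % L]))
            if s_focal.cooperates and s_other.cooperates:
                total += 1.0
            elif s_focal.cooperates:
                total += -params.r
            elif s_other.cooperates:
                total += 1.0 + params.r
    # stage 2: punishment over the mode's scope
    if params.mode == "direct":
        scope = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 if (di, dj) != (0, 0)]
    elif params.mode == "indirect":
        scope = [(di, dj) for di in range(-2, 3) for dj in range(-2, 3)
                 if max(abs(di), abs(dj)) == 2]
    else:
        scope = []
    for di, dj in scope:
        s_other = Strategy(int(grid[(i + di) % L, (j + dj) % L]))
        if s_focal.punishes and not s_other.cooperates:
            total -= params.gamma
        if not s_focal.cooperates and s_other.punishes:
            total -= params.beta
    return total
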
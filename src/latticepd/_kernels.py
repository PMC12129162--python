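"""Numba inner loops for the asynchronous Monte Carlo dynamics.

One Monte Carlo step performs N = L**2 elementary updates: pick a focal
site uniformly at random, pick one of its 8 Moore neighbors, compute
both total payoffs on the current configuration, and let the focal site
imitate with the Fermi probability 1/(1 + exp((pi_i - pi_j) * kappa)).

The kernels receive the stage payoff tables already combined per mode:
``t1`` is summed over the 8 first-order neighbors and, when ``use2`` is
set, ``t2`` over the 16 second-order ring.  For direct mode the caller
folds the punishment table into ``t1`` so the inner loop touches only 8
neighbors; for indirect mode both loops run.

When no defectors are present, every total payoff is identical (the
punishment stage is inert and all first-stage pairs are C-C), so the
Fermi probability is exactly 1/2 for every pair; the step then runs a
cheap neutral-drift branch that consumes the RNG stream in exactly the
same pattern as the full branch and is therefore stream-identical to it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EXP_CLAMP = 700.0  # exp overflow guard; probability saturates to 0/1


@njit(cache=True, inline="always")
def _site_payoff(i, strat, nbr1, nbr2, t1, t2, use2):
    s = strat[i]
    p = 0.0
    for k in range(nbr1.shape[1]):
        p += t1[s, strat[nbr1[i, k]]]
    if use2:
        for k in range(nbr2.shape[1]):
            p += t2[s, strat[nbr2[i, k]]]
    return p


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def mc_step_kernel(strat, nbr1, nbr2, t1, t2, use2, kappa, counts):
    """One Monte Carlo step of N elementary updates, in place."""
    n = strat.size
    if counts[1] + counts[3] == 0:
        # defector-free population: exact neutral drift at w = 1/2
        for _ in range(n):
            i = np.random.randint(n)
            j = nbr1[i, np.random.randint(8)]
            si = strat[i]
            sj = strat[j]
            if si != sj and np.random.random() < 0.5:
                counts[si] -= 1
                strat[i] = sj
                counts[sj] += 1
        return
    for _ in range(n):
        i = np.random.randint(n)
        j = nbr1[i, np.random.randint(8)]
        si = strat[i]
        sj = strat[j]
        if si == sj:
            continue
        pi = _site_payoff(i, strat, nbr1, nbr2, t1, t2, use2)
        pj = _site_payoff(j, strat, nbr1, nbr2, t1, t2, use2)
        x = (pi - pj) * kappa
        if x >= _EXP_CLAMP:
            w = 0.0
        elif x <= -_EXP_CLAMP:
            w = 1.0
        else:
            w = 1.0 / (1.0 + np.exp(x))
        if np.random.random() < w:
            counts[si] -= 1
            strat[i] = sj
            counts[sj] += 1


@njit(cache=True)
def all_payoffs_kernel(strat, nbr1, nbr2, t1, t2, use2, out):
    for i in range(strat.size):
        out[i] = _site_payoff(i, strat, nbr1, nbr2, t1, t2, use2)
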
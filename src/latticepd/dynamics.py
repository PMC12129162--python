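"""Asynchronous Monte Carlo evolution with Fermi pairwise imitation.

A randomly chosen focal player compares its total payoff with that of a
randomly chosen Moore neighbor and copies the neighbor's strategy with
probability

    w(i <- j) = 1 / (1 + exp((pi_i - pi_j) * kappa)),

where kappa is the imitation strength (kappa -> 0: random imitation;
kappa -> inf: strictly payoff-driven).  One Monte Carlo step consists of
N = L**2 such elementary updates, so each player updates once per step
on average.  Both payoffs are evaluated fresh on the current
configuration at the moment of the update.

Two engines implement the same process: a pure-Python reference path
(:func:`elementary_update` / :func:`mc_step`) that returns full update
records, used by the tests, and a compiled path used by :func:`run`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from . import _kernels
from .lattice import Params, Population, Strategy, init_block, init_random
from .payoffs import stage1_matrix, stage2_matrix, total_payoff

__all__ = [
    "fermi_probability",
    "UpdateRecord",
    "elementary_update",
    "mc_step",
    "Trajectory",
    "run",
]

_EXP_CLAMP = 700.0


def fermi_probability(pi_i: float, pi_j: float, kappa: float) -> float:
    """Probability that player i imitates player j.

    Monotone increasing in pi_j - pi_i; exactly 1/2 for equal payoffs or
    kappa = 0. The exponent is clamped so large payoff gaps saturate to
    0 or 1 instead of overflowing.
    """
    x = (pi_i - pi_j) * kappa
    if x >= _EXP_CLAMP:
        return 0.0
    if x <= -_EXP_CLAMP:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


@dataclass(frozen=True)
class UpdateRecord:
    """Outcome of one elementary update."""

    step: int
    focal: int
    model_neighbor: int
    prob: float
    imitated: bool


def elementary_update(
    pop: Population,
    params: Params,
    rng: np.random.Generator,
    step: int = 0,
) -> UpdateRecord:
    """One asynchronous update: focal site may imitate a random neighbor.

    Mutates only the focal site. Reference implementation; the compiled
    path in :mod:`latticepd._kernels` performs the same update.
    """
    strat = pop.strategies_flat
    i = int(rng.integers(pop.n_sites))
    j = int(pop.first_order[i, rng.integers(8)])
    pi = total_payoff(i, pop, params)
    pj = total_payoff(j, pop, params)
    w = fermi_probability(pi, pj, params.kappa)
    imitated = bool(rng.random() < w)
    if imitated:
        strat[i] = strat[j]
    return UpdateRecord(step=step, focal=i, model_neighbor=j, prob=w, imitated=imitated)


def mc_step(
    pop: Population,
    params: Params,
    rng: np.random.Generator,
    step: int = 0,
) -> list[UpdateRecord]:
    """One Monte Carlo step: exactly N = L**2 elementary updates in place."""
    return [elementary_update(pop, params, rng, step) for _ in range(pop.n_sites)]


def _mode_tables(params: Params) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-mode (first-order table, second-order table, use-second) triple."""
    t1 = stage1_matrix(params.r)
    t2 = stage2_matrix(params.beta, params.gamma)
    if params.mode == "direct":
        return t1 + t2, np.zeros((4, 4)), False
    if params.mode == "indirect":
        return t1, t2, True
    return t1, np.zeros((4, 4)), False


@dataclass
class Trajectory:
    """Time series of strategy fractions plus optional snapshots.

    ``fractions[t]`` holds the four strategy fractions (CN, DN, CP, DP)
    after t Monte Carlo steps; row 0 is the initial condition.
    """

    params: Params
    fractions: np.ndarray
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    final: Population | None = None
    absorbed_at: int | None = None

    @property
    def steps(self) -> np.ndarray:
        return np.arange(self.fractions.shape[0])

    @property
    def cooperation(self) -> np.ndarray:
        """Cooperation level (CN + CP fraction) at every recorded step."""
        return self.fractions[:, Strategy.CN] + self.fractions[:, Strategy.CP]

    @property
    def trailing_mean(self) -> np.ndarray:
        """Strategy fractions time-averaged over the trailing window."""
        w = max(1, self.params.steps_average)
        return self.fractions[-w:].mean(axis=0)

    @property
    def trailing_cooperation(self) -> float:
        m = self.trailing_mean
        return float(m[Strategy.CN] + m[Strategy.CP])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": self.steps,
                "frac_CN": self.fractions[:, Strategy.CN],
                "frac_DN": self.fractions[:, Strategy.DN],
                "frac_CP": self.fractions[:, Strategy.CP],
                "frac_DP": self.fractions[:, Strategy.DP],
            }
        )


def run(
    params: Params,
    observers: Sequence[Callable[[int, Population], None]] = (),
    init: str | Population = "random",
    engine: str = "numba",
    snapshot_steps: Iterable[int] = (),
    init_strategies: Sequence[Strategy] | None = None,
    layout=None,
    early_absorb: bool = True,
) -> Trajectory:
    """Run one full simulation and return its trajectory.

    ``init`` is ``"random"``, ``"block"``, or an explicit Population.
    Observers are called as ``observer(step, pop)`` after every Monte
    Carlo step.  With ``early_absorb`` (default), the loop stops once
    the population is monomorphic — an absorbing state under imitation —
    and the remaining fraction rows are filled with the constant state,
    which leaves all time averages exact; observers are not called for
    the filled steps.
    """
    if isinstance(init, Population):
        pop = init.copy()
    elif init == "random":
        rng_init = np.random.default_rng(params.seed)
        pop = init_random(params, rng=rng_init, strategies=init_strategies)
    elif init == "block":
        pop = init_block(params) if layout is None else init_block(params, layout)
    else:
        raise ValueError(f"unknown init {init!r}")

    snapshot_steps = set(snapshot_steps)
    n_steps = params.steps_total
    fractions = np.empty((n_steps + 1, 4))
    counts = pop.counts()
    n = pop.n_sites
    fractions[0] = counts / n
    if 0 in snapshot_steps:
        snapshots = {0: pop.grid.copy()}
    else:
        snapshots = {}
    absorbed_at = None

    if engine == "numba":
        t1, t2, use2 = _mode_tables(params)
        # distinct stream from the init draw; bounded below 2**31
        _kernels.seed_rng((params.seed * 2654435761 + 97) % 2_147_483_647)
        strat = pop.strategies_flat
        nbr1, nbr2 = pop.first_order, pop.second_order
        for step in range(1, n_steps + 1):
            _kernels.mc_step_kernel(strat, nbr1, nbr2, t1, t2, use2, params.kappa, counts)
            fractions[step] = counts / n
            if step in snapshot_steps:
                snapshots[step] = pop.grid.copy()
            for obs in observers:
                obs(step, pop)
            if early_absorb and (counts == n).any():
                absorbed_at = step
                fractions[step + 1 :] = fractions[step]
                break
    elif engine == "python":
        rng = np.random.default_rng(
            (params.seed * 2654435761 + 97) % 2_147_483_647
        )
        for step in range(1, n_steps + 1):
            mc_step(pop, params, rng, step)
            counts = pop.counts()
            fractions[step] = counts / n
            if step in snapshot_steps:
                snapshots[step] = pop.grid.copy()
            for obs in observers:
                obs(step, pop)
            if early_absorb and (counts == n).any():
                absorbed_at = step
                fractions[step + 1 :] = fractions[step]
                break
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return Trajectory(
        params=params,
        fractions=fractions,
        snapshots=snapshots,
        final=pop,
        absorbed_at=absorbed_at,
    )
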
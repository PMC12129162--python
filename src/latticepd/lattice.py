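"""Lattice geometry, strategies, parameters, and population state.

The model lives on an L x L square lattice with periodic (toroidal)
boundaries.  Every site holds one of four strategies combining a
cooperation choice with a punishment choice.  First-stage game partners
are the 8 Moore neighbors (Chebyshev distance 1); the second-order
neighborhood used by indirect punishment is the 16-site ring at
Chebyshev distance exactly 2 (the 5x5 ball minus the 3x3 ball), which
equals "neighbors of neighbors, excluding direct neighbors" on a Moore
lattice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Strategy",
    "Params",
    "Population",
    "LatticeError",
    "LayoutError",
    "MODES",
    "moore_neighbors",
    "second_order_neighbors",
    "init_random",
    "init_block",
    "write_snapshot",
    "read_snapshot",
    "DEFAULT_BLOCK_LAYOUT",
]


class LatticeError(ValueError):
    """Raised for lattice sizes on which the neighborhoods alias."""


class LayoutError(ValueError):
    """Raised for block layouts that do not tile the lattice."""


class Strategy(enum.IntEnum):
    """The four behavioral types of the two-stage game.

    The first letter is the first-stage action (C cooperate / D defect),
    the second whether the player punishes defectors in the second stage
    (P) or not (N).
    """

    CN = 0
    DN = 1
    CP = 2
    DP = 3

    @property
    def cooperates(self) -> bool:
        return self in (Strategy.CN, Strategy.CP)

    @property
    def punishes(self) -> bool:
        return self in (Strategy.CP, Strategy.DP)


#: single-character codes used in plain-text lattice snapshots
STRATEGY_CHARS = {
    Strategy.CN: "C",
    Strategy.DN: "D",
    Strategy.CP: "P",
    Strategy.DP: "Q",
}
_CHAR_TO_STRATEGY = {c: s for s, c in STRATEGY_CHARS.items()}

MODES = ("direct", "indirect", "none")

# fixed, deterministic neighbor orderings: row-major over the offset block
_MOORE_OFFSETS = tuple(
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
)
_RING2_OFFSETS = tuple(
    (di, dj)
    for di in range(-2, 3)
    for dj in range(-2, 3)
    if max(abs(di), abs(dj)) == 2
)


def moore_neighbors(site: tuple[int, int], L: int) -> list[tuple[int, int]]:
    """The 8 Moore (first-order) neighbors of ``site`` with toroidal wrap.

    Ordering is deterministic: row-major over the 3x3 offset block,
    center excluded.
    """
    if L < 3:
        raise LatticeError(f"Moore neighborhood needs L >= 3, got L={L}")
    i, j = site
    if not (0 <= i < L and 0 <= j < L):
        raise ValueError(f"site {site} outside lattice of side {L}")
    return [((i + di) % L, (j + dj) % L) for di, dj in _MOORE_OFFSETS]


def second_order_neighbors(site: tuple[int, int], L: int) -> list[tuple[int, int]]:
    """The 16 second-order neighbors: Chebyshev distance exactly 2.

    Requires L >= 5; on smaller lattices the periodic wrap aliases ring
    sites onto first-order neighbors or the site itself.
    """
    if L < 5:
        raise LatticeError(f"second-order neighborhood needs L >= 5, got L={L}")
    i, j = site
    if not (0 <= i < L and 0 <= j < L):
        raise ValueError(f"site {site} outside lattice of side {L}")
    return [((i + di) % L, (j + dj) % L) for di, dj in _RING2_OFFSETS]


@dataclass(frozen=True)
class Params:
    """Full parameter set of one simulation run.

    Parameters
    ----------
    r
        Dilemma strength. The first-stage game has reward R = 1,
        punishment P = 0, temptation T = 1 + r and sucker's payoff
        S = -r, so any r > 0 yields T > R > P > S and 2R > T + S.
    beta
        Fine deducted from a punished defector per punishment act.
    gamma
        Cost paid by the punisher per punishment act.
    kappa
        Imitation strength of the Fermi rule; kappa -> 0 is random
        imitation, large kappa is strongly payoff-driven. Default 10
        (strong imitation).
    L
        Lattice side length; the population has N = L**2 players.
    mode
        Punishment scope: ``direct`` (8 first-order neighbors),
        ``indirect`` (16 second-order neighbors), or ``none``.
    steps_total, steps_average
        Number of Monte Carlo steps, and the length of the trailing
        window over which strategy fractions are time-averaged.
    seed
        Base RNG seed for the run.
    """

    r: float
    beta: float = 0.0
    gamma: float = 0.0
    kappa: float = 10.0
    L: int = 50
    mode: str = "none"
    steps_total: int = 5000
    steps_average: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r", "beta", "gamma", "kappa"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.L < 5:
            raise LatticeError(
                f"L must be >= 5 (second-order ring aliases below that), got L={self.L}"
            )
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.steps_total < 0:
            raise ValueError(f"steps_total must be >= 0, got {self.steps_total}")
        if not (0 <= self.steps_average <= self.steps_total or self.steps_total == 0):
            raise ValueError(
                f"steps_average must be in [0, steps_total], got "
                f"{self.steps_average} with steps_total={self.steps_total}"
            )

    # derived first-stage payoff elements
    @property
    def T(self) -> float:
        return 1.0 + self.r

    @property
    def S(self) -> float:
        return -self.r

    @property
    def R(self) -> float:
        return 1.0

    @property
    def P(self) -> float:
        return 0.0

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    def with_(self, **kwargs) -> "Params":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _neighbor_table(L: int, offsets: Sequence[tuple[int, int]]) -> np.ndarray:
    """(N, k) array of flat site indices for one offset stencil."""
    idx = np.arange(L * L, dtype=np.int64)
    rows, cols = idx // L, idx % L
    out = np.empty((L * L, len(offsets)), dtype=np.int32)
    for k, (di, dj) in enumerate(offsets):
        out[:, k] = ((rows + di) % L) * L + (cols + dj) % L
    return out


_TABLE_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def neighbor_tables(L: int) -> tuple[np.ndarray, np.ndarray]:
    """Precomputed (first_order, second_order) flat-index tables for side L."""
    if L < 5:
        raise LatticeError(f"L must be >= 5, got L={L}")
    if L not in _TABLE_CACHE:
        _TABLE_CACHE[L] = (
            _neighbor_table(L, _MOORE_OFFSETS),
            _neighbor_table(L, _RING2_OFFSETS),
        )
    return _TABLE_CACHE[L]


@dataclass
class Population:
    """L x L toroidal grid of strategies with precomputed neighborhoods.

    ``grid`` stores integer strategy codes (``Strategy`` values);
    ``first_order`` and ``second_order`` are (N, 8) and (N, 16) arrays
    of flat site indices shared across populations of the same size.
    """

    grid: np.ndarray
    first_order: np.ndarray = field(repr=False)
    second_order: np.ndarray = field(repr=False)

    @classmethod
    def from_grid(cls, grid: np.ndarray) -> "Population":
        grid = np.asarray(grid, dtype=np.int8)
        if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
            raise LatticeError(f"grid must be square, got shape {grid.shape}")
        if not np.isin(grid, [int(s) for s in Strategy]).all():
            raise ValueError("grid contains values outside the four strategy codes")
        first, second = neighbor_tables(grid.shape[0])
        return cls(grid=grid, first_order=first, second_order=second)

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    @property
    def n_sites(self) -> int:
        return self.grid.size

    @property
    def strategies_flat(self) -> np.ndarray:
        return self.grid.ravel()

    def copy(self) -> "Population":
        return Population(
            grid=self.grid.copy(),
            first_order=self.first_order,
            second_order=self.second_order,
        )

    def counts(self) -> np.ndarray:
        """Number of players per strategy, indexed by ``Strategy`` value."""
        return np.bincount(self.grid.ravel(), minlength=4).astype(np.int64)


def init_random(
    params: Params,
    rng: np.random.Generator | None = None,
    strategies: Sequence[Strategy] | None = None,
) -> Population:
    """Random initial condition: each site draws a strategy uniformly.

    By default all four strategies are used with probability 1/4 each.
    ``strategies`` restricts the pool, e.g. ``(Strategy.CN, Strategy.DN)``
    for a classic two-strategy spatial game.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pool = np.array(
        [int(s) for s in (strategies if strategies is not None else list(Strategy))],
        dtype=np.int8,
    )
    grid = rng.choice(pool, size=(params.L, params.L))
    return Population.from_grid(grid)


DEFAULT_BLOCK_LAYOUT = (
    (Strategy.CN, Strategy.CP),
    (Strategy.DN, Strategy.DP),
)


def init_block(
    params: Params,
    layout: Sequence[Sequence[Strategy]] = DEFAULT_BLOCK_LAYOUT,
) -> Population:
    """Block initial condition: the lattice tiled by uniform rectangles.

    ``layout`` is a small 2-D grid of strategies; the lattice is split
    into equal rectangles, one per layout cell. The default is four
    quadrants [CN, CP; DN, DP] read row-major.
    """
    layout_arr = np.array([[int(Strategy(s)) for s in row] for row in layout], dtype=np.int8)
    br, bc = layout_arr.shape
    if params.L % br or params.L % bc:
        raise LayoutError(
            f"L={params.L} not divisible by layout shape {layout_arr.shape}"
        )
    grid = np.kron(layout_arr, np.ones((params.L // br, params.L // bc), dtype=np.int8))
    return Population.from_grid(grid)


def write_snapshot(pop_or_grid, path) -> None:
    """Write a lattice as plain text, one row per line (C/D/P/Q codes)."""
    grid = pop_or_grid.grid if isinstance(pop_or_grid, Population) else np.asarray(pop_or_grid)
    with open(path, "w") as fh:
        for row in grid:
            fh.write("".join(STRATEGY_CHARS[Strategy(int(v))] for v in row) + "\n")


def read_snapshot(path) -> Population:
    """Read a plain-text snapshot written by :func:`write_snapshot`."""
    with open(path) as fh:
        rows = [line.strip() for line in fh if line.strip()]
    try:
        grid = np.array(
            [[int(_CHAR_TO_STRATEGY[c]) for c in row] for row in rows], dtype=np.int8
        )
    except KeyError as exc:
        raise ValueError(f"unknown strategy code {exc.args[0]!r} in snapshot") from exc
    return Population.from_grid(grid)
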
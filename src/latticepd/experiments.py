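"""Ensemble experiments: baselines, parameter sweeps, phase maps,
threshold extraction, block-invasion replays, and punishment statistics.

All quantitative comparisons in the package go through seeded replicate
ensembles: each replicate is one full simulation, time-averaged over its
trailing window; the ensemble reports the mean and standard error over
replicates.  The default protocol is desk-scale (L = 50, 5000 Monte
Carlo steps, trailing window 500, 5 replicates); a larger protocol is a
matter of passing different :class:`~latticepd.lattice.Params`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dynamics import Trajectory, run
from .lattice import Params, Strategy
from .observables import PunishmentLedger, detect_stabilization, punishment_event_stats

__all__ = [
    "EnsembleResult",
    "run_ensemble",
    "SweepResult",
    "sweep",
    "PhaseMap",
    "phase_map",
    "ThresholdResult",
    "find_threshold",
    "block_invasion",
    "PunishmentDistributions",
    "punishment_distributions",
]


@dataclass(frozen=True)
class EnsembleResult:
    """Mean and standard error of trailing-window strategy fractions."""

    params: Params
    seeds: tuple[int, ...]
    mean_fractions: np.ndarray
    se_fractions: np.ndarray

    @property
    def replicates(self) -> int:
        return len(self.seeds)

    @property
    def cooperation(self) -> float:
        return float(self.mean_fractions[Strategy.CN] + self.mean_fractions[Strategy.CP])

    @property
    def cooperation_se(self) -> float:
        # fractions within a replicate are not independent; the SE of the
        # sum is taken over per-replicate cooperation values stored below
        return self._coop_se

    _coop_se: float = 0.0

    @property
    def defection(self) -> float:
        return float(self.mean_fractions[Strategy.DN] + self.mean_fractions[Strategy.DP])


def run_ensemble(
    params: Params,
    replicates: int = 5,
    seeds: Sequence[int] | None = None,
    init: str = "random",
) -> EnsembleResult:
    """Run independent seeded replicates and aggregate trailing means.

    Replicate k uses seed ``params.seed + k`` unless explicit ``seeds``
    are given.
    """
    if seeds is None:
        if replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {replicates}")
        seeds = [params.seed + k for k in range(replicates)]
    means = np.empty((len(seeds), 4))
    for k, s in enumerate(seeds):
        traj = run(params.with_(seed=int(s)), init=init)
        means[k] = traj.trailing_mean
    coop = means[:, Strategy.CN] + means[:, Strategy.CP]
    n = len(seeds)
    se = means.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(4)
    coop_se = float(coop.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return EnsembleResult(
        params=params,
        seeds=tuple(int(s) for s in seeds),
        mean_fractions=means.mean(axis=0),
        se_fractions=se,
        _coop_se=coop_se,
    )


@dataclass
class SweepResult:
    """Ensemble results along one parameter axis, per punishment mode."""

    axis: str
    grid: np.ndarray
    modes: tuple[str, ...]
    table: pd.DataFrame

    def frame(self) -> pd.DataFrame:
        return self.table


def _ensemble_row(res: EnsembleResult) -> dict:
    row = {}
    for s in Strategy:
        row[f"frac_{s.name}"] = float(res.mean_fractions[s])
        row[f"se_{s.name}"] = float(res.se_fractions[s])
    row["cooperation"] = res.cooperation
    row["cooperation_se"] = res.cooperation_se
    row["replicates"] = res.replicates
    return row


def sweep(
    params: Params,
    axis: str,
    grid: Sequence[float],
    modes: Sequence[str] = ("direct", "indirect"),
    replicates: int = 5,
    ensemble_fn: Callable = None,
) -> SweepResult:
    """Ensemble results over a grid of gamma or beta values per mode."""
    if axis not in ("gamma", "beta"):
        raise ValueError(f"axis must be 'gamma' or 'beta', got {axis!r}")
    if len(grid) == 0:
        raise ValueError("sweep grid must be nonempty")
    ensemble_fn = ensemble_fn or run_ensemble
    rows = []
    for mode in modes:
        for value in grid:
            p = params.with_(mode=mode, **{axis: float(value)})
            res = ensemble_fn(p, replicates=replicates)
            rows.append({"mode": mode, axis: float(value), **_ensemble_row(res)})
    return SweepResult(
        axis=axis,
        grid=np.asarray(grid, dtype=float),
        modes=tuple(modes),
        table=pd.DataFrame(rows),
    )


@dataclass
class PhaseMap:
    """Cooperation levels on a (gamma, beta) grid for both modes.

    ``difference`` follows the convention direct minus indirect, so the
    region where indirect punishment wins is negative.
    """

    gamma_grid: np.ndarray
    beta_grid: np.ndarray
    cooperation: dict[str, np.ndarray]  # mode -> (n_gamma, n_beta)
    sign_convention: str = "direct_minus_indirect"

    @property
    def difference(self) -> np.ndarray:
        return self.cooperation["direct"] - self.cooperation["indirect"]

    def regions(self, baseline: float, full: float = 0.99, margin: float = 0.05) -> np.ndarray:
        """Classify each cell into regions I-IV.

        I: indirect beats direct by more than ``margin``; II: direct
        beats indirect; III: both essentially full cooperation; IV: both
        within ``margin`` of the no-punishment baseline.  Cells matching
        none of these are labelled 0.
        """
        d = self.cooperation["direct"]
        i = self.cooperation["indirect"]
        out = np.zeros(d.shape, dtype=int)
        out[(d > full) & (i > full)] = 3
        out[(np.abs(d - baseline) < margin) & (np.abs(i - baseline) < margin)] = 4
        out[i - d > margin] = 1
        out[d - i > margin] = 2
        return out

    def frame(self) -> pd.DataFrame:
        rows = []
        for a, g in enumerate(self.gamma_grid):
            for b, be in enumerate(self.beta_grid):
                rows.append(
                    {
                        "gamma": float(g),
                        "beta": float(be),
                        "coop_direct": float(self.cooperation["direct"][a, b]),
                        "coop_indirect": float(self.cooperation["indirect"][a, b]),
                        "difference": float(self.difference[a, b]),
                    }
                )
        return pd.DataFrame(rows)


def phase_map(
    params: Params,
    gamma_grid: Sequence[float],
    beta_grid: Sequence[float],
    replicates: int = 5,
    ensemble_fn: Callable = None,
) -> PhaseMap:
    """Cooperation level per (gamma, beta) cell for direct and indirect modes."""
    if len(gamma_grid) == 0 or len(beta_grid) == 0:
        raise ValueError("phase-map grids must be nonempty")
    ensemble_fn = ensemble_fn or run_ensemble
    coop = {
        m: np.empty((len(gamma_grid), len(beta_grid))) for m in ("direct", "indirect")
    }
    for mode in ("direct", "indirect"):
        for a, g in enumerate(gamma_grid):
            for b, be in enumerate(beta_grid):
                p = params.with_(mode=mode, gamma=float(g), beta=float(be))
                coop[mode][a, b] = ensemble_fn(p, replicates=replicates).cooperation
    return PhaseMap(
        gamma_grid=np.asarray(gamma_grid, dtype=float),
        beta_grid=np.asarray(beta_grid, dtype=float),
        cooperation=coop,
    )


@dataclass
class ThresholdResult:
    """Boundary located by a grid scan plus one refinement pass."""

    axis: str
    value: float | None
    scan: pd.DataFrame


def find_threshold(
    params: Params,
    axis: str,
    grid: Sequence[float],
    criterion: Callable[[EnsembleResult], bool],
    replicates: int = 5,
    refine: int = 0,
    ensemble_fn: Callable = None,
) -> ThresholdResult:
    """Smallest grid value at which ``criterion`` first becomes true.

    Scans the grid in order without assuming monotonicity (some sweeps
    are reentrant) and reports the first flip from false to true; with
    ``refine`` > 0, one finer pass with that many points is run inside
    the bracketing interval.  If the criterion holds already at the
    first grid point, that point is returned.
    """
    if len(grid) == 0:
        raise ValueError("threshold grid must be nonempty")
    ensemble_fn = ensemble_fn or run_ensemble
    grid = [float(v) for v in grid]

    def evaluate(values):
        rows = []
        for v in values:
            res = ensemble_fn(params.with_(**{axis: v}), replicates=replicates)
            rows.append({axis: v, "satisfied": bool(criterion(res)), **_ensemble_row(res)})
        return rows

    rows = evaluate(grid)
    flags = [r["satisfied"] for r in rows]
    scan = pd.DataFrame(rows)
    if not any(flags):
        return ThresholdResult(axis=axis, value=None, scan=scan)
    first = flags.index(True)
    if first == 0 or refine <= 0:
        return ThresholdResult(axis=axis, value=grid[first], scan=scan)
    lo, hi = grid[first - 1], grid[first]
    fine = list(np.linspace(lo, hi, refine + 2)[1:-1])
    fine_rows = evaluate(fine)
    scan = pd.DataFrame(rows + fine_rows).sort_values(axis).reset_index(drop=True)
    for r in fine_rows:
        if r["satisfied"]:
            return ThresholdResult(axis=axis, value=r[axis], scan=scan)
    return ThresholdResult(axis=axis, value=hi, scan=scan)


def block_invasion(
    mode: str,
    gamma: float,
    beta: float = 0.2,
    r: float = 0.2,
    seed: int = 0,
    params: Params | None = None,
    snapshot_steps: Sequence[int] = (0, 50, 200, 1000, 5000),
) -> Trajectory:
    """Replay the invasion dynamics from a block initial condition.

    The lattice starts from four uniform quadrants (CN, CP / DN, DP) so
    the competition along cluster boundaries is visible; fractions are
    recorded every step and snapshots at the given steps.
    """
    if params is None:
        params = Params(r=r, beta=beta, gamma=gamma, mode=mode, seed=seed)
    else:
        params = params.with_(mode=mode, gamma=gamma, beta=beta, r=r, seed=seed)
    return run(params, init="block", snapshot_steps=snapshot_steps)


@dataclass
class PunishmentDistributions:
    """Pooled punishment-event distributions from one run.

    Per-step ledgers are pooled over all steps before the strategy
    fractions stabilize (or the whole run if they never do), giving the
    frequency distributions of per-punisher total cost and acts imposed,
    and per-defector total fine and acts received.
    """

    params: Params
    ledger: PunishmentLedger
    stabilization_step: int | None

    @property
    def punisher_costs(self) -> np.ndarray:
        return self.ledger.total_costs

    @property
    def punisher_acts(self) -> np.ndarray:
        return self.ledger.acts_imposed

    @property
    def defector_fines(self) -> np.ndarray:
        return self.ledger.total_fines

    @property
    def defector_acts(self) -> np.ndarray:
        return self.ledger.acts_received

    def histograms(self) -> dict[str, pd.DataFrame]:
        out = {}
        for name, values in (
            ("punisher_cost", self.punisher_costs),
            ("defector_fine", self.defector_fines),
            ("acts_imposed", self.punisher_acts),
            ("acts_received", self.defector_acts),
        ):
            vals, counts = np.unique(values, return_counts=True)
            out[name] = pd.DataFrame({"bin": vals, "frequency": counts})
        return out


def punishment_distributions(
    params: Params,
    init: str = "block",
    window: int = 200,
    tol: float = 0.005,
) -> PunishmentDistributions:
    """Run one simulation collecting per-step punishment ledgers.

    Ledgers are recorded each Monte Carlo step and pooled over the steps
    preceding stabilization of the strategy fractions (trailing-window
    range below ``tol``).
    """
    per_step: list[PunishmentLedger] = []

    def collect(step, pop):
        per_step.append(punishment_event_stats(pop, params))

    traj = run(params, observers=[collect], init=init)
    stab = detect_stabilization(traj.fractions, window=window, tol=tol)
    cutoff = stab if stab is not None else len(per_step)
    pool = per_step[:cutoff] or per_step
    ledger = (
        PunishmentLedger.pooled(pool)
        if pool
        else PunishmentLedger(beta=params.beta, gamma=params.gamma)
    )
    return PunishmentDistributions(params=params, ledger=ledger, stabilization_step=stab)
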
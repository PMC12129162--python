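"""Two-stage payoff tables and per-site payoff evaluation.

Stage 1 is the pairwise prisoner's dilemma played with the 8 Moore
neighbors, parametrized by the dilemma strength r (R = 1, P = 0,
T = 1 + r, S = -r).  Stage 2 is the punishment interaction: a punisher
pays cost gamma per act and the punished defector loses the fine beta.
The stage-2 scope depends on the punishment mode: the 8 first-order
neighbors (direct), the 16 second-order neighbors (indirect), or nobody
(none).  A player's total payoff is the plain sum over both stages —
accumulated, not degree-normalized, so indirect mode involves 24
interactions per player against 16 for direct.
"""

from __future__ import annotations

import numpy as np

from .lattice import Params, Population, Strategy

__all__ = [
    "stage1_matrix",
    "stage2_matrix",
    "stage1_payoff",
    "stage2_payoff",
    "total_payoff",
    "format_matrices",
]


def stage1_matrix(r: float) -> np.ndarray:
    """4x4 row-player payoff table of the first stage.

    Rows/columns are indexed by ``Strategy`` (CN, DN, CP, DP); the
    first-stage payoff depends only on the cooperate/defect component,
    so the CN and CP rows coincide, as do DN and DP.
    """
    coop_row = [1.0, -r, 1.0, -r]
    defect_row = [1.0 + r, 0.0, 1.0 + r, 0.0]
    return np.array([coop_row, defect_row, coop_row, defect_row])


def stage2_matrix(beta: float, gamma: float) -> np.ndarray:
    """4x4 row-player payoff table of the punishment stage.

    A punisher (CP, DP) pays -gamma against every defector column
    (DN, DP); a defector (DN, DP) receives -beta against every punisher
    column.  DP combines both roles, so its row is the sum of the DN
    and CP rows.
    """
    return np.array(
        [
            [0.0, 0.0, 0.0, 0.0],  # CN
            [0.0, 0.0, -beta, -beta],  # DN
            [0.0, -gamma, 0.0, -gamma],  # CP
            [0.0, -gamma, -beta, -beta - gamma],  # DP
        ]
    )


def _flat(site, L: int) -> int:
    if isinstance(site, tuple):
        return site[0] * L + site[1]
    return int(site)


def stage1_payoff(site, pop: Population, params: Params) -> float:
    """First-stage payoff: sum of table entries over the 8 Moore neighbors."""
    i = _flat(site, pop.L)
    table = stage1_matrix(params.r)
    strat = pop.strategies_flat
    return float(table[strat[i], strat[pop.first_order[i]]].sum())


def stage2_payoff(site, pop: Population, params: Params) -> float:
    """Second-stage payoff over the mode's punishment scope.

    ``direct`` sums the punishment table over the 8 first-order
    neighbors, ``indirect`` over the 16 second-order neighbors
    (first-order defectors are *not* punished), ``none`` contributes 0.
    """
    if params.mode == "none":
        return 0.0
    i = _flat(site, pop.L)
    scope = pop.first_order if params.mode == "direct" else pop.second_order
    table = stage2_matrix(params.beta, params.gamma)
    strat = pop.strategies_flat
    return float(table[strat[i], strat[scope[i]]].sum())


def total_payoff(site, pop: Population, params: Params) -> float:
    """Total payoff: stage-1 plus stage-2, evaluated on the current grid."""
    return stage1_payoff(site, pop, params) + stage2_payoff(site, pop, params)


def format_matrices(params: Params) -> str:
    """Both payoff tables as a printable diagnostic string."""
    labels = [s.name for s in Strategy]
    lines = []
    for title, table in (
        (f"stage 1 (r={params.r})", stage1_matrix(params.r)),
        (f"stage 2 (beta={params.beta}, gamma={params.gamma})",
         stage2_matrix(params.beta, params.gamma)),
    ):
        lines.append(title)
        lines.append("      " + "".join(f"{c:>8}" for c in labels))
        for name, row in zip(labels, table):
            lines.append(f"  {name:>4}" + "".join(f"{v:8.3g}" for v in row))
    return "\n".join(lines)
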
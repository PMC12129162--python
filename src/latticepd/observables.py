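"""Population observables: strategy fractions, cooperation level,
stabilization detection, and punishment-event accounting.

The punishment ledger counts acts for one lattice configuration: a
punisher (CP or DP) imposes one act on every defector inside its
stage-2 scope, paying gamma per act, and the defector receives the fine
beta per act.  Because the scope relation is symmetric, the number of
acts a defector receives equals the number of punishers whose scope
contains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import Params, Population, Strategy

__all__ = [
    "strategy_fractions",
    "cooperation_level",
    "PunishmentLedger",
    "punishment_event_stats",
    "detect_stabilization",
]


def strategy_fractions(pop: Population) -> np.ndarray:
    """Fractions of (CN, DN, CP, DP); always sums to 1."""
    return pop.counts() / pop.n_sites


def cooperation_level(pop: Population) -> float:
    """Fraction of cooperators: CN + CP."""
    f = strategy_fractions(pop)
    return float(f[Strategy.CN] + f[Strategy.CP])


@dataclass
class PunishmentLedger:
    """Punishment accounting for one configuration (or pooled over steps).

    Only active participants are kept: punishers with at least one act
    imposed and defectors with at least one act received.  Costs and
    fines are per-act amounts times act counts.
    """

    beta: float
    gamma: float
    punisher_sites: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    acts_imposed: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    defector_sites: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    acts_received: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def total_costs(self) -> np.ndarray:
        """Per-punisher total cost, gamma * acts_imposed."""
        return self.gamma * self.acts_imposed

    @property
    def total_fines(self) -> np.ndarray:
        """Per-defector total fine, beta * acts_received."""
        return self.beta * self.acts_received

    @property
    def n_acts(self) -> int:
        return int(self.acts_imposed.sum())

    def is_empty(self) -> bool:
        return self.acts_imposed.size == 0 and self.acts_received.size == 0

    @staticmethod
    def pooled(ledgers: list["PunishmentLedger"]) -> "PunishmentLedger":
        """Concatenate per-step ledgers into one pooled ledger."""
        if not ledgers:
            raise ValueError("cannot pool an empty list of ledgers")
        first = ledgers[0]
        return PunishmentLedger(
            beta=first.beta,
            gamma=first.gamma,
            punisher_sites=np.concatenate([l.punisher_sites for l in ledgers]),
            acts_imposed=np.concatenate([l.acts_imposed for l in ledgers]),
            defector_sites=np.concatenate([l.defector_sites for l in ledgers]),
            acts_received=np.concatenate([l.acts_received for l in ledgers]),
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for site, acts, amount in zip(self.punisher_sites, self.acts_imposed, self.total_costs):
            rows.append(("punisher", int(site), int(acts), float(amount)))
        for site, acts, amount in zip(self.defector_sites, self.acts_received, self.total_fines):
            rows.append(("defector", int(site), int(acts), float(amount)))
        return pd.DataFrame(rows, columns=["role", "site", "acts", "amount"])


def punishment_event_stats(pop: Population, params: Params) -> PunishmentLedger:
    """Punishment acts implied by one configuration under the given mode.

    Returns an empty ledger for mode ``none``.  In direct mode each
    count is at most 8, in indirect mode at most 16.
    """
    if params.mode == "none":
        return PunishmentLedger(beta=params.beta, gamma=params.gamma)
    scope = pop.first_order if params.mode == "direct" else pop.second_order
    strat = pop.strategies_flat
    is_defector = (strat == Strategy.DN) | (strat == Strategy.DP)
    is_punisher = (strat == Strategy.CP) | (strat == Strategy.DP)
    defectors_in_scope = is_defector[scope].sum(axis=1)
    punishers_in_scope = is_punisher[scope].sum(axis=1)

    imposed = is_punisher & (defectors_in_scope > 0)
    received = is_defector & (punishers_in_scope > 0)
    return PunishmentLedger(
        beta=params.beta,
        gamma=params.gamma,
        punisher_sites=np.flatnonzero(imposed),
        acts_imposed=defectors_in_scope[imposed].astype(np.int64),
        defector_sites=np.flatnonzero(received),
        acts_received=punishers_in_scope[received].astype(np.int64),
    )


def detect_stabilization(
    fractions: np.ndarray,
    window: int = 200,
    tol: float = 0.005,
) -> int | None:
    """Earliest step at which all strategy fractions have settled.

    Returns the first index ``t >= window`` such that within the
    trailing window ``[t - window, t]`` the range (max minus min) of
    every strategy fraction is at most ``tol``; ``None`` if the
    trajectory never settles or is shorter than the window.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    fractions = np.asarray(fractions)
    n = fractions.shape[0]
    if n <= window:
        return None
    for t in range(window, n):
        seg = fractions[t - window : t + 1]
        if (seg.max(axis=0) - seg.min(axis=0)).max() <= tol:
            return t
    return None
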
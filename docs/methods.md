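# Methods

## Model

A population of N = L² players occupies a square lattice with periodic
boundaries. Each player holds one of four strategies — CN, DN, CP, DP —
combining a prisoner's-dilemma action (cooperate/defect) with a
punishment action (punish defectors / don't).

Interactions happen in two stages and payoffs accumulate over both:

1. **Game stage.** The focal player plays the pairwise dilemma with its
   8 Moore neighbors. The payoff elements are parametrized by the
   dilemma strength r: R = 1 for mutual cooperation, P = 0 for mutual
   defection, T = 1 + r for unilateral defection, S = −r for the
   exploited cooperator. Any r > 0 satisfies T > R > P > S and
   2R > T + S.
2. **Punishment stage.** A punisher pays cost γ per act to deduct a
   fine β from each defector inside its sanctioning scope. The scope is
   the mode: *direct* = the same 8 first-order neighbors, *indirect* =
   the 16 sites at Chebyshev distance exactly 2 (the 5×5 ball minus the
   3×3 ball; equivalently "neighbors of neighbors excluding direct
   neighbors" on a Moore lattice — the test suite verifies this
   equivalence by brute-force enumeration), *none* = nobody. A DP
   player both pays costs (as a punisher) and receives fines (as a
   defector); punishment is unconditional per in-scope (punisher,
   defector) pair.

Payoffs are accumulated sums, not degree-normalized averages, so a
player in indirect mode has 8 + 16 = 24 interactions per evaluation
against 16 in direct mode. This asymmetry is part of the model.

**Update rule.** Asynchronous Monte Carlo. One step = N elementary
updates; each picks a focal player uniformly at random (with
replacement), picks one of its 8 Moore neighbors uniformly, computes
both *total* payoffs fresh on the current configuration, and imitates
with the Fermi probability w = 1/(1 + exp[(Π_i − Π_j)·κ]). κ is an
imitation *strength* (κ→0 random imitation, κ→∞ payoff-driven) — note
this is the inverse of the common noise-temperature convention, and the
package implements it exactly as stated.

## Parameters

| name | meaning | default |
|------|---------|---------|
| r | dilemma strength (dimensionless) | required |
| β | fine per punishment act (payoff units) | 0 |
| γ | cost per punishment act (payoff units) | 0 |
| κ | imitation strength (dimensionless) | 10 |
| L | lattice side (sites); N = L² | 50 |
| mode | direct / indirect / none | none |
| steps_total | Monte Carlo steps | 5000 |
| steps_average | trailing averaging window (steps) | 500 |

L ≥ 5 is enforced: below that the periodic wrap aliases the 16-site
second-order ring onto the first-order neighborhood or the site itself.

## Protocol and problem sizes

The package's default protocol is desk-scale: L = 50, 5000 Monte Carlo
steps, strategy fractions time-averaged over the trailing 500 steps,
ensembles of 5 seeded replicates (replicate k uses seed base + k; each
run draws its initial condition and its update stream from independent
streams derived from the seed). Large-lattice protocols (L ≥ 100, >10⁵
steps, 50 replicates) are a matter of passing different `Params`; all
quantities reported by `scripts/acceptance.py` use the desk-scale
protocol.

Finite-size consequences, measured with this package and expected by
design:

- Ensemble means at coexistence points carry standard errors of a few
  percent with 5 replicates.
- Threshold locations shift by up to ≈0.02 in γ and ≈0.06–0.08 in β
  relative to large-lattice values, generally in the direction that
  favors absorption: at L = 50 a minority cluster can die by
  fluctuation, so extinction/elimination fines and costs are slightly
  lower than in the large-L limit.
- The second-order free-rider window of the indirect β-sweep (CN
  replacing CP at intermediate fines, before cooperation re-establishes
  near β ≈ 0.6) is *shallow* at this scale: ensemble cooperation sags
  to ≈0.75–0.9 rather than collapsing below 0.5, and isolated
  full-cooperation ensembles occur inside it. First-crossing rules are
  therefore noise-dominated for this quantity; the reemergence fine is
  located as the onset of sustained recovery — the smallest fine beyond
  which ensemble cooperation stays at or above 0.95 for every larger
  fine in the scan (0.95 tolerates about one partially invaded
  replicate out of five).

## Numerical choices

- **Fermi exponent clamping.** (Π_i − Π_j)·κ is clamped at ±700 before
  exponentiation; beyond the clamp the probability saturates exactly to
  0 or 1. With κ = 10 and accumulated payoffs, gaps of ~25 payoff units
  occur and would overflow a naive exponential.
- **Early absorption.** A monomorphic population cannot change under
  pairwise imitation (there is nothing else to copy), so once a single
  strategy occupies every site the run stops and the remaining fraction
  rows are filled with the constant state. This leaves every trailing
  average exactly equal to that of a continued run; it is an exact
  shortcut, not an approximation, and can be disabled
  (`early_absorb=False`).
- **Defector-free shortcut.** When no defectors remain, every player's
  total payoff is provably identical (all stage-1 pairs are mutual
  cooperation and stage 2 is inert), so every imitation draw is exactly
  1/2. The compiled inner loop then switches to a neutral-drift branch
  that consumes the random stream in the same pattern as the full
  branch — the trajectory is bit-identical to the unoptimized one.
- **Two engines.** The pure-Python update path (`elementary_update`,
  `mc_step`) is the readable reference and returns full update records;
  the numba path used by `run()` implements the same update. Both are
  checked against an independent brute-force payoff oracle, and against
  each other on deterministic fixation scenarios.
- **Threshold conventions.** "Cooperation extinct" means ensemble-mean
  cooperation < 0.01, "full cooperation" > 0.99, "defection eliminated"
  mean defector fraction < 0.01 — absorbing-state noise at finite L
  makes exact 0/1 unreliable. Grid scans report the first grid value
  satisfying the criterion, scanning in axis order without assuming
  monotonicity (the indirect fine sweep is reentrant);
  `find_threshold` optionally adds one finer refinement pass inside the
  bracketing interval.
- **Stabilization criterion** (for pooling punishment-event ledgers
  "before stabilization"): the earliest step at which every strategy
  fraction's range over the trailing 200 steps is ≤ 0.005; both window
  and tolerance are configurable, as no canonical criterion exists.

## Initial conditions

- `random`: each site draws one of the four strategies uniformly
  (a two-strategy CN/DN pool is available for classic spatial-PDG
  baselines; with β = γ = 0 the four-strategy run is payoff-equivalent
  to it, since the punishment flag is then inert).
- `block`: the lattice is tiled by uniform rectangles, by default four
  quadrants [CN, CP; DN, DP] read row-major. The arrangement is a
  package convention (no canonical one exists) and is configurable; a
  permutation of the layout only relabels which quadrant holds which
  strategy.

## Punishment-event ledger

For one configuration, each punisher's `acts_imposed` is the number of
defectors in its scope and each defector's `acts_received` the number
of punishers whose scope contains it (the scope relation is symmetric).
Total acts imposed always equal total acts received; per-punisher cost
is γ·acts and per-defector fine β·acts. Distributions keep only active
participants (≥ 1 act), matching the "defectors who are punished"
convention. Pooled over the pre-stabilization steps of a block-start
run at γ = 0.01, these ledgers exhibit the mechanism behind the
indirect mode's advantage: boundary defectors receive up to 16
punishments (direct mode caps at 8) while mean per-punisher total cost
rises by much less than one direct-scope load (8γ).

## What the simulations do and do not show

All quantitative claims in the test suite are properties of *this
model*: a homogeneous lattice, deterministic payoff tables, noiseless
imitation of a single neighbor, unconditional punishment. Passing tests
say nothing about heterogeneous networks, reputation-mediated indirect
sanctions, probabilistic or budget-limited punishment, antisocial
punishment, or mutation — all outside scope. Desk-scale thresholds are
reproducible under their stated seeds but sit within a finite-size
shift of the large-lattice values, as quantified above.
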
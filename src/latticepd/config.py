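"""Run configuration files, provenance-stamped CSV output, and the
deterministic lattice fixtures used by the test suite.

Config files are flat key-value YAML (JSON is a YAML subset, so both
dialects load).  Unknown keys are rejected and every numeric value is
validated through :class:`~latticepd.lattice.Params` before any run
starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .lattice import Params, Population, Strategy

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "make_fixture",
    "FIXTURE_NAMES",
    "write_csv",
]


class ConfigError(ValueError):
    """Raised for unknown, missing, or invalid configuration keys."""


_PARAM_FIELDS = {f.name for f in dataclasses.fields(Params)}


@dataclass(frozen=True)
class RunConfig:
    """A validated simulation configuration plus experiment settings."""

    params: Params
    replicates: int = 5
    init: str = "random"
    gamma_grid: tuple[float, ...] | None = None
    beta_grid: tuple[float, ...] | None = None
    snapshot_steps: tuple[int, ...] = ()
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        if self.init not in ("random", "block"):
            raise ConfigError(f"init must be 'random' or 'block', got {self.init!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        d.update(
            replicates=self.replicates,
            init=self.init,
            snapshot_steps=list(self.snapshot_steps),
            out_dir=self.out_dir,
        )
        if self.gamma_grid is not None:
            d["gamma_grid"] = list(self.gamma_grid)
        if self.beta_grid is not None:
            d["beta_grid"] = list(self.beta_grid)
        return d


_EXTRA_KEYS = {"replicates", "init", "gamma_grid", "beta_grid", "snapshot_steps", "out_dir"}


def config_from_dict(data: dict) -> RunConfig:
    """Build a validated RunConfig from a flat mapping."""
    if not isinstance(data, dict):
        raise ConfigError(f"config must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _PARAM_FIELDS - _EXTRA_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    param_kwargs = {k: v for k, v in data.items() if k in _PARAM_FIELDS}
    try:
        params = Params(**param_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid parameters: {exc}") from exc
    kwargs = {}
    for key in _EXTRA_KEYS:
        if key in data:
            v = data[key]
            if key in ("gamma_grid", "beta_grid"):
                v = tuple(float(x) for x in v)
            elif key == "snapshot_steps":
                v = tuple(int(x) for x in v)
            kwargs[key] = v
    return RunConfig(params=params, **kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(config: RunConfig, path) -> None:
    """Write a config so that :func:`load_config` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# deterministic hand-placed lattices for unit tests

def _lone_dn_in_cp() -> Population:
    grid = np.full((7, 7), int(Strategy.CP), dtype=np.int8)
    grid[3, 3] = int(Strategy.DN)
    return Population.from_grid(grid)


def _halves_cp_dn() -> Population:
    grid = np.empty((10, 10), dtype=np.int8)
    grid[:5] = int(Strategy.CP)
    grid[5:] = int(Strategy.DN)
    return Population.from_grid(grid)


def _quadrants() -> Population:
    grid = np.empty((8, 8), dtype=np.int8)
    grid[:4, :4] = int(Strategy.CN)
    grid[:4, 4:] = int(Strategy.CP)
    grid[4:, :4] = int(Strategy.DN)
    grid[4:, 4:] = int(Strategy.DP)
    return Population.from_grid(grid)


_FIXTURES = {
    "lone_DN_in_CP": _lone_dn_in_cp,
    "halves_CP_DN": _halves_cp_dn,
    "quadrants": _quadrants,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def make_fixture(name: str) -> Population:
    """Deterministic hand-specified lattices for payoff/ledger tests."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ConfigError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}") from None
    return builder()


def write_csv(frame, path, params: Params | None = None, extra: dict | None = None) -> None:
    """Write a DataFrame as CSV with a provenance header comment.

    The header lines start with '#' and record the full parameter set
    (and any extra metadata) so every output file is self-describing.
    """
    meta = {}
    if params is not None:
        meta.update(dataclasses.asdict(params))
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + ", ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        frame.to_csv(fh, index=False)
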
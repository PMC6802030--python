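"""Experiment grids, presets, configuration validation, and output plumbing.

An :class:`ExperimentGrid` expands lists of parameter values into a
Cartesian grid of scenarios; :func:`run_experiment` executes every cell and
writes aggregated summary tables, a sample event log per cell, and a plain
-text manifest sufficient to reproduce the run byte-for-byte.  Presets
re-create the package's reference experiments (fitness trajectories, the
regime-comparison grid, and the asymmetry power curves) at desk scale.

Seeds are derived purely from ``(base seed, cell index, replicate index)``,
so any single cell re-run in isolation reproduces its rows from the full
-grid run.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import MUTATION_DISTRIBUTIONS
from .simulate import (
    REGIMES,
    ReplicateResults,
    ScenarioConfig,
    replicate_rng,
    run_abiotic_matched,
    run_conflict,
    run_replicates,
    run_standard,
)

__all__ = [
    "ExperimentGrid",
    "run_experiment",
    "validate_config",
    "ConfigError",
    "fitness_trajectory",
    "PRESETS",
    "run_preset",
]

logger = logging.getLogger("fgmconflict")

#: Scenario parameters that an :class:`ExperimentGrid` can vary per cell.
GRID_AXES = ("regime", "lag_load", "mean_size", "omega", "f", "kappa", "r", "pop_size")


def _astuple(value):
    if isinstance(value, (list, tuple)):
        return tuple(value)
    return (value,)


@dataclass(frozen=True)
class ExperimentGrid:
    """A Cartesian grid of scenarios sharing iteration/replicate settings.

    Each axis takes a list of values; every combination becomes one cell
    (one :class:`~fgmconflict.simulate.ScenarioConfig`).  Cell indices
    enumerate combinations in the documented axis order
    (regime, lag_load, mean_size, omega, f, kappa, r, pop_size), last axis
    fastest.
    """

    regime: tuple = ("conflict",)
    lag_load: tuple = (0.2,)
    mean_size: tuple = (0.1,)
    omega: tuple = (0.5,)
    f: tuple = (1.0,)
    kappa: tuple = (1.0,)
    r: tuple = (1,)
    pop_size: tuple = (None,)
    mut_dist: str = "normal"
    n_iterations: int = 5000
    burn_in: int | None = None
    n_replicates: int = 200
    base_seed: int = 0

    def __post_init__(self):
        for axis in GRID_AXES:
            object.__setattr__(self, axis, _astuple(getattr(self, axis)))

    @property
    def n_cells(self) -> int:
        return math.prod(len(getattr(self, axis)) for axis in GRID_AXES)

    def cells(self):
        """Yield ``(cell_index, axis_values, ScenarioConfig)`` per cell."""
        axes = [getattr(self, axis) for axis in GRID_AXES]
        for index, combo in enumerate(itertools.product(*axes)):
            values = dict(zip(GRID_AXES, combo))
            pop = values.pop("pop_size")
            cfg = ScenarioConfig(
                **values,
                pop_size=(pop, pop),
                mut_dist=self.mut_dist,
                n_iterations=self.n_iterations,
                burn_in=self.burn_in,
                n_replicates=self.n_replicates,
                seed=self.base_seed,
            )
            yield index, values, cfg


def run_experiment(grid: ExperimentGrid, out_dir) -> pd.DataFrame:
    """Run every cell of ``grid`` and write tables + manifest under ``out_dir``.

    Writes ``summary.tsv`` (long format: cell, parameter columns, party,
    statistic, mean, se, n_replicates), one ``events_cell<i>.tsv`` sample
    event log (first replicate) per cell, and ``manifest.txt``.  Re-running
    with the same grid reproduces the outputs byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = []
    for index, values, cfg in grid.cells():
        t0 = time.perf_counter()
        res = run_replicates(cfg, cell=index, keep_first_log=True)
        agg = res.aggregate()
        agg.insert(0, "cell", index)
        for k, v in values.items():
            agg[k] = "inf" if (k == "pop_size" and v is None) else v
        tables.append(agg)
        res.first_log.to_csv(out / f"events_cell{index:03d}.tsv", sep="\t", index=False)
        logger.info(
            "cell %d/%d %s done in %.1fs",
            index + 1, grid.n_cells, values, time.perf_counter() - t0,
        )
    summary = pd.concat(tables, ignore_index=True)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    manifest = {
        "package": "fgmconflict",
        "version": __version__,
        "grid": {
            f.name: getattr(grid, f.name) for f in dataclasses.fields(grid)
        },
        "seed_derivation": (
            "numpy SeedSequence(entropy=base_seed, spawn_key=(cell, replicate, stream)); "
            "stream 0 = standard/conflict walk, stream 1 = paired abiotic walk"
        ),
        "n_cells": grid.n_cells,
    }
    (out / "manifest.txt").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return summary


class ConfigError(ValueError):
    """Raised by :func:`validate_config` with all problems collected."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


#: Baseline defaults filled in by :func:`validate_config`.
CONFIG_DEFAULTS = {
    "regime": "conflict",
    "lag_load": 0.2,
    "omega": 0.5,
    "mean_size": 0.1,
    "f": 1.0,
    "kappa": 1.0,
    "r": 1,
    "pop_size": (None, None),
    "mut_dist": "normal",
    "n_iterations": 5000,
    "burn_in": None,
    "n_replicates": 200,
    "seed": 0,
    "z_init": 0.0,
}


def validate_config(raw: dict) -> ScenarioConfig:
    """Range-check a raw key/value mapping and build a :class:`ScenarioConfig`.

    Problems are collected (not fail-fast) and raised together as a
    :class:`ConfigError` naming every offending field; missing keys fall
    back to the baseline defaults (conflict regime, lag load 0.2, mean
    mutation size 0.1, shape 1/2, infinite populations, f = kappa = r = 1).
    """
    errors: list[str] = []
    cfg = dict(CONFIG_DEFAULTS)
    unknown = set(raw) - set(cfg)
    for key in sorted(unknown):
        errors.append(f"unknown parameter {key!r}")
    cfg.update({k: v for k, v in raw.items() if k in cfg})

    def check(name, ok, message):
        if not ok:
            errors.append(f"{name}: {message} (got {cfg[name]!r})")

    def is_num(v):
        return isinstance(v, (int, float)) and not isinstance(v, bool) and math.isfinite(v)

    check("regime", cfg["regime"] in REGIMES, f"must be one of {REGIMES}")
    check("lag_load", is_num(cfg["lag_load"]) and 0.0 < cfg["lag_load"] < 1.0,
          "must lie in the open interval (0, 1)")
    for name in ("omega", "mean_size", "f", "kappa"):
        check(name, is_num(cfg[name]) and cfg[name] > 0.0, "must be a positive number")
    check("r", is_num(cfg["r"]) and cfg["r"] >= 1 and int(cfg["r"]) == cfg["r"],
          "mutational-input multiplier must be a positive integer")
    pop = cfg["pop_size"]
    if not isinstance(pop, (list, tuple)):
        pop = (pop, pop)
    pop = tuple(None if p in (None, "inf", "infinite") else p for p in pop)
    ok_pop = len(pop) == 2 and all(
        p is None or (is_num(p) and int(p) == p and p >= 2) for p in pop
    )
    check("pop_size", ok_pop, "each entry must be an integer >= 2 or 'inf'")
    if ok_pop:
        cfg["pop_size"] = tuple(None if p is None else int(p) for p in pop)
    check("mut_dist", cfg["mut_dist"] in MUTATION_DISTRIBUTIONS,
          f"must be one of {MUTATION_DISTRIBUTIONS}")
    check("n_iterations", is_num(cfg["n_iterations"]) and cfg["n_iterations"] >= 1
          and int(cfg["n_iterations"]) == cfg["n_iterations"],
          "must be a positive integer")
    check("burn_in", cfg["burn_in"] is None or (
        is_num(cfg["burn_in"]) and cfg["burn_in"] >= 0
        and int(cfg["burn_in"]) == cfg["burn_in"]),
        "must be a nonnegative integer or omitted")
    check("n_replicates", is_num(cfg["n_replicates"]) and cfg["n_replicates"] >= 1
          and int(cfg["n_replicates"]) == cfg["n_replicates"],
          "must be a positive integer")
    check("seed", isinstance(cfg["seed"], int) and not isinstance(cfg["seed"], bool),
          "must be an integer")
    check("z_init", is_num(cfg["z_init"]), "must be a finite number")
    if errors:
        raise ConfigError(errors)
    for name in ("r", "n_iterations", "n_replicates"):
        cfg[name] = int(cfg[name])
    if cfg["burn_in"] is not None:
        cfg["burn_in"] = int(cfg["burn_in"])
    return ScenarioConfig(**cfg)


def fitness_trajectory(config: ScenarioConfig, cell: int = 0) -> pd.DataFrame:
    """Mean party-1 fitness per iteration, averaged across replicates.

    Runs the scenario's replicates and samples fitness at the end of every
    iteration (burn-in included), giving the full adaptation trajectory.
    """
    n = config.total_iterations
    acc = np.zeros(n)
    for rep in range(config.n_replicates):
        rng = replicate_rng(config.seed, rep, stream=0, cell=cell)
        if config.regime == "standard":
            log = run_standard(config, rng)
        elif config.regime == "conflict":
            log = run_conflict(config, rng)
        else:
            clog = run_conflict(config.as_conflict(), rng)
            arng = replicate_rng(config.seed, rep, stream=1, cell=cell)
            log = run_abiotic_matched(clog, config, arng)
        k = len(log) // n
        acc += log["w1_after"].to_numpy()[k - 1 :: k]
    return pd.DataFrame(
        {"iteration": np.arange(n), "mean_fitness": acc / config.n_replicates}
    )


def _preset_figure2(seed, n_replicates, n_iterations, burn_in):
    """Fitness trajectories: standard, conflict from origin, conflict from
    party 1's optimum, and the paired abiotic control, at baseline
    parameters (lag load 0.2, mean mutation size 0.1, shape 1/2,
    infinite populations)."""
    base = dict(
        lag_load=0.2, omega=0.5, mean_size=0.1,
        n_iterations=n_iterations, burn_in=burn_in,
        n_replicates=n_replicates, seed=seed,
    )
    from .core import optimum_from_lagload

    o1 = optimum_from_lagload(0.8, 0.5, +1)
    scenarios = {
        "standard": ScenarioConfig(regime="standard", **base),
        "conflict_from_origin": ScenarioConfig(regime="conflict", **base),
        "conflict_from_optimum": ScenarioConfig(regime="conflict", z_init=o1, **base),
        "abiotic": ScenarioConfig(regime="abiotic_matched", **base),
    }
    parts = []
    for cell, (name, cfg) in enumerate(scenarios.items()):
        traj = fitness_trajectory(cfg, cell=cell)
        traj.insert(0, "scenario", name)
        parts.append(traj)
        logger.info("trajectory %s done", name)
    return pd.concat(parts, ignore_index=True), "trajectories.tsv"


def _preset_figure3(seed, n_replicates, n_iterations, burn_in):
    """Regime-comparison grid: equilibrium distance, fitness, fixation
    fraction and fixation size across lag loads and mutation sizes for the
    standard, conflict and abiotic regimes."""
    grid = ExperimentGrid(
        regime=("standard", "conflict", "abiotic_matched"),
        lag_load=(0.05, 0.2, 0.4),
        mean_size=(0.02, 0.1, 0.3),
        n_iterations=n_iterations,
        burn_in=burn_in,
        n_replicates=n_replicates,
        base_seed=seed,
    )
    return grid, None


def _preset_figure4a(seed, n_replicates, n_iterations, burn_in):
    """Power versus relative selection strength f (omega2 = omega1 / f)."""
    grid = ExperimentGrid(
        regime=("conflict",), f=(1.0, 2.0, 4.0, 8.0), mean_size=(0.05, 0.1, 0.3),
        n_iterations=n_iterations, burn_in=burn_in,
        n_replicates=n_replicates, base_seed=seed,
    )
    return grid, None


def _preset_figure4b(seed, n_replicates, n_iterations, burn_in):
    """Power versus relative mutational input r (equal fitness curves)."""
    grid = ExperimentGrid(
        regime=("conflict",), r=(1, 2, 4, 8), mean_size=(0.05, 0.1, 0.3),
        n_iterations=n_iterations, burn_in=burn_in,
        n_replicates=n_replicates, base_seed=seed,
    )
    return grid, None


def _preset_figure4c(seed, n_replicates, n_iterations, burn_in):
    """Power versus relative mutation size kappa (mbar1 = kappa * mbar2)."""
    grid = ExperimentGrid(
        regime=("conflict",), kappa=(0.25, 0.5, 1.0, 2.0, 4.0),
        mean_size=(0.05, 0.1, 0.3),
        n_iterations=n_iterations, burn_in=burn_in,
        n_replicates=n_replicates, base_seed=seed,
    )
    return grid, None


PRESETS = {
    "figure2": _preset_figure2,
    "figure3": _preset_figure3,
    "figure4a": _preset_figure4a,
    "figure4b": _preset_figure4b,
    "figure4c": _preset_figure4c,
}


def run_preset(
    name: str,
    out_dir,
    seed: int = 0,
    n_replicates: int = 200,
    n_iterations: int = 5000,
    burn_in: int | None = None,
) -> pd.DataFrame:
    """Run a named preset experiment at desk scale and write its tables."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result, filename = PRESETS[name](seed, n_replicates, n_iterations, burn_in)
    if isinstance(result, ExperimentGrid):
        return run_experiment(result, out)
    result.to_csv(out / filename, sep="\t", index=False)
    manifest = {
        "package": "fgmconflict",
        "version": __version__,
        "preset": name,
        "seed": seed,
        "n_replicates": n_replicates,
        "n_iterations": n_iterations,
        "burn_in": burn_in,
    }
    (out / "manifest.txt").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return result
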
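"""Adaptive-walk simulators: standard adaptation, two-party conflict, and the
magnitude-matched moving-optimum (abiotic) control.

The dynamics follow the strong-selection/weak-mutation regime: the population
is monomorphic between fixations, one mutation is under selection at a time,
and each proposal either fixes (shifting the joint phenotype ``z`` additively
by the mutation's effect) or is lost.

Regimes
-------
``standard``
    One party walks toward a single fixed optimum ``o1``; one proposal per
    iteration.
``conflict``
    Two parties share the phenotype ``z`` but hold optima on opposite sides
    of the origin.  Each iteration, party 1 makes ``r`` contiguous
    proposal/resolution rounds and party 2 makes one; a fair coin per
    iteration decides which block goes first.
``abiotic_matched``
    A single-party control paired to a completed conflict run: each
    iteration the optimum is displaced, in a random direction, by the same
    magnitude that party 2 shifted ``z`` in the paired conflict iteration
    (zero when party 2 fixed nothing), and the focal party then makes its
    own ``r`` rounds.  Conflict and control thus experience environmental
    change of identical magnitude, differing only in its direction.

Event logs
----------
Runs return a :class:`pandas.DataFrame` with one row per proposal, in
column order ``iteration, party, effect, s, fixed, z_after, w1_after,
w2_after, optimum1, optimum2`` (``w2_after``/``optimum2`` are NaN in
single-party regimes; ``optimum1`` tracks the moving optimum in the abiotic
regime).  Rows per iteration are constant within a run: 1 (standard),
``r + 1`` (conflict), ``r`` (abiotic).

Randomness
----------
Every run consumes a ``numpy.random.Generator``.  Per replicate, streams
are derived from ``(seed, cell, replicate, stream)`` via
``numpy.random.SeedSequence`` spawn keys, so any cell or replicate can be
re-run in isolation and reproduce its slice of a larger experiment exactly.
Within a run the stream is consumed in a fixed order (party 1 effects,
party 2 effects, party 1 fixation uniforms, party 2 fixation uniforms,
first-mover coins; the abiotic stream: direction coins, effects, uniforms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    MUTATION_DISTRIBUTIONS,
    Party,
    fitness,
    fixation_prob_finite,
    fixation_probability,
    optimum_from_lagload,
    selection_coefficient,
)
from .mutation import draw_effect, draw_effects, sigma_from_mean_size
from .summaries import EquilibriumSummary, fitness_power, summarize_window

__all__ = [
    "REGIMES",
    "ScenarioConfig",
    "WalkState",
    "EventRecord",
    "LOG_COLUMNS",
    "replicate_rng",
    "propose_and_resolve",
    "run_standard",
    "run_conflict",
    "run_abiotic_matched",
    "party2_net_shifts",
    "run_replicates",
    "ReplicateResults",
]

REGIMES = ("standard", "conflict", "abiotic_matched")

#: Column order of event-log data frames.
LOG_COLUMNS = (
    "iteration",
    "party",
    "effect",
    "s",
    "fixed",
    "z_after",
    "w1_after",
    "w2_after",
    "optimum1",
    "optimum2",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one simulation scenario.

    Parameters
    ----------
    regime
        ``"standard"``, ``"conflict"`` or ``"abiotic_matched"``.
    lag_load
        Shared lag load ``1 - w0`` at the curve intersection, in (0, 1);
        the conflict intensity.  Also places the standard/abiotic optimum.
    omega
        Party 1's fitness-curve shape; party 2's is ``omega / f``.
    mean_size
        Party 2's average absolute mutation size ``mbar2``; party 1's is
        ``kappa * mean_size``.  (With ``kappa = 1`` both parties share it.)
    f
        Relative selection strength, ``omega1 = f * omega2``.
    kappa
        Relative mutation size, ``mbar1 = kappa * mbar2``.
    r
        Relative mutational input: party 1 makes ``r`` proposal rounds per
        iteration for party 2's one.  Positive integer.
    pop_size
        ``(N1, N2)``; ``None`` entries mean effectively infinite.
    mut_dist
        Mutation-effect distribution family for both parties.
    n_iterations
        Length of the post-burn-in equilibrium window; the walk runs for
        ``burn_in + n_iterations`` iterations in total.
    burn_in
        Iterations discarded as the initial adaptation period.  ``None``
        defaults to ``round(250 / min(omega1, omega2))`` — the slower party
        sets the adaptation timescale.
    n_replicates
        Number of independent replicate walks.
    seed
        Base seed for all randomness.
    z_init
        Initial joint phenotype (origin by default).
    parties
        Optional explicit ``(Party,)`` or ``(Party, Party)`` tuple
        overriding the parties derived from the scalar parameters.
    """

    regime: str
    lag_load: float = 0.2
    omega: float = 0.5
    mean_size: float = 0.1
    f: float = 1.0
    kappa: float = 1.0
    r: int = 1
    pop_size: tuple[int | None, int | None] = (None, None)
    mut_dist: str = "normal"
    n_iterations: int = 5000
    burn_in: int | None = None
    n_replicates: int = 200
    seed: int = 0
    z_init: float = 0.0
    parties: tuple[Party, ...] | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if not (0.0 < self.lag_load < 1.0):
            raise ValueError(f"lag_load must lie in (0, 1), got {self.lag_load}")
        if not self.omega > 0.0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if not self.mean_size > 0.0:
            raise ValueError(f"mean_size must be positive, got {self.mean_size}")
        if not self.f > 0.0:
            raise ValueError(f"f must be positive, got {self.f}")
        if not self.kappa > 0.0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if int(self.r) != self.r or self.r < 1:
            raise ValueError(f"r must be a positive integer, got {self.r}")
        if self.mut_dist not in MUTATION_DISTRIBUTIONS:
            raise ValueError(
                f"mut_dist must be one of {MUTATION_DISTRIBUTIONS}, got {self.mut_dist!r}"
            )
        if self.n_iterations < 0:
            raise ValueError(f"n_iterations must be >= 0, got {self.n_iterations}")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError(f"burn_in must be >= 0, got {self.burn_in}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if not math.isfinite(self.z_init):
            raise ValueError(f"z_init must be finite, got {self.z_init}")
        if self.parties is not None and len(self.parties) not in (1, 2):
            raise ValueError("parties must hold one or two Party values")

    @property
    def w0(self) -> float:
        return 1.0 - self.lag_load

    def build_parties(self) -> tuple[Party, ...]:
        """Parties of this scenario (derived unless given explicitly).

        Party 1 gets the positive optimum, shape ``omega`` and mean
        mutation size ``kappa * mean_size``; party 2 (conflict only) the
        negative optimum, shape ``omega / f`` and mean size ``mean_size``.
        Single-party regimes use party 1's parameter values.
        """
        if self.parties is not None:
            return self.parties
        omega1 = self.omega
        p1 = Party(
            index=1,
            omega=omega1,
            optimum=optimum_from_lagload(self.w0, omega1, +1),
            sigma=sigma_from_mean_size(self.kappa * self.mean_size),
            pop_size=self.pop_size[0],
            mut_input=float(self.r),
            mut_dist=self.mut_dist,
        )
        if self.regime != "conflict":
            return (p1,)
        omega2 = self.omega / self.f
        p2 = Party(
            index=2,
            omega=omega2,
            optimum=optimum_from_lagload(self.w0, omega2, -1),
            sigma=sigma_from_mean_size(self.mean_size),
            pop_size=self.pop_size[1],
            mut_input=1.0,
            mut_dist=self.mut_dist,
        )
        return (p1, p2)

    @property
    def effective_burn_in(self) -> int:
        """Burn-in actually used: explicit value or ``250 / min(omega_i)``."""
        if self.burn_in is not None:
            return self.burn_in
        omegas = [self.omega]
        if self.regime in ("conflict", "abiotic_matched"):
            omegas.append(self.omega / self.f)
        if self.parties is not None:
            omegas = [p.omega for p in self.parties]
        return int(round(250.0 / min(omegas)))

    @property
    def total_iterations(self) -> int:
        return self.effective_burn_in + self.n_iterations

    def as_conflict(self) -> "ScenarioConfig":
        """The paired conflict scenario of an abiotic-matched control."""
        return replace(self, regime="conflict", parties=None)


@dataclass
class WalkState:
    """Mutable state of a walk: phenotype, per-party optima, iteration index."""

    z: float
    optima: list[float]
    iteration: int = 0


@dataclass(frozen=True)
class EventRecord:
    """One proposal/resolution event (one event-log row)."""

    iteration: int
    party_index: int
    effect: float
    s: float
    fixed: bool
    z_after: float
    w1_after: float
    w2_after: float = math.nan


def replicate_rng(
    seed: int, replicate: int, stream: int = 0, cell: int = 0
) -> np.random.Generator:
    """Generator for one (cell, replicate, stream) of an experiment.

    A pure function of its arguments: re-running a single replicate in
    isolation reproduces its stream from a full-grid run.  Stream 0 drives
    standard/conflict walks; stream 1 drives the abiotic control paired to
    the conflict run of the same replicate.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cell, replicate, stream))
    )


def propose_and_resolve(
    state: WalkState,
    party: Party,
    rng: np.random.Generator,
    other_party: Party | None = None,
) -> EventRecord:
    """Draw one mutation for ``party`` and resolve fixation, updating ``state``.

    Exactly one mutation is under selection at a time; on fixation the
    phenotype shifts additively by the mutation's effect.  The party's
    current optimum is taken from ``state.optima`` (it may be moving in the
    abiotic regime).
    """
    draw = draw_effect(party, rng)
    o = state.optima[party.index - 1]
    moved = replace(party, optimum=o) if o != party.optimum else party
    w_cur = fitness(state.z, moved)
    w_mut = fitness(state.z + draw.effect, moved)
    s = selection_coefficient(w_mut, w_cur)
    pi = fixation_probability(s, party.pop_size)
    fixed = rng.random() < pi
    if fixed:
        state.z += draw.effect
    w_self = w_mut if fixed else w_cur
    if other_party is not None:
        o_other = state.optima[other_party.index - 1]
        w_other = fitness(state.z, replace(other_party, optimum=o_other))
        if party.index == 1:
            w1, w2 = w_self, w_other
        else:
            w1, w2 = w_other, w_self
    else:
        w1, w2 = w_self, math.nan
    return EventRecord(
        iteration=state.iteration,
        party_index=party.index,
        effect=draw.effect,
        s=s,
        fixed=fixed,
        z_after=state.z,
        w1_after=w1,
        w2_after=w2,
    )


def _pfix(s: float, N: int | None) -> float:
    # scalar hot-path version of fixation_probability (no validation)
    if N is None:
        return -math.expm1(-2.0 * s) if s > 0.0 else 0.0
    return fixation_prob_finite(s, N)


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        LOG_COLUMNS,
        (np.int64, np.int64, float, float, bool, float, float, float, float, float),
    )})


def _frame(n_iter, rows_per_iter, party, eff, s, fixed, z, w1, w2, o1, o2):
    return pd.DataFrame(
        {
            "iteration": np.repeat(np.arange(n_iter, dtype=np.int64), rows_per_iter),
            "party": np.asarray(party, dtype=np.int64),
            "effect": np.asarray(eff, dtype=float),
            "s": np.asarray(s, dtype=float),
            "fixed": np.asarray(fixed, dtype=bool),
            "z_after": np.asarray(z, dtype=float),
            "w1_after": np.asarray(w1, dtype=float),
            "w2_after": np.asarray(w2, dtype=float),
            "optimum1": np.asarray(o1, dtype=float),
            "optimum2": np.asarray(o2, dtype=float),
        }
    )


def run_standard(config: ScenarioConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Single-party adaptive walk toward a fixed optimum.

    One proposal per iteration for ``burn_in + n_iterations`` iterations.
    """
    if config.regime != "standard":
        raise ValueError(f"run_standard requires regime 'standard', got {config.regime!r}")
    if rng is None:
        rng = replicate_rng(config.seed, 0)
    (p1,) = config.build_parties()
    n = config.total_iterations
    if n == 0:
        return _empty_log()
    o1, om1, N1 = p1.optimum, p1.omega, p1.pop_size
    eff = draw_effects(p1, n, rng).tolist()
    unif = rng.random(n).tolist()
    exp = math.exp
    s_l = []
    fixed_l = []
    z_l = []
    w1_l = []
    z = config.z_init
    for t in range(n):
        m = eff[t]
        d = o1 - z
        wc = exp(-om1 * d * d)
        zm = z + m
        d = o1 - zm
        wm = exp(-om1 * d * d)
        s = wm / wc - 1.0
        if N1 is None:
            fx = s > 0.0 and unif[t] < -math.expm1(-2.0 * s)
        else:
            fx = unif[t] < _pfix(s, N1)
        if fx:
            z = zm
            w = wm
        else:
            w = wc
        s_l.append(s)
        fixed_l.append(fx)
        z_l.append(z)
        w1_l.append(w)
    return _frame(n, 1, [1] * n, eff, s_l, fixed_l, z_l, w1_l,
                  [math.nan] * n, [o1] * n, [math.nan] * n)


def run_conflict(config: ScenarioConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Two-party conflict walk over the shared joint phenotype.

    Each iteration: party 1's ``r`` contiguous rounds and party 2's single
    round, block order decided by a fair coin per iteration.  Both parties'
    fitnesses are evaluated on the shared ``z`` after every event.
    """
    if config.regime != "conflict":
        raise ValueError(f"run_conflict requires regime 'conflict', got {config.regime!r}")
    if rng is None:
        rng = replicate_rng(config.seed, 0)
    parties = config.build_parties()
    if len(parties) != 2:
        raise ValueError("conflict regime requires two parties")
    p1, p2 = parties
    if not (p1.optimum > 0.0 and p2.optimum < 0.0):
        raise ValueError("party 1 must hold the positive optimum and party 2 the negative")
    n = config.total_iterations
    r = int(config.r)
    if n == 0:
        return _empty_log()
    o1, om1, N1 = p1.optimum, p1.omega, p1.pop_size
    o2, om2, N2 = p2.optimum, p2.omega, p2.pop_size
    eff1 = draw_effects(p1, (n, r), rng).tolist()
    eff2 = draw_effects(p2, n, rng).tolist()
    u1 = rng.random((n, r)).tolist()
    u2 = rng.random(n).tolist()
    first1 = (rng.random(n) < 0.5).tolist()
    exp = math.exp
    expm1 = math.expm1
    order_first = (True,) * r + (False,)
    order_last = (False,) + (True,) * r
    party_l = []
    eff_l = []
    s_l = []
    fixed_l = []
    z_l = []
    w1_l = []
    w2_l = []
    ap = party_l.append
    ae = eff_l.append
    as_ = s_l.append
    af = fixed_l.append
    az = z_l.append
    aw1 = w1_l.append
    aw2 = w2_l.append
    z = config.z_init
    for t in range(n):
        e1t = eff1[t]
        u1t = u1[t]
        j = 0
        for is_p1 in order_first if first1[t] else order_last:
            if is_p1:
                m = e1t[j]
                u = u1t[j]
                j += 1
                d = o1 - z
                wc = exp(-om1 * d * d)
                zm = z + m
                d = o1 - zm
                wm = exp(-om1 * d * d)
                s = wm / wc - 1.0
                if N1 is None:
                    fx = s > 0.0 and u < -expm1(-2.0 * s)
                else:
                    fx = u < _pfix(s, N1)
                if fx:
                    z = zm
                    w1 = wm
                else:
                    w1 = wc
                d = o2 - z
                w2 = exp(-om2 * d * d)
                ap(1)
            else:
                m = eff2[t]
                u = u2[t]
                d = o2 - z
                wc = exp(-om2 * d * d)
                zm = z + m
                d = o2 - zm
                wm = exp(-om2 * d * d)
                s = wm / wc - 1.0
                if N2 is None:
                    fx = s > 0.0 and u < -expm1(-2.0 * s)
                else:
                    fx = u < _pfix(s, N2)
                if fx:
                    z = zm
                    w2 = wm
                else:
                    w2 = wc
                d = o1 - z
                w1 = exp(-om1 * d * d)
                ap(2)
            ae(m)
            as_(s)
            af(fx)
            az(z)
            aw1(w1)
            aw2(w2)
    return _frame(n, r + 1, party_l, eff_l, s_l, fixed_l, z_l, w1_l, w2_l,
                  [o1] * (n * (r + 1)), [o2] * (n * (r + 1)))


def party2_net_shifts(conflict_log: pd.DataFrame, n_iterations: int) -> np.ndarray:
    """Net phenotype shift contributed by party 2's fixations, per iteration."""
    shifts = np.zeros(n_iterations)
    sub = conflict_log[(conflict_log["party"] == 2) & conflict_log["fixed"]]
    np.add.at(shifts, sub["iteration"].to_numpy(), sub["effect"].to_numpy())
    return shifts


def run_abiotic_matched(
    conflict_log: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Moving-optimum control paired to a completed conflict run.

    Each iteration ``t`` the optimum is displaced by the magnitude of the
    phenotype change party 2 caused at iteration ``t`` of the paired run
    (zero when party 2 fixed nothing), in a direction chosen by fair coin;
    the focal party (a copy of party 1) then makes its ``r`` rounds.  The
    direction coin is drawn every iteration — even zero-displacement ones —
    so the stream layout is independent of the paired run's content.
    """
    if config.regime != "abiotic_matched":
        raise ValueError(
            f"run_abiotic_matched requires regime 'abiotic_matched', got {config.regime!r}"
        )
    if rng is None:
        rng = replicate_rng(config.seed, 0, stream=1)
    n = config.total_iterations
    if n == 0:
        return _empty_log()
    n_logged = int(conflict_log["iteration"].max()) + 1 if len(conflict_log) else 0
    if n_logged < n:
        raise ValueError(
            f"paired conflict log covers {n_logged} iterations, need {n}"
        )
    (p1,) = config.build_parties()
    r = int(config.r)
    om1, N1 = p1.omega, p1.pop_size
    shifts = np.abs(party2_net_shifts(conflict_log, n)).tolist()
    signs = np.where(rng.random(n) < 0.5, -1.0, 1.0).tolist()
    eff = draw_effects(p1, (n, r), rng).tolist()
    unif = rng.random((n, r)).tolist()
    exp = math.exp
    expm1 = math.expm1
    eff_l = []
    s_l = []
    fixed_l = []
    z_l = []
    w1_l = []
    o_l = []
    z = config.z_init
    o1 = p1.optimum
    for t in range(n):
        o1 += signs[t] * shifts[t]
        et = eff[t]
        ut = unif[t]
        for j in range(r):
            m = et[j]
            d = o1 - z
            wc = exp(-om1 * d * d)
            zm = z + m
            d = o1 - zm
            wm = exp(-om1 * d * d)
            s = wm / wc - 1.0
            if N1 is None:
                fx = s > 0.0 and ut[j] < -expm1(-2.0 * s)
            else:
                fx = ut[j] < _pfix(s, N1)
            if fx:
                z = zm
                w1 = wm
            else:
                w1 = wc
            eff_l.append(m)
            s_l.append(s)
            fixed_l.append(fx)
            z_l.append(z)
            w1_l.append(w1)
            o_l.append(o1)
    nr = n * r
    return _frame(n, r, [1] * nr, eff_l, s_l, fixed_l, z_l, w1_l,
                  [math.nan] * nr, o_l, [math.nan] * nr)


@dataclass
class ReplicateResults:
    """Per-replicate equilibrium summaries of one scenario.

    ``per_replicate`` holds one row per (replicate, party) with the
    equilibrium statistics and, for two-party runs, the replicate's fitness
    power (repeated on both party rows).  For the abiotic regime,
    ``paired`` holds the results of the paired conflict runs.
    """

    config: ScenarioConfig
    per_replicate: pd.DataFrame
    paired: "ReplicateResults | None" = None
    first_log: pd.DataFrame | None = None

    def aggregate(self) -> pd.DataFrame:
        from .summaries import aggregate_replicates

        return aggregate_replicates(self.per_replicate)

    def stat(self, name: str, party: int = 1) -> tuple[float, float]:
        """(mean, standard error) of a per-replicate statistic for ``party``."""
        vals = self.per_replicate.loc[
            self.per_replicate["party"] == party, name
        ].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            return math.nan, math.nan
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
        return float(np.mean(vals)), se

    def power(self) -> tuple[float, float]:
        """(mean, standard error) of party 1's fitness power across replicates."""
        return self.stat("power_party1", party=1)


def _summary_rows(replicate, summaries, power):
    rows = []
    for p, s in sorted(summaries.items()):
        rows.append(
            {
                "replicate": replicate,
                "party": p,
                "mean_distance": s.mean_distance,
                "mean_fitness": s.mean_fitness,
                "fixation_fraction": s.fixation_fraction,
                "mean_fixation_size": s.mean_fixation_size,
                "mean_lag_load": s.mean_lag_load,
                "power_party1": power,
            }
        )
    return rows


def run_replicates(
    config: ScenarioConfig, cell: int = 0, keep_first_log: bool = False
) -> ReplicateResults:
    """Run all replicates of a scenario and summarize the equilibrium window.

    For ``abiotic_matched``, each replicate first runs its paired conflict
    walk (stream 0) and then the control walk on an independent stream
    (stream 1); summaries of the paired conflict runs are returned in
    ``ReplicateResults.paired`` at no extra simulation cost.
    """
    burn = config.effective_burn_in
    window = config.n_iterations
    rows = []
    paired_rows = []
    first_log = None
    for rep in range(config.n_replicates):
        rng = replicate_rng(config.seed, rep, stream=0, cell=cell)
        if config.regime == "standard":
            log = run_standard(config, rng)
        elif config.regime == "conflict":
            log = run_conflict(config, rng)
        else:
            clog = run_conflict(config.as_conflict(), rng)
            csum = summarize_window(clog, burn, window)
            paired_rows.extend(
                _summary_rows(rep, csum, fitness_power(csum).power_party1)
            )
            arng = replicate_rng(config.seed, rep, stream=1, cell=cell)
            log = run_abiotic_matched(clog, config, arng)
        summ = summarize_window(log, burn, window)
        power = fitness_power(summ).power_party1 if len(summ) == 2 else math.nan
        rows.extend(_summary_rows(rep, summ, power))
        if keep_first_log and first_log is None:
            first_log = log
    results = ReplicateResults(
        config=config,
        per_replicate=pd.DataFrame(rows),
        first_log=first_log,
    )
    if paired_rows:
        results.paired = ReplicateResults(
            config=config.as_conflict(), per_replicate=pd.DataFrame(paired_rows)
        )
    return results
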
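"""Closed-form mathematics of the one-trait geometric model.

This module is the pure maths layer shared by the simulators: the Gaussian
fitness function, the placement of party optima from a shared lag load, the
selection coefficient of a new mutation, and Kimura's fixation probabilities
for infinite and finite haploid populations.

Conventions
-----------
A *party* is one evolving side of a (possibly two-sided) interaction over a
single joint phenotype ``z``.  Party ``i`` has a Gaussian fitness curve

    w_i(z) = exp(-omega_i * (o_i - z)**2)

peaking at 1 at its optimum ``o_i``; the shape parameter ``omega_i`` sets how
fast fitness falls off with distance.  In a two-party conflict the two curves
intersect at the origin ``z = 0`` with common fitness ``w0``; the shared
*lag load* ``1 - w0`` measures the intensity of conflict, and party 1 is
assigned the positive optimum by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MUTATION_DISTRIBUTIONS",
    "Party",
    "ConflictGeometry",
    "fitness",
    "optimum_from_lagload",
    "selection_coefficient",
    "fixation_prob_infinite",
    "fixation_prob_finite",
    "fixation_probability",
]

#: Supported mutation-effect distributions (see :mod:`fgmconflict.mutation`).
MUTATION_DISTRIBUTIONS = ("normal", "uniform", "exponential")

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)

# |4Ns| below this uses the neutral limit 1/(2N) of the finite-N formula.
_NEUTRAL_BRANCH = 1e-8


@dataclass(frozen=True)
class Party:
    """Parameters of one evolving party.

    Parameters
    ----------
    index
        Party label, 1 or 2.  In two-party scenarios party 1 holds the
        positive optimum and party 2 the negative one.
    omega
        Shape of the Gaussian fitness curve (> 0); larger values mean
        narrower curves and stronger selection per unit distance.
    optimum
        Position ``o_i`` of the fitness peak, in phenotype units.
    sigma
        Scale of the mutation-effect distribution (> 0).  For all supported
        distributions the mean absolute effect is ``sigma * sqrt(2/pi)``
        (the half-normal mean), so distributions are compared at matched
        average mutation size.
    pop_size
        Haploid population size ``N_i`` (>= 2), or ``None`` for the
        effectively infinite-population limit where drift is negligible.
    mut_input
        Relative mutational input (number of mutations this party tests per
        iteration relative to the baseline of one); kept as metadata, the
        simulator's ``r`` parameter controls the actual round counts.
    mut_dist
        One of ``"normal"``, ``"uniform"``, ``"exponential"``.
    """

    index: int
    omega: float
    optimum: float
    sigma: float
    pop_size: int | None = None
    mut_input: float = 1.0
    mut_dist: str = "normal"

    def __post_init__(self) -> None:
        if self.index not in (1, 2):
            raise ValueError(f"party index must be 1 or 2, got {self.index}")
        if not (self.omega > 0.0 and math.isfinite(self.omega)):
            raise ValueError(f"omega must be positive and finite, got {self.omega}")
        if not (self.sigma > 0.0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")
        if not math.isfinite(self.optimum):
            raise ValueError(f"optimum must be finite, got {self.optimum}")
        if self.pop_size is not None:
            if int(self.pop_size) != self.pop_size or self.pop_size < 2:
                raise ValueError(
                    f"pop_size must be an integer >= 2 or None (infinite), got {self.pop_size}"
                )
        if not self.mut_input > 0.0:
            raise ValueError(f"mut_input must be positive, got {self.mut_input}")
        if self.mut_dist not in MUTATION_DISTRIBUTIONS:
            raise ValueError(
                f"mut_dist must be one of {MUTATION_DISTRIBUTIONS}, got {self.mut_dist!r}"
            )

    @property
    def mean_mutation_size(self) -> float:
        """Average absolute mutation effect, ``sigma * sqrt(2/pi)``."""
        return self.sigma * _SQRT_2_OVER_PI


@dataclass(frozen=True)
class ConflictGeometry:
    """Geometry of a two-party conflict: intersection fitness and lag load.

    The two fitness curves intersect at the origin with common fitness
    ``w0``; the shared lag load ``1 - w0`` is the conflict intensity.
    """

    w0: float
    origin: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.w0 < 1.0):
            raise ValueError(f"w0 must lie in (0, 1), got {self.w0}")

    @classmethod
    def from_lag_load(cls, lag_load: float) -> "ConflictGeometry":
        if not (0.0 < lag_load < 1.0):
            raise ValueError(f"lag_load must lie in (0, 1), got {lag_load}")
        return cls(w0=1.0 - lag_load)

    @property
    def lag_load(self) -> float:
        return 1.0 - self.w0

    def optimum(self, omega: float, sign: int) -> float:
        """Optimum for a party with shape ``omega`` on the given side."""
        return optimum_from_lagload(self.w0, omega, sign)


def fitness(z: float, party: Party) -> float:
    """Gaussian fitness of ``party`` at joint phenotype ``z``.

    Returns ``exp(-omega * (optimum - z)**2)``, which is 1 exactly at the
    optimum and strictly decreasing in distance from it.  May underflow to
    0.0 at astronomically large distances.
    """
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    d = party.optimum - z
    return math.exp(-party.omega * d * d)


def optimum_from_lagload(w0: float, omega: float, sign: int = 1) -> float:
    """Optimum position giving intersection fitness ``w0`` at the origin.

    Solves ``exp(-omega * o**2) = w0`` for ``o``, i.e.
    ``o = sign * sqrt(-ln(w0) / omega)``.  ``sign`` selects the side of the
    origin (+1 for party 1, -1 for party 2 by convention).
    """
    if not (0.0 < w0 < 1.0):
        raise ValueError(f"w0 must lie in (0, 1), got {w0}")
    if not omega > 0.0:
        raise ValueError(f"omega must be positive, got {omega}")
    if sign not in (1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    return sign * math.sqrt(-math.log(w0) / omega)


def selection_coefficient(w_mutant: float, w_current: float) -> float:
    """Selection coefficient ``s = w_mutant / w_current - 1``.

    Positive when the mutant is fitter than the current (monomorphic)
    population, zero when equal.  ``w_current`` must be strictly positive;
    a zero arises only from fitness underflow at extreme distances, and a
    clear error beats a silent NaN there.
    """
    if not w_current > 0.0:
        raise ValueError(
            f"current fitness must be positive, got {w_current} (fitness underflow?)"
        )
    return w_mutant / w_current - 1.0


def fixation_prob_infinite(s: float) -> float:
    """Fixation probability of a new mutation in an effectively infinite population.

    ``1 - exp(-2s)`` for beneficial mutations (s > 0); deleterious and
    neutral mutations (s <= 0) never fix without drift.
    """
    if not math.isfinite(s):
        raise ValueError(f"s must be finite, got {s}")
    if s <= 0.0:
        return 0.0
    return -math.expm1(-2.0 * s)


def fixation_prob_finite(s: float, N: int) -> float:
    """Fixation probability of a new mutation in a haploid population of size ``N``.

    ``(1 - exp(-2s)) / (1 - exp(-4Ns))`` for any finite ``s``; deleterious
    mutations can still fix by drift.  Continuous at ``s = 0`` with the
    neutral limit ``1/(2N)``, used whenever ``|4Ns| < 1e-8``.
    """
    if not math.isfinite(s):
        raise ValueError(f"s must be finite, got {s}")
    if N is None or not N >= 2 or int(N) != N:
        raise ValueError(f"N must be an integer >= 2, got {N}")
    x = 4.0 * N * s
    if abs(x) < _NEUTRAL_BRANCH:
        return 1.0 / (2.0 * N)
    if x < -700.0:
        # denominator overflows; use (1-e^{-2s})/(1-e^{-4Ns}) ~ e^{4Ns-2s}(1-e^{2s})
        return math.exp(x - 2.0 * s) * (-math.expm1(2.0 * s))
    return math.expm1(-2.0 * s) / math.expm1(-x)


def fixation_probability(s: float, pop_size: int | None = None) -> float:
    """Dispatch to the infinite- or finite-population formula."""
    if pop_size is None:
        return fixation_prob_infinite(s)
    return fixation_prob_finite(s, pop_size)
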
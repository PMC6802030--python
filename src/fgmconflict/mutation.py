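"""Mutation-effect distributions for the joint phenotype.

Mutations cause additive, unbiased (zero-mean) shifts of the trait ``z``.
Three effect distributions are supported, all parameterised so that the
mean absolute effect equals the same average mutation size

    mbar = sigma * sqrt(2 / pi)

(the mean of a half-normal with scale ``sigma``), so that results under
different distributions are comparable at matched average mutation size:

``normal``
    effect ~ Normal(0, sigma).
``uniform``
    effect ~ Uniform(-b, b) with ``b = 2 * mbar``, since E|U(-b, b)| = b/2.
``exponential``
    |effect| ~ Exponential(mean = mbar) with an independent fair sign
    (a symmetric, Laplace-like construction).

Draw order is fixed and documented per distribution (for ``exponential``:
all magnitudes first, then all signs), so a given generator state always
yields the same effect sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Party

__all__ = [
    "MutationDraw",
    "mean_size_from_sigma",
    "sigma_from_mean_size",
    "draw_effects",
    "draw_effect",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class MutationDraw:
    """One proposed mutation: a signed additive shift of the joint phenotype."""

    effect: float
    magnitude: float
    party_index: int


def mean_size_from_sigma(sigma: float) -> float:
    """Average absolute mutation size ``sigma * sqrt(2/pi)``."""
    if not sigma > 0.0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return sigma * _SQRT_2_OVER_PI


def sigma_from_mean_size(mean_size: float) -> float:
    """Inverse of :func:`mean_size_from_sigma` (exact round trip)."""
    if not mean_size > 0.0:
        raise ValueError(f"mean_size must be positive, got {mean_size}")
    return mean_size / _SQRT_2_OVER_PI


def draw_effects(party: Party, size, rng: np.random.Generator) -> np.ndarray:
    """Draw an array of signed mutation effects for ``party``.

    Parameters
    ----------
    party
        Supplies the scale ``sigma`` and the distribution family.
    size
        Output shape (as for numpy's samplers).
    rng
        A ``numpy.random.Generator``; consumed in a fixed, documented order.
    """
    dist = party.mut_dist
    if dist == "normal":
        return rng.normal(0.0, party.sigma, size)
    if dist == "uniform":
        b = 2.0 * party.mean_mutation_size
        return rng.uniform(-b, b, size)
    if dist == "exponential":
        magnitude = rng.exponential(party.mean_mutation_size, size)
        sign = np.where(rng.random(size) < 0.5, -1.0, 1.0)
        return magnitude * sign
    raise ValueError(f"unknown mutation distribution {dist!r}")


def draw_effect(party: Party, rng: np.random.Generator) -> MutationDraw:
    """Draw a single mutation as a :class:`MutationDraw`."""
    effect = float(draw_effects(party, (), rng))
    return MutationDraw(effect=effect, magnitude=abs(effect), party_index=party.index)
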
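"""Twelve-reaction nearest-neighbour collaborative methylation system.

A CpG dyad is unmethylated (u), hemimethylated (h) or methylated (m).
Non-collaborative reactions involve a single target CpG; collaborative
reactions additionally involve a mediator CpG that must be a nearest
neighbour of the target on the (circular) lattice and is unchanged by the
reaction.  All twelve rate constants are generated from three parameters:
a rate scale ``a``, a collaborativity strength ``x`` and a methylation
strength ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "U",
    "H",
    "M",
    "STATE_CHARS",
    "Params",
    "ReactionRates",
    "rates_from_params",
    "site_propensities",
]

# internal integer codes for the three dyad states
U, H, M = 0, 1, 2
STATE_CHARS = "uhm"


class ParameterError(ValueError):
    """Raised for parameter values outside the model's domain."""


@dataclass(frozen=True)
class Params:
    """Model parameters.

    Attributes
    ----------
    a : float
        Overall rate scale (time^-1), ``a > 0``.
    x : float
        Collaborativity strength (dimensionless), ``x >= 0``.  ``x < 1``
        means non-collaborative reactions dominate.
    y : float
        Methylation strength (dimensionless), ``y >= 0``.  ``y > 1``
        means methylation dominates demethylation.
    """

    a: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ParameterError(f"rate scale a must be positive, got {self.a}")
        if self.x < 0:
            raise ParameterError(f"collaborativity x must be >= 0, got {self.x}")
        if self.y < 0:
            raise ParameterError(f"methylation strength y must be >= 0, got {self.y}")


@dataclass(frozen=True)
class ReactionRates:
    """Per-reaction rate constants (time^-1).

    Semantics (target transition; '+' marks the mediator):

    ==== ===============================
    k1   u -> h
    k2   h -> m
    k3   m -> h
    k4   h -> u
    k5   u + h -> h + h
    k6   u + m -> h + m
    k7   h + h -> m + h
    k8   h + m -> m + m
    k9   m + h -> h + h
    k10  m + u -> h + u
    k11  h + h -> u + h
    k12  h + u -> u + u
    ==== ===============================
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float
    k11: float
    k12: float

    def __post_init__(self) -> None:
        for name, val in self.__dict__.items():
            if val < 0:
                raise ParameterError(f"rate {name} must be >= 0, got {val}")

    def as_array(self) -> np.ndarray:
        """Rates as a float64 array with ``arr[i-1] == k_i``."""
        return np.array(
            [self.k1, self.k2, self.k3, self.k4, self.k5, self.k6,
             self.k7, self.k8, self.k9, self.k10, self.k11, self.k12],
            dtype=np.float64,
        )


def rates_from_params(p: Params) -> ReactionRates:
    """Map ``(a, x, y)`` to the twelve reaction rates.

    Non-collaborative demethylation runs at ``a`` (k3 = k4), non-collaborative
    methylation at ``a*y`` (k1 = k2), collaborative demethylation at ``a*x``
    (k9..k12) and collaborative methylation at ``a*x*y`` (k5..k8).
    """
    a, x, y = p.a, p.x, p.y
    return ReactionRates(
        k1=a * y, k2=a * y,
        k3=a, k4=a,
        k5=a * x * y, k6=a * x * y, k7=a * x * y, k8=a * x * y,
        k9=a * x, k10=a * x, k11=a * x, k12=a * x,
    )


def site_propensities(
    pattern: np.ndarray, i: int, r: ReactionRates
) -> list[tuple[int, float]]:
    """Exit channels of site ``i`` given its two circular neighbours.

    Each site has exactly two directed neighbour slots (left and right); for
    N = 2 the single other site fills both slots and is counted twice, which
    keeps the finite lattice consistent with the factor-of-two structure of
    the mean-field effective rates.

    Returns a list of ``(new_state, total_propensity)`` pairs.  There is
    never a direct u <-> m channel.
    """
    pattern = np.asarray(pattern)
    n = pattern.shape[0]
    if not (0 <= i < n):
        raise IndexError(f"site index {i} out of range for N={n}")
    left = pattern[(i - 1) % n]
    right = pattern[(i + 1) % n]
    n_u = int(left == U) + int(right == U)
    n_h = int(left == H) + int(right == H)
    n_m = int(left == M) + int(right == M)
    s = pattern[i]
    if s == U:
        return [(H, r.k1 + r.k5 * n_h + r.k6 * n_m)]
    if s == H:
        return [
            (M, r.k2 + r.k7 * n_h + r.k8 * n_m),
            (U, r.k4 + r.k11 * n_h + r.k12 * n_u),
        ]
    if s == M:
        return [(H, r.k3 + r.k9 * n_h + r.k10 * n_u)]
    raise ValueError(f"invalid state code {s!r} at site {i}")
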
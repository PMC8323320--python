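"""Colony-trait genetic parameters for honey bees.

Honey-bee colony phenotypes are driven by two correlated genetic effects:
a *direct* effect contributed by the worker group and a *maternal* effect
contributed by the queen heading the colony,

    y = mean(a_W) + m_Q + e.

Because the workers of one colony are a family of super-sisters and
half-sisters (the queen mates with many drones reared from a group of
sister drone-producing queens), the phenotypic variance involves the mean
numerator relationship ``A_ii`` between two workers of one colony:

    sigma_ph^2 = A_ii * sigma_a^2 + sigma_m^2 + sigma_am + sigma_e^2.

From the base (co)variance components this module derives the phenotypic
variance, the direct and maternal heritabilities, the genetic correlation,
the genetic variances of queens (sigma_Q^2 = sigma_a^2 + sigma_m^2 +
2*sigma_am) and worker groups (sigma_W^2 = A_ii * sigma_Q^2, the
large-group limit), and the heritabilities of the two selection criteria:
colony-based selection (h_CBS^2 = sigma_W^2 / sigma_ph^2) and genomic
preselection on the queen's own effects (h_GPS^2 = sigma_Q^2 / sigma_ph^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraitBase",
    "TraitParameters",
    "derive_trait_parameters",
    "MOD",
    "HGC",
    "PRESETS",
]

#: Mean numerator relationship between two workers of one colony for a
#: non-inbred queen mated to 12 drones reared from 8 unrelated DPQ.
DEFAULT_A_II = 0.32


class InvalidParametersError(ValueError):
    """Raised when (co)variance components violate their constraints."""


@dataclass(frozen=True)
class TraitBase:
    """Base (co)variance components of a direct+maternal colony trait.

    Parameters
    ----------
    sigma_a2 : float
        Additive genetic variance of the direct (worker) effect.
    sigma_m2 : float
        Additive genetic variance of the maternal (queen) effect.
    sigma_am : float
        Additive genetic covariance between direct and maternal effects.
    sigma_e2 : float
        Residual (non-heritable) variance of the colony phenotype.
    A_ii : float
        Mean numerator relationship between two workers of one colony.
    """

    sigma_a2: float
    sigma_m2: float
    sigma_am: float
    sigma_e2: float
    A_ii: float = DEFAULT_A_II

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_m2 < 0 or self.sigma_e2 < 0:
            raise InvalidParametersError("variance components must be non-negative")
        if self.sigma_am**2 > self.sigma_a2 * self.sigma_m2 + 1e-12:
            raise InvalidParametersError(
                "sigma_am^2 > sigma_a2*sigma_m2: V_a is not positive semidefinite"
            )
        if not 0.0 < self.A_ii <= 1.0:
            raise InvalidParametersError("A_ii must be in (0, 1]")

    @property
    def V_a(self) -> np.ndarray:
        """2x2 additive genetic covariance matrix of (direct, maternal)."""
        return np.array(
            [[self.sigma_a2, self.sigma_am], [self.sigma_am, self.sigma_m2]]
        )


@dataclass(frozen=True)
class TraitParameters:
    """All derived genetic parameters of a colony trait."""

    base: TraitBase
    sigma_ph2: float
    h_a2: float
    h_m2: float
    r_G: float
    sigma_Q2: float
    sigma_W2: float
    h_CBS2: float
    h_GPS2: float

    def as_dict(self) -> dict[str, float]:
        b = self.base
        return {
            "sigma_a2": b.sigma_a2,
            "sigma_m2": b.sigma_m2,
            "sigma_am": b.sigma_am,
            "sigma_e2": b.sigma_e2,
            "A_ii": b.A_ii,
            "sigma_ph2": self.sigma_ph2,
            "h_a2": self.h_a2,
            "h_m2": self.h_m2,
            "r_G": self.r_G,
            "sigma_Q2": self.sigma_Q2,
            "sigma_W2": self.sigma_W2,
            "h_CBS2": self.h_CBS2,
            "h_GPS2": self.h_GPS2,
        }


def derive_trait_parameters(base: TraitBase) -> TraitParameters:
    """Derive all honey-bee-specific genetic parameters from base components.

    Closed-form: the phenotypic variance weights the direct variance by the
    mean worker-worker relationship; heritabilities of the direct and
    maternal effects are ``A_ii*sigma_a2/sigma_ph2`` and
    ``sigma_m2/sigma_ph2``; the queen-criterion heritability is
    ``sigma_Q2/sigma_ph2``.

    Raises
    ------
    InvalidParametersError
        If the base components violate their invariants (checked on
        construction of :class:`TraitBase`).
    """
    sigma_ph2 = (
        base.A_ii * base.sigma_a2 + base.sigma_m2 + base.sigma_am + base.sigma_e2
    )
    if sigma_ph2 <= 0:
        raise InvalidParametersError("phenotypic variance must be positive")
    sigma_Q2 = base.sigma_a2 + base.sigma_m2 + 2.0 * base.sigma_am
    if sigma_Q2 < -1e-12:
        raise InvalidParametersError("queen genetic variance is negative")
    sigma_Q2 = max(sigma_Q2, 0.0)
    sigma_W2 = base.A_ii * sigma_Q2
    denom = math.sqrt(base.sigma_a2 * base.sigma_m2)
    r_G = base.sigma_am / denom if denom > 0 else 0.0
    return TraitParameters(
        base=base,
        sigma_ph2=sigma_ph2,
        h_a2=base.A_ii * base.sigma_a2 / sigma_ph2,
        h_m2=base.sigma_m2 / sigma_ph2,
        r_G=r_G,
        sigma_Q2=sigma_Q2,
        sigma_W2=sigma_W2,
        h_CBS2=sigma_W2 / sigma_ph2,
        h_GPS2=sigma_Q2 / sigma_ph2,
    )


#: Moderate negative direct-maternal correlation preset (honey-yield-like).
MOD = TraitBase(sigma_a2=2.0, sigma_m2=1.0, sigma_am=-0.5, sigma_e2=1.0)

#: High negative direct-maternal correlation preset.
HGC = TraitBase(sigma_a2=2.0, sigma_m2=1.0, sigma_am=-1.0, sigma_e2=1.0)

PRESETS: dict[str, TraitBase] = {"MOD": MOD, "HGC": HGC}
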
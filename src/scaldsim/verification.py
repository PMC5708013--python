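"""Closed-form conduction solutions used to verify the numerical scheme.

These oracles are independent of the finite-difference solver: the
semi-infinite half-space solution checks transient conduction against the
error-function profile, and the effusivity-weighted contact temperature
checks the instantaneous interface temperature of two bodies brought into
perfect contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .materials import InvalidParameterError

__all__ = [
    "HalfSpaceProblem",
    "half_space_temperature",
    "contact_temperature",
    "thermal_effusivity",
]


@dataclass(frozen=True)
class HalfSpaceProblem:
    """Semi-infinite solid, uniform initial temperature, surface held fixed."""

    a: float  # thermal diffusivity, m2/s
    T_initial: float  # degC
    T_surface: float  # degC

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidParameterError("diffusivity must be positive")


def half_space_temperature(p: HalfSpaceProblem, x, t: float):
    """T(x, t) = T_s + (T_i - T_s) * erf(x / (2 sqrt(a t))).

    ``x`` may be a scalar or array of depths (m, >= 0); ``t`` > 0 s.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise InvalidParameterError("depth must be non-negative")
    if t <= 0:
        raise InvalidParameterError("time must be positive")
    eta = x_arr / (2.0 * math.sqrt(p.a * t))
    T = p.T_surface + (p.T_initial - p.T_surface) * erf(eta)
    return float(T) if np.isscalar(x) else T


def thermal_effusivity(k: float, rhoC: float) -> float:
    """b = sqrt(k * rho * C), W s^1/2/(m2 K)."""
    if k <= 0 or rhoC <= 0:
        raise InvalidParameterError("properties must be positive")
    return math.sqrt(k * rhoC)


def contact_temperature(
    k1: float, rhoC1: float, T1: float, k2: float, rhoC2: float, T2: float
) -> float:
    """Interface temperature of two semi-infinite bodies in perfect contact.

    Effusivity-weighted mean (b1*T1 + b2*T2)/(b1 + b2); it is attained
    instantaneously and held while both bodies behave as half-spaces.
    """
    b1 = thermal_effusivity(k1, rhoC1)
    b2 = thermal_effusivity(k2, rhoC2)
    return (b1 * T1 + b2 * T2) / (b1 + b2)
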
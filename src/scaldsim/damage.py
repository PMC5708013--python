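"""Arrhenius thermal-injury kinetics (Henriques-Moritz damage integral).

The damage index is Omega = -ln(C_tau/C_0), the negative log of the fraction
of undamaged cells.  Its rate follows first-order Arrhenius kinetics,

    dOmega/dt = P * exp(-dE / (R*T)),

with the classic hot-water constants P = 3.1e98 1/s and dE = 6.28e5 J/mol
(frequently quoted as 6.28e8 J/kmol).  The integral is accumulated only
while the basal-layer temperature is at or above a 43.0 degC gate.
Evaluation is done in log space: the 1e98 prefactor overflows double
precision if the exponential is formed naively.

Burn severity at the basal layer is classified against Omega = 0.53
(superficial-burn limit) and Omega = 1.0 (superficial partial-thickness
limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .materials import InvalidParameterError

__all__ = [
    "DamageParams",
    "DamageResult",
    "damage_rate",
    "accumulate_damage",
    "undamaged_fraction",
    "classify_burn",
    "burn_depth",
    "OMEGA_SUPERFICIAL",
    "OMEGA_PARTIAL_THICKNESS",
]

OMEGA_SUPERFICIAL = 0.53
OMEGA_PARTIAL_THICKNESS = 1.0

_KELVIN = 273.15


@dataclass(frozen=True)
class DamageParams:
    """Arrhenius damage-kinetics constants.

    P : pre-exponential frequency factor, 1/s
    dE : activation energy, J/mol
    R : molar gas constant, J/(mol K)
    T_threshold : integration gate, degC; the rate is zero below it
    quadrature : "trapezoid" (default) or "rectangle" (left-endpoint),
        for sensitivity checks of the time integration
    """

    P: float = 3.1e98
    dE: float = 6.28e5
    R: float = 8.314
    T_threshold: float = 43.0
    quadrature: str = "trapezoid"

    def __post_init__(self) -> None:
        if self.P <= 0 or self.dE <= 0 or self.R <= 0:
            raise InvalidParameterError("P, dE and R must be positive")
        if self.quadrature not in ("trapezoid", "rectangle"):
            raise InvalidParameterError(f"unknown quadrature {self.quadrature!r}")

    @property
    def log_P(self) -> float:
        return math.log(self.P)


def damage_rate(T_kelvin, params: DamageParams | None = None):
    """Instantaneous damage rate dOmega/dt at absolute temperature T, 1/s.

    Accepts a scalar or array temperature in kelvin.  Computed as
    ``exp(ln P - dE/(R*T))`` so the huge prefactor never materializes.
    The 43 degC gate is *not* applied here; see :func:`accumulate_damage`.
    """
    if params is None:
        params = DamageParams()
    T = np.asarray(T_kelvin, dtype=float)
    if np.any(T <= 0):
        raise InvalidParameterError("absolute temperature must be positive")
    rate = np.exp(params.log_P - params.dE / (params.R * T))
    return float(rate) if np.isscalar(T_kelvin) else rate


@dataclass(frozen=True)
class DamageResult:
    """Damage-integral outcome at a single depth (normally the basal layer)."""

    times: np.ndarray  # s
    omega_series: np.ndarray  # Omega(t), dimensionless, non-decreasing
    time_above_threshold: float  # s spent at or above the gate temperature

    @property
    def omega_final(self) -> float:
        return float(self.omega_series[-1])

    @property
    def undamaged_fraction(self) -> float:
        return undamaged_fraction(self.omega_final)

    @property
    def burn_class(self) -> str:
        return classify_burn(self.omega_final)


def _gated_rate(temps_C: np.ndarray, params: DamageParams) -> np.ndarray:
    rate = damage_rate(temps_C + _KELVIN, params)
    return np.where(temps_C >= params.T_threshold, rate, 0.0)


def accumulate_damage(
    times,
    temps_C,
    params: DamageParams | None = None,
) -> DamageResult:
    """Integrate the damage rate over a temperature time series.

    Parameters
    ----------
    times : strictly increasing sample times, s
    temps_C : temperature at each sample, degC
    params : kinetics constants; defaults to the hot-water set

    The integrand is zeroed wherever the temperature is below the
    ``T_threshold`` gate; integration is trapezoidal by default.
    """
    if params is None:
        params = DamageParams()
    t = np.asarray(times, dtype=float)
    T = np.asarray(temps_C, dtype=float)
    if t.size == 0:
        raise InvalidParameterError("empty temperature series")
    if t.shape != T.shape:
        raise InvalidParameterError("times and temperatures must align")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise InvalidParameterError("times must be strictly increasing")

    rate = _gated_rate(T, params)
    if t.size == 1:
        omega = np.zeros(1)
    elif params.quadrature == "trapezoid":
        omega = cumulative_trapezoid(rate, t, initial=0.0)
    else:  # left-endpoint rectangle rule
        omega = np.concatenate(([0.0], np.cumsum(rate[:-1] * np.diff(t))))
    hot = T >= params.T_threshold
    dt_weights = np.zeros_like(t)
    if t.size > 1:
        seg = np.diff(t)
        dt_weights[:-1] += 0.5 * seg
        dt_weights[1:] += 0.5 * seg
    return DamageResult(
        times=t,
        omega_series=omega,
        time_above_threshold=float(np.sum(dt_weights[hot])),
    )


def undamaged_fraction(omega: float) -> float:
    """Fraction of cells still undamaged, C_tau/C_0 = exp(-Omega)."""
    if omega < 0:
        raise InvalidParameterError("omega must be non-negative")
    return math.exp(-omega)


def classify_burn(omega_basal: float) -> str:
    """Burn-severity label from the basal-layer damage integral.

    Omega < 0.53 is below the superficial-burn limit; 0.53 <= Omega < 1.0 is
    a superficial burn; Omega >= 1.0 a superficial partial-thickness burn.
    """
    if omega_basal < 0:
        raise InvalidParameterError("omega must be non-negative")
    if omega_basal < OMEGA_SUPERFICIAL:
        return "sub-threshold"
    if omega_basal < OMEGA_PARTIAL_THICKNESS:
        return "superficial"
    return "superficial partial-thickness"


def burn_depth(history, params: DamageParams | None = None) -> float | None:
    """Deepest skin depth at which the damage integral reaches 1.0, m.

    Evaluates :func:`accumulate_damage` on every skin cell of the stored
    field snapshots and interpolates the Omega = 1 crossing between adjacent
    nodes.  Returns None when no cell reaches Omega = 1.
    """
    if params is None:
        params = DamageParams()
    t = history.field_times
    fields = history.skin_fields
    # cells that never reach the gate cannot accumulate damage
    hot_cols = np.flatnonzero(np.any(fields >= params.T_threshold, axis=0))
    if hot_cols.size == 0:
        return None
    omegas = np.zeros(fields.shape[1])
    for j in hot_cols:
        omegas[j] = accumulate_damage(t, fields[:, j], params).omega_final
    reached = omegas >= OMEGA_PARTIAL_THICKNESS
    if not np.any(reached):
        return None
    deepest = int(np.flatnonzero(reached)[-1])
    x = history.skin_nodes
    if deepest + 1 >= x.size:
        return float(x[deepest])
    o0, o1 = omegas[deepest], omegas[deepest + 1]
    if o1 >= o0:  # no decaying crossing below; report the cell center
        return float(x[deepest])
    w = (o0 - OMEGA_PARTIAL_THICKNESS) / (o0 - o1)
    return float(x[deepest] + w * (x[deepest + 1] - x[deepest]))
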
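"""The thirteen tabulated spill scenarios (Cases A-M) and parameter sweeps.

Each case varies one parameter of the base case A: an 85 degC spill
instantly soaking a 1.0 mm cotton fabric on skin with a 50 um epidermis,
with the fabric never removed.  Variants remove the fabric after a delay,
apply running-water cooling, or change the epidermis thickness, fabric
thickness or spill temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .damage import DamageParams, DamageResult, accumulate_damage
from .materials import default_skin_stack, default_wet_fabric
from .solver import ExposureTimeline, SolverConfig, TemperatureHistory, simulate

__all__ = ["CaseSpec", "CaseResult", "case_table", "get_case", "run_case", "sweep"]


@dataclass(frozen=True)
class CaseSpec:
    """One spill scenario: geometry, spill temperature and event times."""

    id: str
    L_epi_um: float  # epidermis thickness, um
    L_fabric_mm: float  # soaked-fabric thickness, mm
    T_spill: float  # degC
    t_off: float | None  # s, fabric removal (None: never)
    t_cool: float | None  # s, water-cooling start (None: never)
    comment: str = ""


_CASES = (
    CaseSpec("A", 50, 1.0, 85, None, None, "Base case, 50 um epidermis, fabric not removed"),
    CaseSpec("B", 50, 1.0, 85, 5.0, 10.0, "Fabric off at 5 s and water cooling at 10 s"),
    CaseSpec("C", 50, 1.0, 85, 2.5, 5.0, "Fabric off at 2.5 s and water cooling at 5 s"),
    CaseSpec("D", 50, 1.0, 85, 5.0, None, "As Case B but no water cooling"),
    CaseSpec("E", 50, 1.0, 85, 2.5, None, "As Case C but no water cooling"),
    CaseSpec("F", 50, 1.0, 85, 2.5, 2.6, "As Case C but water cooling at 2.6 s"),
    CaseSpec("G", 40, 1.0, 85, None, None, "As the base case but 40 um epidermis"),
    CaseSpec("H", 60, 1.0, 85, None, None, "As the base case but 60 um epidermis"),
    CaseSpec("I", 80, 1.0, 85, None, None, "As the base case but 80 um epidermis"),
    CaseSpec("J", 50, 1.1, 85, None, None, "As the base case but 1.1 mm thick fabric"),
    CaseSpec("K", 50, 0.9, 85, None, None, "As the base case but 0.9 mm thick fabric"),
    CaseSpec("L", 50, 1.0, 90, None, None, "As the base case but spilled liquid at 90 C"),
    CaseSpec("M", 50, 1.0, 80, None, None, "As the base case but spilled liquid at 80 C"),
)


def case_table() -> list[CaseSpec]:
    """The built-in scenario table (13 cases, A-M)."""
    return list(_CASES)


def get_case(case_id: str) -> CaseSpec:
    for case in _CASES:
        if case.id == case_id.upper():
            return case
    raise KeyError(f"unknown case {case_id!r}; expected one of A-M")


@dataclass
class CaseResult:
    """End-to-end outcome of one scenario run."""

    case: CaseSpec
    history: TemperatureHistory
    damage: DamageResult

    @property
    def omega_final(self) -> float:
        return self.damage.omega_final

    @property
    def burn_class(self) -> str:
        return self.damage.burn_class

    @property
    def basal_peak_temp(self) -> float:
        return float(np.max(self.history.basal))

    @property
    def basal_peak_time(self) -> float:
        return float(self.history.times[int(np.argmax(self.history.basal))])


def run_case(
    spec: CaseSpec,
    *,
    t_end: float = 30.0,
    timeline: ExposureTimeline | None = None,
    config: SolverConfig | None = None,
    damage_params: DamageParams | None = None,
    T_dry: float = 30.0,
) -> CaseResult:
    """Run one scenario: materials -> bioheat solver -> damage integral.

    ``timeline`` overrides the ambient/coolant settings while keeping the
    case's event times; ``config`` overrides the numerics; ``damage_params``
    the injury kinetics.
    """
    stack = default_skin_stack(spec.L_epi_um * 1e-6)
    fabric = default_wet_fabric(spec.L_fabric_mm * 1e-3, spec.T_spill, T_dry=T_dry)
    base = timeline if timeline is not None else ExposureTimeline()
    tl = replace(base, t_end=t_end, t_off=spec.t_off, t_cool=spec.t_cool)
    history = simulate(stack, fabric, tl, config)
    damage = accumulate_damage(history.times, history.basal, damage_params)
    return CaseResult(case=spec, history=history, damage=damage)


_SWEEPABLE = {"T_spill", "L_fabric_mm", "L_epi_um", "t_off", "t_cool"}


def sweep(
    base: CaseSpec,
    parameter: str,
    values,
    **run_kwargs,
) -> pd.DataFrame:
    """One-at-a-time parameter sweep around a base scenario.

    Returns a tidy table with one row per value: the swept value, the final
    basal damage integral, the burn class and the basal peak temperature.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; expected one of {sorted(_SWEEPABLE)}"
        )
    rows = []
    for value in values:
        spec = replace(base, id=f"{base.id}[{parameter}={value}]", **{parameter: value})
        result = run_case(spec, **run_kwargs)
        rows.append(
            {
                "case": spec.id,
                parameter: value,
                "omega": result.omega_final,
                "burn_class": result.burn_class,
                "basal_peak_C": result.basal_peak_temp,
            }
        )
    return pd.DataFrame(rows)
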
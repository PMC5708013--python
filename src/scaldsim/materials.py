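"""Material properties of the skin layers, dry/soaked fabric and blood.

All quantities are SI; temperatures are handled in degrees Celsius at the
interface and converted to kelvin only inside the Arrhenius damage term.

The default skin stack is a four-layer slab model of the thigh (epidermis,
dermis, subcutaneous fat, muscle).  The clothing layer is cotton fabric whose
pores are assumed to be filled instantaneously by the spilled liquid; its
effective thermal properties are those of soaked cotton and its initial
temperature follows from a volumetric-heat-capacity-weighted mixing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SkinLayer",
    "LayerStack",
    "WetFabricSpec",
    "BloodModel",
    "thermal_diffusivity",
    "wet_fabric_temperature",
    "default_skin_stack",
    "default_wet_fabric",
    "DRY_FABRIC_RHO",
    "DRY_FABRIC_C",
    "PORE_WATER_RHO",
    "WATER_C",
    "SOAKED_FABRIC_K",
    "SOAKED_FABRIC_RHOC",
]

# Cotton fabric and water constants used by the mixing rule.  The pore-water
# density is chosen so that dry fabric (200 kg/m3) plus the water filling its
# voids sums to the soaked-fabric density of 1000 kg/m3.
DRY_FABRIC_RHO = 200.0  # kg/m3
DRY_FABRIC_C = 1340.0  # J/(kg K)
PORE_WATER_RHO = 800.0  # kg/m3
WATER_C = 4184.0  # J/(kg K)

# Effective properties of soaked cotton: conductivity of water at ~330 K and
# the tabulated volumetric heat capacity of the soaked fabric.
SOAKED_FABRIC_K = 0.65  # W/(m K)
SOAKED_FABRIC_RHOC = 3.6e6  # J/(m3 K)


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


def thermal_diffusivity(k: float, rho: float, C: float) -> float:
    """Thermal diffusivity a = k / (rho * C) in m2/s.

    Parameters
    ----------
    k : thermal conductivity, W/(m K)
    rho : density, kg/m3
    C : specific heat, J/(kg K)
    """
    if k <= 0 or rho <= 0 or C <= 0:
        raise InvalidParameterError(
            f"thermal_diffusivity requires positive arguments, got k={k}, rho={rho}, C={C}"
        )
    return k / (rho * C)


def wet_fabric_temperature(
    rhoC_fabric: float, T_fabric: float, rhoC_water: float, T_water: float
) -> float:
    """Uniform temperature of fabric the instant its pores fill with liquid.

    Volumetric-heat-capacity-weighted mean of the dry-fabric and pore-water
    temperatures:

        T0_wf = (rho_f C_f T_f + rho_w C_w T_w) / (rho_f C_f + rho_w C_w)

    where ``rho_w`` is the mass of water per unit volume of soaked fabric.
    This is the energy-conserving instantaneous mixing temperature of the two
    constituents at constant volume.
    """
    if rhoC_fabric <= 0 or rhoC_water <= 0:
        raise InvalidParameterError("volumetric heat capacities must be positive")
    return (rhoC_fabric * T_fabric + rhoC_water * T_water) / (rhoC_fabric + rhoC_water)


@dataclass(frozen=True)
class SkinLayer:
    """A homogeneous tissue slab with constant thermal properties.

    Attributes
    ----------
    name : layer label (e.g. ``"epidermis"``)
    k : thermal conductivity, W/(m K)
    rho : density, kg/m3
    C : specific heat, J/(kg K)
    thickness : slab thickness, m
    """

    name: str
    k: float
    rho: float
    C: float
    thickness: float

    def __post_init__(self) -> None:
        for attr in ("k", "rho", "C", "thickness"):
            if getattr(self, attr) <= 0:
                raise InvalidParameterError(
                    f"layer {self.name!r}: {attr} must be positive, got {getattr(self, attr)}"
                )

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity k/(rho C), m2/s."""
        return thermal_diffusivity(self.k, self.rho, self.C)

    @property
    def rhoC(self) -> float:
        """Volumetric heat capacity rho*C, J/(m3 K)."""
        return self.rho * self.C


@dataclass(frozen=True)
class LayerStack:
    """Ordered tissue layers from the skin surface inward."""

    layers: tuple[SkinLayer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise InvalidParameterError("LayerStack needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def total_depth(self) -> float:
        """Domain depth: sum of layer thicknesses, m."""
        return sum(layer.thickness for layer in self.layers)

    @property
    def epidermis_thickness(self) -> float:
        """Thickness of the outermost layer (the basal layer sits at its base)."""
        return self.layers[0].thickness

    def layer_boundaries(self) -> list[float]:
        """Cumulative depths of the layer interfaces, starting at 0."""
        depths = [0.0]
        for layer in self.layers:
            depths.append(depths[-1] + layer.thickness)
        return depths

    def with_epidermis_thickness(self, thickness: float) -> "LayerStack":
        """Copy of the stack with the outermost layer set to ``thickness``."""
        new_epi = replace(self.layers[0], thickness=thickness)
        return LayerStack((new_epi,) + self.layers[1:])


@dataclass(frozen=True)
class WetFabricSpec:
    """A clothing layer soaked by the spilled liquid.

    ``T0_wf`` is the uniform temperature of the wet fabric the instant the
    spill fills its pores, from :func:`wet_fabric_temperature`.
    """

    thickness: float  # m
    T_spill: float  # degC, spilled-liquid temperature
    T_dry: float = 30.0  # degC, fabric temperature before the spill
    k_wet: float = SOAKED_FABRIC_K
    rhoC_wet: float = SOAKED_FABRIC_RHOC
    T0_wf: float = field(init=False)

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidParameterError("fabric thickness must be positive")
        if self.k_wet <= 0 or self.rhoC_wet <= 0:
            raise InvalidParameterError("soaked-fabric properties must be positive")
        t0 = wet_fabric_temperature(
            DRY_FABRIC_RHO * DRY_FABRIC_C,
            self.T_dry,
            PORE_WATER_RHO * WATER_C,
            self.T_spill,
        )
        object.__setattr__(self, "T0_wf", t0)


@dataclass(frozen=True)
class BloodModel:
    """Constant-parameter perfusion and metabolic source terms.

    The perfusion sink is ``Wb * rho_b * C_b * (T_b - T)`` and the metabolic
    source is ``Q_met``, applied only in the perfused (vascular) layers.
    Setting ``enabled=False`` zeroes both terms everywhere.
    """

    Wb: float = 1.25e-3  # 1/s, volumetric blood flow per tissue volume
    rho_b: float = 1060.0  # kg/m3
    C_b: float = 3770.0  # J/(kg K)
    T_b: float = 37.0  # degC, arterial blood temperature
    Q_met: float = 420.0  # W/m3
    perfused_layers: tuple[str, ...] = ("dermis", "subcutaneous", "muscle")
    enabled: bool = True

    def __post_init__(self) -> None:
        for attr in ("Wb", "rho_b", "C_b", "Q_met"):
            if getattr(self, attr) < 0:
                raise InvalidParameterError(f"BloodModel.{attr} must be non-negative")

    @property
    def perfusion_coefficient(self) -> float:
        """Wb * rho_b * C_b, W/(m3 K); zero when disabled."""
        if not self.enabled:
            return 0.0
        return self.Wb * self.rho_b * self.C_b

    @property
    def metabolic_heat(self) -> float:
        """Q_met, W/m3; zero when disabled."""
        return self.Q_met if self.enabled else 0.0

    def disabled(self) -> "BloodModel":
        return replace(self, enabled=False)


#: Tabulated skin-layer properties (thigh): k, rho, C, thickness.
_DEFAULT_LAYERS = (
    ("epidermis", 0.22, 1200.0, 3600.0, 50e-6),
    ("dermis", 0.40, 1200.0, 3600.0, 0.002),
    ("subcutaneous", 0.20, 1000.0, 2500.0, 0.010),
    ("muscle", 0.45, 1000.0, 3800.0, 0.030),
)


def default_skin_stack(epidermis_thickness: float = 50e-6) -> LayerStack:
    """Four-layer thigh model with the default tabulated properties.

    Only the epidermis thickness is variable (40-80 um in the scenarios
    studied); dermis (2 mm), subcutaneous fat (10 mm) and muscle (30 mm) are
    fixed.
    """
    if epidermis_thickness <= 0:
        raise InvalidParameterError("epidermis_thickness must be positive")
    layers = []
    for name, k, rho, C, thickness in _DEFAULT_LAYERS:
        if name == "epidermis":
            thickness = epidermis_thickness
        layers.append(SkinLayer(name, k, rho, C, thickness))
    return LayerStack(tuple(layers))


def default_wet_fabric(
    thickness: float, T_spill: float, T_dry: float = 30.0
) -> WetFabricSpec:
    """Soaked cotton clothing layer for a given spill temperature."""
    return WetFabricSpec(thickness=thickness, T_spill=T_spill, T_dry=T_dry)
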
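"""Explicit finite-difference solver for the 1D Pennes bioheat equation.

The domain is a vertex-centered grid spanning an optional wet-fabric layer
(x < 0) and the skin layers (x >= 0, surface at x = 0).  Nodes are spaced
``dx`` apart and every material interface falls exactly on a node, so each
segment between two nodes lies in a single material and carries that
material's conductivity — no interface averaging is needed.  A node's heat
capacity is the sum of the two half-segments beside it.  The update is
forward-time centered-space (explicit Euler).

The outer face carries a convective (Robin) boundary condition whose
reservoir switches through up to three stages:

1. fabric_contact — wet fabric on the skin, outer fabric face convects to air;
2. air_exposed   — fabric removed at ``t_off``, skin surface convects to air;
3. water_cooled  — running-water cooling from ``t_cool`` (larger h).

The innermost face is adiabatic.  Blood perfusion and metabolic heating act
as volumetric source terms in the perfused layers only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import BloodModel, InvalidParameterError, LayerStack, WetFabricSpec

__all__ = [
    "Grid1D",
    "ExposureTimeline",
    "SolverConfig",
    "TemperatureHistory",
    "ConvectiveBC",
    "DirichletBC",
    "StabilityError",
    "NumericalError",
    "check_stability",
    "step",
    "simulate",
    "probe",
]

FABRIC_LABEL = "fabric"


class StabilityError(ValueError):
    """The explicit scheme would be unstable (Fourier number >= 0.5)."""


class NumericalError(RuntimeError):
    """A non-finite temperature appeared during time stepping."""


@dataclass(frozen=True)
class ConvectiveBC:
    """Robin boundary: flux h*(T_env - T_surface) into the outermost node."""

    h: float  # W/(m2 K)
    T_env: float  # degC


@dataclass(frozen=True)
class DirichletBC:
    """Outermost node held at a fixed temperature (verification use)."""

    T_surface: float  # degC


@dataclass(frozen=True)
class Grid1D:
    """Vertex-centered 1D grid; material properties live on segments.

    ``seg_k`` and ``seg_rhoC`` are per-segment (between adjacent nodes);
    nodes number one more than segments.  Fabric segments (if any) come
    first; the fabric-skin interface node sits at x = 0.
    """

    dx: float
    seg_k: np.ndarray  # W/(m K), per segment
    seg_rhoC: np.ndarray  # J/(m3 K), per segment
    seg_labels: tuple[str, ...]  # layer label per segment
    fabric_segment_count: int = 0

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise InvalidParameterError("dx must be positive")
        k = np.asarray(self.seg_k, dtype=float)
        rhoC = np.asarray(self.seg_rhoC, dtype=float)
        if k.shape != rhoC.shape or k.ndim != 1 or k.size == 0:
            raise InvalidParameterError("seg_k and seg_rhoC must be equal-length 1D arrays")
        if len(self.seg_labels) != k.size:
            raise InvalidParameterError("seg_labels must match the segment count")
        if np.any(k <= 0) or np.any(rhoC <= 0):
            raise InvalidParameterError("segment properties must be positive")
        if not 0 <= self.fabric_segment_count <= k.size:
            raise InvalidParameterError("invalid fabric segment count")
        object.__setattr__(self, "seg_k", k)
        object.__setattr__(self, "seg_rhoC", rhoC)
        object.__setattr__(self, "seg_labels", tuple(self.seg_labels))

    @property
    def n_segments(self) -> int:
        return self.seg_k.size

    @property
    def n_nodes(self) -> int:
        return self.n_segments + 1

    @property
    def n_fabric_nodes(self) -> int:
        """Nodes strictly inside the fabric (x < 0)."""
        return self.fabric_segment_count

    @property
    def nodes(self) -> np.ndarray:
        """Node coordinates; x = 0 at the skin surface."""
        return (np.arange(self.n_nodes) - self.fabric_segment_count) * self.dx

    def node_capacity(self) -> np.ndarray:
        """Per-node heat capacity per unit area, J/(m2 K): two half-segments."""
        cap = np.zeros(self.n_nodes)
        half = self.seg_rhoC * self.dx / 2.0
        cap[:-1] += half
        cap[1:] += half
        return cap

    def segment_conductance(self) -> np.ndarray:
        """Per-segment conductance g = k/dx, W/(m2 K)."""
        return self.seg_k / self.dx

    def skin_only(self) -> "Grid1D":
        """The grid with fabric segments removed (after fabric removal)."""
        nf = self.fabric_segment_count
        if nf == 0:
            return self
        return Grid1D(
            dx=self.dx,
            seg_k=self.seg_k[nf:],
            seg_rhoC=self.seg_rhoC[nf:],
            seg_labels=self.seg_labels[nf:],
            fabric_segment_count=0,
        )

    @classmethod
    def from_layers(
        cls,
        stack: LayerStack,
        fabric: WetFabricSpec | None = None,
        dx: float = 10e-6,
    ) -> "Grid1D":
        """Build the grid from a skin stack plus optional fabric layer.

        Every layer thickness must be an integer multiple of ``dx`` so that
        each material interface falls on a node.
        """
        ks: list[float] = []
        rcs: list[float] = []
        labels: list[str] = []
        nf = 0
        if fabric is not None:
            nf = _segments_for(fabric.thickness, dx, FABRIC_LABEL)
            ks += [fabric.k_wet] * nf
            rcs += [fabric.rhoC_wet] * nf
            labels += [FABRIC_LABEL] * nf
        for layer in stack.layers:
            n = _segments_for(layer.thickness, dx, layer.name)
            ks += [layer.k] * n
            rcs += [layer.rhoC] * n
            labels += [layer.name] * n
        return cls(
            dx=dx,
            seg_k=np.array(ks),
            seg_rhoC=np.array(rcs),
            seg_labels=tuple(labels),
            fabric_segment_count=nf,
        )


def _segments_for(thickness: float, dx: float, name: str) -> int:
    n = round(thickness / dx)
    if n < 1 or abs(n * dx - thickness) > 1e-9 * max(thickness, dx):
        raise InvalidParameterError(
            f"layer {name!r} thickness {thickness} m is not a positive integer "
            f"multiple of dx = {dx} m"
        )
    return n


@dataclass(frozen=True)
class ExposureTimeline:
    """Event schedule of the exposure.

    ``t_off`` is the fabric-removal time (None: never removed); ``t_cool``
    the start of running-water cooling (None: never; requires the fabric to
    have been removed first).
    """

    t_end: float = 30.0  # s
    t_off: float | None = None  # s, fabric removal
    t_cool: float | None = None  # s, water-cooling start
    T_air: float = 20.0  # degC
    T_water_cool: float = 20.0  # degC, tempered water
    h_air: float = 10.0  # W/(m2 K)
    h_water: float = 600.0  # W/(m2 K)

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise InvalidParameterError("t_end must be positive")
        if self.h_air <= 0 or self.h_water <= 0:
            raise InvalidParameterError("convection coefficients must be positive")
        if self.t_off is not None and self.t_off < 0:
            raise InvalidParameterError("t_off must be non-negative")
        if self.t_cool is not None:
            if self.t_off is None:
                raise InvalidParameterError(
                    "water cooling requires the fabric to be removed first "
                    "(set t_off <= t_cool)"
                )
            if self.t_cool < self.t_off:
                raise InvalidParameterError("t_cool must be >= t_off")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of the explicit scheme.

    ``record_interval`` controls the probe-series sampling and
    ``field_interval`` the (coarser) full-field snapshots used for burn-depth
    evaluation; both in seconds of simulated time.
    """

    dt: float = 2e-4  # s
    dx: float = 10e-6  # m
    blood: BloodModel = field(default_factory=BloodModel)
    Q_ext: float = 0.0  # W/m3
    record_interval: float = 0.01  # s
    field_interval: float = 0.05  # s

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0:
            raise InvalidParameterError("dt and dx must be positive")
        if self.record_interval < self.dt or self.field_interval < self.dt:
            raise InvalidParameterError("record intervals must be >= dt")


def check_stability(grid: Grid1D, dt: float) -> dict[str, float]:
    """Maximum Fourier number per layer label.

    Per node, Fo = dt * (g_left + g_right) / (2 * capacity); for a node
    inside a uniform material this reduces to a*dt/dx^2.  The explicit
    scheme requires Fo < 0.5 everywhere.  An interface node contributes to
    both adjacent layers' maxima.
    """
    g = grid.segment_conductance()
    cap = grid.node_capacity()
    gsum = np.zeros(grid.n_nodes)
    gsum[:-1] += g
    gsum[1:] += g
    fo = dt * gsum / (2.0 * cap)
    out: dict[str, float] = {}
    for i, label in enumerate(grid.seg_labels):
        node_max = max(float(fo[i]), float(fo[i + 1]))
        out[label] = max(out.get(label, 0.0), node_max)
    return out


def _require_stable(grid: Grid1D, dt: float) -> dict[str, float]:
    report = check_stability(grid, dt)
    bad = {name: fo for name, fo in report.items() if fo >= 0.5}
    if bad:
        raise StabilityError(
            "explicit scheme unstable; Fourier number >= 0.5 in: "
            + ", ".join(f"{n} (Fo={fo:.3f})" for n, fo in bad.items())
        )
    return report


class _StageKernel:
    """Precomputed update coefficients for one boundary-condition stage."""

    def __init__(
        self,
        grid: Grid1D,
        dt: float,
        bc: ConvectiveBC | DirichletBC | None,
        blood: BloodModel,
        Q_ext: float,
    ) -> None:
        self.dt = dt
        self.bc = bc
        self.g = grid.segment_conductance()
        cap = grid.node_capacity()
        self.inv_cap = dt / cap
        # volumetric sources, volume-weighted onto nodes from half-segments
        seg_labels = np.array(grid.seg_labels)
        perf_seg = np.zeros(grid.n_segments)
        src_seg = np.full(grid.n_segments, Q_ext, dtype=float)
        src_seg[seg_labels == FABRIC_LABEL] = 0.0
        if blood.enabled:
            vascular = np.isin(seg_labels, blood.perfused_layers)
            perf_seg[vascular] = blood.perfusion_coefficient
            src_seg[vascular] += blood.metabolic_heat
        half = grid.dx / 2.0
        perf = np.zeros(grid.n_nodes)  # W/(m2 K) per node
        src = np.zeros(grid.n_nodes)  # W/m2 per node
        perf[:-1] += perf_seg * half
        perf[1:] += perf_seg * half
        src[:-1] += src_seg * half
        src[1:] += src_seg * half
        # linear form: T <- decay*T + inv_cap*net_conduction + const
        self.decay = 1.0 - self.inv_cap * perf
        self.const = self.inv_cap * (perf * blood.T_b + src)
        self._has_source = bool(np.any(perf) or np.any(src))

    def run(self, T: np.ndarray, n_steps: int) -> None:
        """Advance ``T`` in place by ``n_steps`` explicit Euler steps."""
        g = self.g
        inv_cap = self.inv_cap
        bc = self.bc
        net = np.empty_like(T)
        convective = isinstance(bc, ConvectiveBC)
        dirichlet = isinstance(bc, DirichletBC)
        if dirichlet:
            T[0] = bc.T_surface
        for _ in range(n_steps):
            flux = g * np.diff(T)
            net[0] = flux[0]
            net[-1] = -flux[-1]
            np.subtract(flux[1:], flux[:-1], out=net[1:-1])
            if convective:
                net[0] += bc.h * (bc.T_env - T[0])
            if self._has_source:
                T *= self.decay
                T += inv_cap * net
                T += self.const
            else:
                T += inv_cap * net
            if dirichlet:
                T[0] = bc.T_surface


def step(
    T: np.ndarray,
    grid: Grid1D,
    dt: float,
    bc: ConvectiveBC | DirichletBC | None = None,
    blood: BloodModel | None = None,
    Q_ext: float = 0.0,
) -> np.ndarray:
    """One explicit Euler update of the nodal temperature field.

    The inner (last-index) face is adiabatic; the outer face is adiabatic
    too unless a boundary condition is given.  Returns a new array.
    """
    _require_stable(grid, dt)
    if blood is None:
        blood = BloodModel(enabled=False)
    out = np.array(T, dtype=float)
    if out.shape != (grid.n_nodes,):
        raise InvalidParameterError(
            f"temperature array has {out.size} entries, grid has {grid.n_nodes} nodes"
        )
    kern = _StageKernel(grid, dt, bc, blood, Q_ext)
    kern.run(out, 1)
    _check_finite(out)
    return out


def _check_finite(T: np.ndarray) -> None:
    if not np.all(np.isfinite(T)):
        bad = int(np.flatnonzero(~np.isfinite(T))[0])
        raise NumericalError(
            f"non-finite temperature at node {bad}: the solution has diverged"
        )


@dataclass
class TemperatureHistory:
    """Recorded temperature fields and named probe series.

    ``probes`` are sampled every ``record_interval``; the full fields every
    ``field_interval`` (coarser, for burn-depth evaluation).  Fabric probe
    and field values are NaN after fabric removal.
    """

    times: np.ndarray  # s, probe sampling times
    probes: dict[str, np.ndarray]  # degC, per probe name
    field_times: np.ndarray  # s, snapshot times
    skin_fields: np.ndarray  # degC, (n_snapshots, n_skin_nodes), x >= 0
    fabric_fields: np.ndarray | None  # degC, (n_snapshots, n_fabric_nodes), x < 0
    skin_nodes: np.ndarray  # m, skin node depths (0 ... total_depth)
    fabric_nodes: np.ndarray | None  # m, negative coordinates, or None
    epidermis_thickness: float  # m
    total_depth: float  # m
    stability_report: dict[str, float]

    @property
    def basal(self) -> np.ndarray:
        """Basal-layer (epidermis-dermis interface) temperature series."""
        return self.probes["basal"]

    def probe_at(self, depth: float) -> np.ndarray:
        """Interpolated temperature series at ``depth`` (snapshot times)."""
        return probe(self, depth)


def probe(history: TemperatureHistory, depth: float) -> np.ndarray:
    """Temperature time series at a given depth, m (negative: inside fabric).

    Linear interpolation between adjacent nodes of the stored field
    snapshots; exact at node positions.
    """
    if depth >= 0:
        if depth > history.total_depth:
            raise InvalidParameterError(
                f"depth {depth} m is below the domain ({history.total_depth} m)"
            )
        x = history.skin_nodes
        f = history.skin_fields
    else:
        if history.fabric_fields is None:
            raise InvalidParameterError("no fabric layer in this simulation")
        if depth < history.fabric_nodes[0]:
            raise InvalidParameterError(f"depth {depth} m is outside the fabric")
        x = history.fabric_nodes
        f = history.fabric_fields
    i, j, w = _interp_weights(x, depth)
    return (1.0 - w) * f[:, i] + w * f[:, j]


def _interp_weights(positions: np.ndarray, depth: float) -> tuple[int, int, float]:
    """Indices and weight for linear interpolation at ``depth`` (clamped)."""
    i = int(np.searchsorted(positions, depth))
    if i == 0:
        return 0, 0, 0.0
    if i == len(positions):
        return len(positions) - 1, len(positions) - 1, 0.0
    if positions[i] == depth:
        return i, i, 0.0
    w = (depth - positions[i - 1]) / (positions[i] - positions[i - 1])
    return i - 1, i, float(w)


def simulate(
    stack: LayerStack,
    fabric: WetFabricSpec | None,
    timeline: ExposureTimeline,
    config: SolverConfig | None = None,
) -> TemperatureHistory:
    """Run the staged exposure and return the recorded history.

    The initial condition is a uniform 37 degC skin (all nodes x >= 0,
    including the fabric-skin interface node) and, if a fabric is present,
    a uniform wet fabric at its instantaneous mixing temperature ``T0_wf``
    (nodes x < 0).  At ``t_off`` the fabric nodes are deleted together with
    their enthalpy and the skin surface becomes the convective outer face;
    at ``t_cool`` the reservoir switches to running water.
    """
    if config is None:
        config = SolverConfig()
    grid = Grid1D.from_layers(stack, fabric, config.dx)
    stability = _require_stable(grid, config.dt)

    dt = config.dt
    n_total = round(timeline.t_end / dt)
    if n_total < 1:
        raise InvalidParameterError("t_end must cover at least one time step")
    rec_stride = max(1, round(config.record_interval / dt))
    # field snapshots land on probe-record boundaries
    field_stride = rec_stride * max(1, round(config.field_interval / config.record_interval))

    nf = grid.n_fabric_nodes
    if fabric is not None and timeline.t_off == 0:
        raise InvalidParameterError("t_off = 0 removes the fabric before the spill")
    step_off = (
        round(timeline.t_off / dt)
        if (fabric is not None and timeline.t_off is not None)
        else None
    )
    if step_off is not None and step_off >= n_total:
        step_off = None
    step_cool = round(timeline.t_cool / dt) if timeline.t_cool is not None else None
    if step_cool is not None and (step_off is None or step_cool >= n_total):
        step_cool = None

    skin_grid = grid.skin_only()
    n_skin = skin_grid.n_nodes
    skin_nodes = skin_grid.nodes
    fabric_nodes = grid.nodes[:nf] if nf else None

    # initial condition: skin (incl. the interface node at x = 0) at 37 degC
    T = np.empty(grid.n_nodes)
    T[:nf] = fabric.T0_wf if fabric is not None else 37.0
    T[nf:] = 37.0

    epi = stack.epidermis_thickness
    probe_depths = {
        "skin_surface": 0.0,
        "basal": epi,
        "dermis_center": epi + 0.001,
        "subcutaneous_center": epi + 0.002 + 0.005,
    }
    skin_weights = {
        name: _interp_weights(skin_nodes, d) for name, d in probe_depths.items()
    }
    fabric_idx = {}
    if nf:
        fabric_idx = {
            "fabric_outer": 0,
            "fabric_center": nf // 2,
            "fabric_inner": nf - 1,
        }

    n_rec = n_total // rec_stride + 1
    times = np.arange(n_rec) * (rec_stride * dt)
    probes = {name: np.empty(n_rec) for name in probe_depths}
    for name in fabric_idx:
        probes[name] = np.full(n_rec, np.nan)
    n_field = n_total // field_stride + 1
    field_times = np.arange(n_field) * (field_stride * dt)
    skin_fields = np.empty((n_field, n_skin))
    fabric_fields = np.full((n_field, nf), np.nan) if nf else None

    def record(step_idx: int, T: np.ndarray, has_fabric: bool) -> None:
        cur_nf = nf if has_fabric else 0
        skin_T = T[cur_nf:]
        if step_idx % rec_stride == 0:
            r = step_idx // rec_stride
            for name, (i, j, w) in skin_weights.items():
                probes[name][r] = (1.0 - w) * skin_T[i] + w * skin_T[j]
            if has_fabric:
                for name, i in fabric_idx.items():
                    probes[name][r] = T[i]
        if step_idx % field_stride == 0:
            s = step_idx // field_stride
            skin_fields[s] = skin_T
            if has_fabric:
                fabric_fields[s] = T[:nf]

    # stage schedule: (end_step, grid for the stage, boundary condition)
    stages: list[tuple[int, Grid1D, ConvectiveBC]] = []
    air = ConvectiveBC(timeline.h_air, timeline.T_air)
    water = ConvectiveBC(timeline.h_water, timeline.T_water_cool)
    if step_off is None:
        stages.append((n_total, grid, air))
    else:
        stages.append((step_off, grid, air))
        if step_cool is None:
            stages.append((n_total, skin_grid, air))
        else:
            stages.append((step_cool, skin_grid, air))
            stages.append((n_total, skin_grid, water))

    record(0, T, has_fabric=nf > 0)
    step_idx = 0
    for end_step, stage_grid, bc in stages:
        has_fabric = stage_grid.fabric_segment_count > 0
        if not has_fabric and T.size != n_skin:
            T = T[nf:].copy()  # fabric removed together with its enthalpy
        kern = _StageKernel(stage_grid, dt, bc, config.blood, config.Q_ext)
        while step_idx < end_step:
            n_chunk = min(
                end_step - step_idx,
                rec_stride - step_idx % rec_stride or rec_stride,
            )
            kern.run(T, n_chunk)
            step_idx += n_chunk
            _check_finite(T)
            record(step_idx, T, has_fabric)

    return TemperatureHistory(
        times=times,
        probes=probes,
        field_times=field_times,
        skin_fields=skin_fields,
        fabric_fields=fabric_fields,
        skin_nodes=skin_nodes,
        fabric_nodes=fabric_nodes,
        epidermis_thickness=epi,
        total_depth=stack.total_depth,
        stability_report=stability,
    )
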
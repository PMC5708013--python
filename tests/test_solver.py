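import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scaldsim as ss
from scaldsim.materials import InvalidParameterError
from scaldsim.solver import (
    ConvectiveBC,
    DirichletBC,
    ExposureTimeline,
    Grid1D,
    NumericalError,
    SolverConfig,
    StabilityError,
    _StageKernel,
    check_stability,
    probe,
    simulate,
    step,
)
from scaldsim.verification import HalfSpaceProblem, contact_temperature, half_space_temperature


def uniform_grid(n_seg: int, k: float = 1.0, rhoC: float = 1.0, dx: float = 1.0) -> Grid1D:
    return Grid1D(
        dx=dx,
        seg_k=np.full(n_seg, k),
        seg_rhoC=np.full(n_seg, rhoC),
        seg_labels=("slab",) * n_seg,
    )


class TestGrid:
    def test_default_case_geometry(self):
        grid = Grid1D.from_layers(
            ss.default_skin_stack(50e-6), ss.default_wet_fabric(1.0e-3, 85.0), dx=10e-6
        )
        assert grid.fabric_segment_count == 100
        assert grid.n_segments - grid.fabric_segment_count == 4205
        assert grid.n_nodes == 4306
        assert grid.nodes[0] == pytest.approx(-1.0e-3)
        assert grid.nodes[grid.n_fabric_nodes] == 0.0
        assert grid.nodes[-1] == pytest.approx(0.04205)

    def test_rejects_thickness_not_multiple_of_dx(self):
        stack = ss.default_skin_stack(45e-6)
        with pytest.raises(InvalidParameterError, match="multiple"):
            Grid1D.from_layers(stack, None, dx=10e-6)

    def test_interfaces_fall_on_nodes(self):
        stack = ss.default_skin_stack(50e-6)
        grid = Grid1D.from_layers(stack, None, dx=10e-6)
        for boundary in stack.layer_boundaries():
            assert np.any(np.isclose(grid.nodes, boundary))


class TestStability:
    def test_default_fourier_numbers(self):
        grid = Grid1D.from_layers(
            ss.default_skin_stack(), ss.default_wet_fabric(1.0e-3, 85.0), dx=10e-6
        )
        report = check_stability(grid, 2e-4)
        assert report["muscle"] == pytest.approx(0.237, abs=0.01)
        assert report["fabric"] == pytest.approx(0.361, abs=0.01)
        assert all(fo < 0.5 for fo in report.values())

    def test_zero_dt_gives_zero_fourier_numbers(self):
        grid = uniform_grid(5)
        assert all(fo == 0.0 for fo in check_stability(grid, 0.0).values())

    def test_guard_triggers_before_any_stepping(self):
        stack = ss.default_skin_stack()
        timeline = ExposureTimeline(t_end=1.0)
        config = SolverConfig(dt=5e-4)  # muscle Fo ~ 0.59
        with pytest.raises(StabilityError, match="Fourier"):
            simulate(stack, None, timeline, config)


class TestStep:
    def test_hand_computed_ftcs_update(self):
        """3-node rod, k=rhoC=dx=1, dt=0.1, T=[0,1,0]: center -> 0.8."""
        grid = uniform_grid(2)
        T = np.array([0.0, 1.0, 0.0])
        out = step(T, grid, dt=0.1)
        assert out[1] == pytest.approx(0.8)
        # end nodes carry half a cell each; total enthalpy is conserved
        cap = grid.node_capacity()
        assert float(cap @ out) == pytest.approx(float(cap @ T))

    def test_uniform_body_temperature_is_fixed_point(self):
        grid = Grid1D.from_layers(ss.default_skin_stack(), None, dx=10e-6)
        blood = ss.BloodModel(T_b=37.0, Q_met=0.0)
        T = np.full(grid.n_nodes, 37.0)
        out = step(T, grid, dt=2e-4, bc=None, blood=blood)
        assert out == pytest.approx(T, abs=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_energy_conserved_with_insulated_ends(self, seed):
        rng = np.random.default_rng(seed)
        grid = uniform_grid(20, k=0.3, rhoC=2.0, dx=0.01)
        T = rng.uniform(0.0, 100.0, grid.n_nodes)
        cap = grid.node_capacity()
        before = float(cap @ T)
        kern = _StageKernel(grid, dt=5e-5, bc=None, blood=ss.BloodModel(enabled=False), Q_ext=0.0)
        kern.run(T, 200)
        assert float(cap @ T) == pytest.approx(before, rel=1e-12)

    def test_divergent_state_raises_naming_the_node(self):
        grid = uniform_grid(3)
        T = np.array([0.0, np.nan, 0.0, 0.0])
        with pytest.raises(NumericalError, match="non-finite temperature"):
            step(T, grid, dt=0.1)


class TestSimulate:
    def test_all_body_temperature_stays_constant(self):
        """No fabric, 37 C air, blood at 37 C with no metabolism: nothing moves."""
        stack = ss.default_skin_stack()
        timeline = ExposureTimeline(t_end=0.5, T_air=37.0)
        config = SolverConfig(blood=ss.BloodModel(T_b=37.0, Q_met=0.0))
        history = simulate(stack, None, timeline, config)
        for series in history.probes.values():
            assert series == pytest.approx(np.full_like(series, 37.0), abs=1e-9)

    def test_maximum_principle(self, case_a_8s):
        """All temperatures stay between the coolest reservoir and T0_wf."""
        h = case_a_8s.history
        lo, hi = 20.0, ss.default_wet_fabric(1.0e-3, 85.0).T0_wf
        for name, series in h.probes.items():
            vals = series[np.isfinite(series)]
            assert np.all(vals >= lo - 1e-9), name
            assert np.all(vals <= hi + 1e-9), name
        assert np.nanmin(h.skin_fields) >= lo - 1e-9
        assert np.nanmax(h.skin_fields) <= hi + 1e-9

    def test_basal_peak_bounded_and_early(self, case_a_8s):
        r = case_a_8s
        assert 37.0 < r.basal_peak_temp < ss.default_wet_fabric(1.0e-3, 85.0).T0_wf
        assert r.basal_peak_time < 5.0

    def test_initial_conditions_via_probe(self, case_a_8s):
        h = case_a_8s.history
        assert probe(h, 0.0)[0] == pytest.approx(37.0)  # skin side at t = 0
        assert probe(h, -0.5e-3)[0] == pytest.approx(80.92, abs=0.01)  # mid-fabric
        assert h.probes["skin_surface"][0] == pytest.approx(37.0)

    def test_probe_interpolates_between_nodes(self, case_a_8s):
        h = case_a_8s.history
        mid = probe(h, 15e-6)
        lo, hi = probe(h, 10e-6), probe(h, 20e-6)
        assert mid == pytest.approx((lo + hi) / 2.0)

    def test_probe_rejects_depth_outside_domain(self, case_a_8s):
        with pytest.raises(InvalidParameterError):
            probe(case_a_8s.history, 1.0)
        with pytest.raises(InvalidParameterError):
            probe(case_a_8s.history, -2e-3)

    def test_fabric_probes_nan_after_removal(self):
        result = ss.run_case(ss.get_case("E"), t_end=4.0)  # fabric off at 2.5 s
        h = result.history
        before = h.times < 2.5
        assert np.all(np.isfinite(h.probes["fabric_center"][before]))
        assert np.all(np.isnan(h.probes["fabric_center"][h.times > 2.6]))

    def test_cooling_requires_fabric_removal_first(self):
        with pytest.raises(InvalidParameterError):
            ExposureTimeline(t_end=10.0, t_off=None, t_cool=5.0)
        with pytest.raises(InvalidParameterError):
            ExposureTimeline(t_end=10.0, t_off=5.0, t_cool=2.0)


class TestVerificationOracles:
    def test_half_space_erf_solution(self):
        """Dirichlet surface on a thick single-material slab matches erf profile."""
        slab = ss.LayerStack((ss.SkinLayer("slab", 0.40, 1200.0, 3600.0, 0.020),))
        grid = Grid1D.from_layers(slab, None, dx=1e-4)
        dt = 0.02
        T = np.full(grid.n_nodes, 37.0)
        kern = _StageKernel(grid, dt, DirichletBC(60.0), ss.BloodModel(enabled=False), 0.0)
        kern.run(T, round(10.0 / dt))
        p = HalfSpaceProblem(a=0.40 / (1200 * 3600), T_initial=37.0, T_surface=60.0)
        # compare on interior depths the heat wave has reached; domain still
        # effectively semi-infinite (2*sqrt(a*t) ~ 1.9 mm << 20 mm)
        for depth in (0.5e-3, 1e-3, 2e-3):
            num = float(np.interp(depth, grid.nodes, T))
            assert abs(num - half_space_temperature(p, depth, 10.0)) < 0.01 * 23.0

    def test_early_surface_temperature_matches_contact_oracle(self, case_a_8s):
        h = case_a_8s.history
        fabric = ss.default_wet_fabric(1.0e-3, 85.0)
        expected = contact_temperature(
            fabric.k_wet, fabric.rhoC_wet, fabric.T0_wf, 0.22, 1200 * 3600, 37.0
        )
        early = (h.times >= 0.01) & (h.times <= 0.1)
        surf = h.probes["skin_surface"][early]
        assert np.all(np.abs(surf - expected) < 2.0)


class TestGridConvergence:
    def test_refinement_changes_little(self):
        """Halving dx and quartering dt barely moves the base-case answer."""
        spec = ss.get_case("A")
        coarse = ss.run_case(spec, t_end=6.0)
        fine = ss.run_case(
            spec, t_end=6.0, config=SolverConfig(dt=5e-5, dx=5e-6)
        )
        assert abs(fine.basal_peak_temp - coarse.basal_peak_temp) < 0.5
        assert fine.omega_final == pytest.approx(coarse.omega_final, rel=0.05)
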
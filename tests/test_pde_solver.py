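import numpy as np
import pytest

from btu.binding_kinetics import equilibrium_bound
from btu.model_core import Domain, DosingParams, DrugParams, spatial_experiment_params
from btu.pde_solver import (
    Grid,
    SolverOptions,
    StateField,
    default_output_times,
    nondimensionalize,
    semidiscrete_rhs,
    simulate,
)


def uniform_equilibrium_state(dp: DrugParams, g: Grid, C: float) -> StateField:
    B1 = equilibrium_bound(C, dp.B1max, dp.k1on, dp.k1off) if dp.k1on else 0.0
    B2 = equilibrium_bound(C, dp.B2max, dp.k2on, dp.k2off) if dp.k2on else 0.0
    return StateField(
        t=0.0,
        C=np.full(g.shape, C),
        B1=np.full(g.shape, B1),
        B2=np.full(g.shape, B2),
    )


class TestSemidiscreteRhs:
    def test_closed_domain_steady_state(self):
        # P = 0, uniform C, binding at equilibrium: nothing moves
        dp = DrugParams(P=0.0)
        g = Grid.from_domain(Domain(nx=7, ny=7))
        state = uniform_equilibrium_state(dp, g, 0.8)
        d = semidiscrete_rhs(0.0, state, dp, DosingParams(), g)
        assert np.allclose(d.C, 0.0, atol=1e-12)
        assert np.allclose(d.B1, 0.0, atol=1e-12)
        assert np.allclose(d.B2, 0.0, atol=1e-12)

    def test_equilibrated_with_plasma(self):
        # uniform C = Cpl: the Robin terms vanish along with everything else
        dp = DrugParams()
        g = Grid.from_domain(Domain(nx=7, ny=7))
        cbar = 0.6
        state = uniform_equilibrium_state(dp, g, cbar)
        d = semidiscrete_rhs(0.0, state, dp, DosingParams(), g, cpl_fn=lambda t: cbar)
        assert np.allclose(d.C, 0.0, atol=1e-12)

    def test_interior_stencil_hand_arithmetic(self):
        # 3x3 grid; the single interior node sees the plain 5-point stencil
        dp = DrugParams(D_eff=2.0, v=3.0, P=0.0, B1max=0.0, B2max=0.0)
        dom = Domain(xr=2.0, yr=2.0, nx=3, ny=3)
        g = Grid.from_domain(dom)  # hx = hy = 1
        C = np.array(
            [
                [1.0, 2.0, 3.0],
                [4.0, 5.0, 6.0],
                [7.0, 8.0, 9.0],
            ]
        )
        state = StateField(t=0.0, C=C, B1=np.zeros((3, 3)), B2=np.zeros((3, 3)))
        d = semidiscrete_rhs(0.0, state, dp, DosingParams(), g, cpl_fn=lambda t: 0.0)
        # lap = (C[0,1] + C[2,1] + C[1,0] + C[1,2] - 4*C[1,1]) / 1
        lap = 2.0 + 8.0 + 4.0 + 6.0 - 4 * 5.0
        # adv (central) = (C[2,1] - C[0,1]) / 2
        adv = (8.0 - 2.0) / 2.0
        assert d.C[1, 1] == pytest.approx(dp.D_eff * lap - dp.v * adv)

    def test_boundary_robin_hand_arithmetic(self):
        # wall node (0,1): ghost value C[-1,1] = C[1,1] + 2*h*(P/D)*(Cpl-C[0,1])
        D, P, Cpl, h = 2.0, 0.5, 10.0, 1.0
        dp = DrugParams(D_eff=D, v=0.0, P=P, B1max=0.0, B2max=0.0)
        dom = Domain(xr=2.0, yr=2.0, nx=3, ny=3)
        g = Grid.from_domain(dom)
        C = np.array(
            [
                [1.0, 2.0, 3.0],
                [4.0, 5.0, 6.0],
                [7.0, 8.0, 9.0],
            ]
        )
        state = StateField(t=0.0, C=C, B1=np.zeros((3, 3)), B2=np.zeros((3, 3)))
        d = semidiscrete_rhs(0.0, state, dp, DosingParams(), g, cpl_fn=lambda t: Cpl)
        ghost = C[1, 1] + 2 * h * (P / D) * (Cpl - C[0, 1])
        lap_x = (ghost - 2 * C[0, 1] + C[1, 1]) / h**2
        lap_y = (C[0, 0] - 2 * C[0, 1] + C[0, 2]) / h**2
        assert d.C[0, 1] == pytest.approx(D * (lap_x + lap_y))

    def test_corner_gets_both_wall_closures(self):
        D, P, Cpl, h = 2.0, 0.5, 10.0, 1.0
        dp = DrugParams(D_eff=D, v=0.0, P=P, B1max=0.0, B2max=0.0)
        g = Grid.from_domain(Domain(xr=2.0, yr=2.0, nx=3, ny=3))
        C = np.arange(9.0).reshape(3, 3)
        state = StateField(t=0.0, C=C, B1=np.zeros((3, 3)), B2=np.zeros((3, 3)))
        d = semidiscrete_rhs(0.0, state, dp, DosingParams(), g, cpl_fn=lambda t: Cpl)
        gx = C[1, 0] + 2 * h * (P / D) * (Cpl - C[0, 0])
        gy = C[0, 1] + 2 * h * (P / D) * (Cpl - C[0, 0])
        lap = (gx - 2 * C[0, 0] + C[1, 0]) / h**2 + (gy - 2 * C[0, 0] + C[0, 1]) / h**2
        assert d.C[0, 0] == pytest.approx(D * lap)

    def test_nonfinite_state_rejected(self):
        dp = DrugParams()
        g = Grid.from_domain(Domain(nx=3, ny=3))
        C = np.zeros((3, 3))
        C[1, 1] = np.nan
        state = StateField(t=0.0, C=C, B1=np.zeros((3, 3)), B2=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="non-finite"):
            semidiscrete_rhs(3.5, state, dp, DosingParams(), g)

    def test_shape_mismatch_rejected(self):
        dp = DrugParams()
        g = Grid.from_domain(Domain(nx=5, ny=5))
        state = StateField(t=0.0, C=np.zeros((3, 3)), B1=np.zeros((3, 3)), B2=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="shape"):
            semidiscrete_rhs(0.0, state, dp, DosingParams(), g)


class TestSimulate:
    def test_zero_permeability_stays_zero(self, small_domain):
        dp = DrugParams(P=0.0)
        r = simulate(dp, DosingParams(), small_domain, t_end=1e4)
        assert np.all(r.center_C == 0.0)
        assert np.all(r.center_B1 == 0.0)
        assert r.diagnostics["max_B2"] == 0.0

    def test_deterministic(self, small_domain):
        dp, dos = DrugParams(), DosingParams()
        times = default_output_times(1e4, 50)
        r1 = simulate(dp, dos, small_domain, t_end=1e4, output_times=times)
        r2 = simulate(dp, dos, small_domain, t_end=1e4, output_times=times)
        assert np.array_equal(r1.center_C, r2.center_C)
        assert np.array_equal(r1.cpl, r2.cpl)

    def test_positivity_and_caps(self, default_run, defaults):
        dp, _, _ = defaults
        d = default_run.diagnostics
        assert d["min_C"] >= -1e-9
        assert d["min_B1"] >= -1e-9
        assert d["min_B2"] >= -1e-9
        assert d["max_B1"] <= dp.B1max * (1 + 1e-9)
        assert d["max_B2"] <= dp.B2max * (1 + 1e-9)

    def test_no_binding_crosses_cpl_after_peak(self, small_domain):
        dp = DrugParams(B1max=0.0, B2max=0.0)
        r = simulate(dp, DosingParams(), small_domain, t_end=2e5)
        k_peak = int(np.argmax(r.cpl))
        assert np.all(r.center_C[1 : k_peak + 1] <= r.cpl[1 : k_peak + 1])
        assert np.any(r.center_C[k_peak + 1 :] > r.cpl[k_peak + 1 :])

    def test_constant_forcing_well_mixed_closed_form(self, small_domain):
        # no binding + constant plasma: C(t) -> Cbar(1 - exp(-k_ex t))
        dp = DrugParams(B1max=0.0, B2max=0.0)
        dom = small_domain
        k_ex = 4.0 * dp.P / dom.xr
        times = default_output_times(1e5, 150)
        r = simulate(
            dp, DosingParams(), dom, t_end=1e5, output_times=times, cpl_fn=lambda t: 1.0
        )
        expected = 1.0 - np.exp(-k_ex * times)
        mask = times > 500.0
        rel = np.abs(r.center_C[mask] - expected[mask]) / expected[mask]
        assert np.max(rel) < 0.01

    def test_snapshots_at_requested_times(self, small_domain):
        dp, dos = DrugParams(), DosingParams()
        r = simulate(dp, dos, small_domain, t_end=1e4, snapshot_times=[100.0, 1e4])
        assert [s.t for s in r.snapshots] == [100.0, 1e4]
        assert r.snapshots[0].C.shape == (small_domain.nx, small_domain.ny)

    def test_invalid_t_end(self, small_domain):
        with pytest.raises(ValueError):
            simulate(DrugParams(), DosingParams(), small_domain, t_end=0.0)

    def test_output_times_outside_range(self, small_domain):
        with pytest.raises(ValueError):
            simulate(
                DrugParams(), DosingParams(), small_domain, t_end=10.0, output_times=[0.0, 20.0]
            )

    def test_upwind_scheme_close_to_central(self, small_domain):
        dp, dos = DrugParams(B1max=0.0, B2max=0.0), DosingParams()
        times = default_output_times(2e4, 50)
        rc = simulate(dp, dos, small_domain, t_end=2e4, output_times=times)
        ru = simulate(
            dp,
            dos,
            small_domain,
            t_end=2e4,
            output_times=times,
            opts=SolverOptions(advection_scheme="upwind"),
        )
        mask = times > 1000.0
        assert np.allclose(ru.center_C[mask], rc.center_C[mask], rtol=0.05)

    def test_advection_direction_early(self):
        # bulk flow in +x piles drug on the left half early on
        dp, dos, dom = spatial_experiment_params()
        dom = Domain(nx=21, ny=21)
        r = simulate(dp, dos, dom, t_end=250.0, output_times=[0.0, 250.0], snapshot_times=[250.0])
        C = r.snapshots[0].C
        nx = C.shape[0]
        assert np.mean(C[: nx // 2, :]) > np.mean(C[nx - nx // 2 :, :])


class TestNondimensionalize:
    def test_default_groups(self, defaults):
        dp, dos, dom = defaults
        groups = nondimensionalize(dp, dos, dom)
        assert groups["peclet"] == pytest.approx(0.5)
        assert groups["t_diffusion_s"] == pytest.approx(50.0)
        assert groups["biot"] == pytest.approx(1e-3)
        assert groups["exchange_rate_s^-1"] == pytest.approx(8e-5)

    def test_damkohler_scales_with_rates(self, defaults):
        dp, dos, dom = defaults
        g1 = nondimensionalize(dp, dos, dom)
        g2 = nondimensionalize(dp.with_(k1on=dp.k1on * 10), dos, dom)
        assert g2["damkohler_specific"] == pytest.approx(10 * g1["damkohler_specific"])


class TestGrid:
    def test_node_coordinates(self):
        g = Grid.from_domain(Domain(xr=1e-5, yr=2e-5, nx=5, ny=3))
        assert g.x[0] == 0.0
        assert g.x[-1] == pytest.approx(1e-5)
        assert g.y[1] == pytest.approx(1e-5)

    def test_center_index_odd_grid(self):
        g = Grid.from_domain(Domain(nx=51, ny=51))
        assert g.center_index() == (25, 25)

    def test_area_weights_sum_to_area(self):
        dom = Domain(xr=3e-5, yr=5e-5, nx=7, ny=9)
        g = Grid.from_domain(dom)
        assert np.sum(g.area_weights()) == pytest.approx(dom.xr * dom.yr)
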
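import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from vasotherm.core import (
    DEFAULT_TUMOR_BOX,
    Quantity,
    ScalarField,
    TissueProperties,
    make_grid,
    region_mask,
)
from vasotherm.solvers import (
    CBVNSystem,
    PerfusionModel,
    SolverConfig,
    SolverError,
    blood_path_profile,
    energy_balance,
    solve_cbvn,
    solve_keff,
    solve_pbhte,
    tumor_midplane_paths,
)
from vasotherm.vasculature import assign_flows, build_network


def dense_solution(grid, k, s, q, Ta=37.0):
    """Direct sparse solve of the same 7-point system (independent oracle)."""
    nx, ny, nz = grid.shape
    h = grid.spacing_m
    N = nx * ny * nz
    idx = np.arange(N).reshape(grid.shape)
    interior = np.zeros(grid.shape, bool)
    interior[1:-1, 1:-1, 1:-1] = True
    rows, cols, vals = [], [], []
    b = np.zeros(N)
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
            (0, 0, -1)]
    for I in range(N):
        i, j, kk = np.unravel_index(I, grid.shape)
        if not interior[i, j, kk]:
            rows.append(I); cols.append(I); vals.append(1.0)
            b[I] = Ta
            continue
        rows.append(I); cols.append(I); vals.append(6 * k / h**2 + s)
        b[I] = q[i, j, kk] + s * Ta
        for d in offs:
            rows.append(I)
            cols.append(int(idx[i + d[0], j + d[1], kk + d[2]]))
            vals.append(-k / h**2)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
    return spsolve(A, b).reshape(grid.shape)


@pytest.fixture(scope="module")
def small_case():
    grid = make_grid((16, 16, 16), 2)
    q = np.zeros(grid.shape)
    q[3:6, 3:6, 3:6] = 1e5
    return grid, ScalarField(grid, q, Quantity.power_Wm3)


class TestPennes:
    def test_zero_power_gives_exactly_body_temperature(self, grid9, props):
        q = ScalarField(grid9, np.zeros(grid9.shape), Quantity.power_Wm3)
        T = solve_pbhte(grid9, props, PerfusionModel(0.5), q)
        assert np.array_equal(T.values, np.full(grid9.shape, 37.0))

    @pytest.mark.parametrize("w_b", [0.0, 0.5])
    def test_matches_direct_sparse_solve(self, small_case, props, w_b):
        grid, q = small_case
        cfg = SolverConfig()
        T = solve_pbhte(grid, props, PerfusionModel(w_b), q, cfg)
        Td = dense_solution(grid, props.k_t, w_b * props.c_b, q.values)
        assert np.abs(T.values - Td).max() < 10 * cfg.tol

    def test_linearity_in_power(self, small_case, props):
        grid, q = small_case
        tight = SolverConfig(tol=1e-10)
        T1 = solve_pbhte(grid, props, PerfusionModel(0.5), q, tight)
        q2 = ScalarField(grid, 2 * q.values, Quantity.power_Wm3)
        T2 = solve_pbhte(grid, props, PerfusionModel(0.5), q2, tight)
        np.testing.assert_allclose(T2.values - 37, 2 * (T1.values - 37),
                                   rtol=1e-6, atol=1e-6)

    def test_increasing_perfusion_never_heats(self, small_case, props):
        grid, q = small_case
        T_low = solve_pbhte(grid, props, PerfusionModel(0.1), q)
        T_high = solve_pbhte(grid, props, PerfusionModel(1.0), q)
        assert (T_high.values <= T_low.values + 1e-5).all()

    def test_maximum_principle(self, small_case, props):
        grid, q = small_case
        T = solve_pbhte(grid, props, PerfusionModel(0.5), q)
        assert T.values.min() == pytest.approx(37.0, abs=1e-9)

    def test_nonconvergence_raises_with_history(self, small_case, props):
        grid, q = small_case
        with pytest.raises(SolverError) as e:
            solve_pbhte(grid, props, PerfusionModel(0.5), q,
                        SolverConfig(max_iters=3))
        assert len(e.value.residual_history) == 3


class TestKeff:
    def test_zero_power_is_uniform(self, grid9, props):
        q = ScalarField(grid9, np.zeros(grid9.shape), Quantity.power_Wm3)
        T = solve_keff(grid9, props, q=q)
        assert np.array_equal(T.values, np.full(grid9.shape, 37.0))

    def test_equals_pennes_without_perfusion(self, small_case, props):
        grid, q = small_case
        Tk = solve_keff(grid, props, SolverConfig(keff=props.k_t), q)
        Tp = solve_pbhte(grid, props, PerfusionModel(0.0), q)
        assert np.abs(Tk.values - Tp.values).max() < 1e-5

    def test_matches_direct_solve(self, small_case, props):
        grid, q = small_case
        cfg = SolverConfig(keff=0.5)
        T = solve_keff(grid, props, cfg, q)
        Td = dense_solution(grid, 0.5, 0.0, q.values)
        assert np.abs(T.values - Td).max() < 10 * cfg.tol


class TestCBVN:
    def test_no_flow_reduces_to_pure_conduction(self, grid, props,
                                                uniform_tumor_power):
        net = assign_flows(build_network(grid), 0.0)
        sol = solve_cbvn(grid, props, net, uniform_tumor_power)
        Tc = solve_pbhte(grid, props, PerfusionModel(0.0),
                         uniform_tumor_power)
        assert np.abs(sol.tissue.values - Tc.values).max() < 1e-5

    def test_linearity_in_power_with_flow(self, grid, props, network,
                                          uniform_tumor_power):
        system = CBVNSystem(grid, props, network)
        s1 = system.solve(uniform_tumor_power)
        q2 = ScalarField(grid, 2 * uniform_tumor_power.values,
                         Quantity.power_Wm3)
        s2 = system.solve(q2)
        np.testing.assert_allclose(
            s2.tissue.values - 37, 2 * (s1.tissue.values - 37),
            rtol=1e-5, atol=2e-5)

    def test_maximum_principle_and_venous_return(self, grid, props, network,
                                                 uniform_tumor_power):
        sol = solve_cbvn(grid, props, network, uniform_tumor_power)
        assert sol.tissue.values.min() == pytest.approx(37.0, abs=1e-9)
        for arr in sol.blood.values():
            assert (arr >= 37.0 - 1e-9).all()
        assert (sol.T_coll >= 37.0 - 1e-9).all()

    def test_single_vessel_profile_matches_exponential(self, grid, props,
                                                       network):
        # clamp the surrounding tissue and march the main artery: the blood
        # profile must follow T_w + (37 - T_w) exp(-pi Nu k_b s / (mdot c))
        system = CBVNSystem(grid, props, network)
        sd = next(s for s in system.art
                  if s.seg.level == 1 and s.seg.parent is None)
        T_w = 45.0
        T_flat = np.full(int(np.prod(grid.shape)), T_w)
        q_flat = np.zeros_like(T_flat)
        blood, exit_val = {}, {}
        system._march_tree([sd], T_flat, q_flat, blood, exit_val,
                           lambda _sd: 37.0)
        s_arc = np.arange(sd.path_idx.size) * grid.spacing_m
        U = np.pi * props.Nu * props.k_b
        analytic = T_w + (37.0 - T_w) * np.exp(
            -U * s_arc / (sd.seg.mass_flow * props.c_b))
        rel = np.abs(blood[sd.seg.id] - analytic).max() / (T_w - 37.0)
        assert rel < 0.01

    def test_energy_balance_converged(self, grid, props, network,
                                      uniform_tumor_power):
        system = CBVNSystem(grid, props, network)
        sol = system.solve(uniform_tumor_power)
        eb = energy_balance(sol, uniform_tumor_power, network, props,
                            system=system)
        assert eb <= 1e-3

    def test_energy_balance_flags_unconverged_state(self, grid, props,
                                                    network,
                                                    uniform_tumor_power):
        system = CBVNSystem(grid, props, network)
        # one coupling cycle from a cold start is far from steady state
        T = system.sor.new_field()
        blood = {}
        q_flat = uniform_tumor_power.values.ravel()
        d, T_exit, T_coll = system.march(T.ravel(), q_flat, blood)
        b = system._source(uniform_tumor_power.values[1:-1, 1:-1, 1:-1],
                           T.ravel(), T_exit)
        system.sor.sweep(T, b, 1.8)
        sol = system._package(T, blood, T_exit, T_coll, 1)
        assert energy_balance(sol, uniform_tumor_power, network, props,
                              system=system) > 1e-3

    def test_zero_energy_convention(self, grid, props, network):
        q0 = ScalarField(grid, np.zeros(grid.shape), Quantity.power_Wm3)
        sol = solve_cbvn(grid, props, network, q0)
        assert energy_balance(sol, q0, network, props) == 0.0

    def test_grid_mismatch_rejected(self, props, network):
        from vasotherm.core import ConfigurationError
        other = make_grid((16, 16, 16), 2)
        with pytest.raises(ConfigurationError):
            CBVNSystem(other, props, network)


class TestBloodProfiles:
    def test_midplane_path_endpoints_span_20mm(self, grid, props, network,
                                               uniform_tumor_power):
        sol = solve_cbvn(grid, props, network, uniform_tumor_power)
        art, ven = tumor_midplane_paths(network)
        for ids in (art, ven):
            prof = blood_path_profile(sol, ids, network)
            assert prof.s_m.iloc[0] == 0.0
            assert prof.s_m.iloc[-1] == pytest.approx(0.02)

    def test_zero_power_profile_is_body_temperature(self, grid, props,
                                                    network):
        q0 = ScalarField(grid, np.zeros(grid.shape), Quantity.power_Wm3)
        sol = solve_cbvn(grid, props, network, q0)
        art, _ = tumor_midplane_paths(network)
        prof = blood_path_profile(sol, art, network)
        assert np.abs(prof.T_C - 37.0).max() < 1e-6

    def test_noncontiguous_path_rejected(self, grid, props, network,
                                         uniform_tumor_power):
        from vasotherm.core import ConfigurationError
        sol = solve_cbvn(grid, props, network, uniform_tumor_power)
        art, ven = tumor_midplane_paths(network)
        with pytest.raises(ConfigurationError):
            blood_path_profile(sol, [art[0], ven[0]], network)


class TestGridRefinement:
    def test_halving_the_spacing_changes_little(self, grid, props):
        # inject a smooth tumor power field on 2-mm and 1-mm grids
        from scipy.interpolate import RegularGridInterpolator
        q2 = np.zeros(grid.shape)
        q2[region_mask(grid, DEFAULT_TUMOR_BOX)] = 1e5
        T2 = solve_pbhte(grid, props, PerfusionModel(0.5),
                         ScalarField(grid, q2, Quantity.power_Wm3))
        fine = make_grid((82, 80, 80), 1)
        interp = RegularGridInterpolator(
            [grid.axis_coords_mm(a) for a in range(3)], q2, method="linear")
        pts = np.stack(np.meshgrid(*[fine.axis_coords_mm(a) for a in range(3)],
                                   indexing="ij"), axis=-1)
        q1 = interp(pts.reshape(-1, 3)).reshape(fine.shape)
        T1 = solve_pbhte(fine, props, PerfusionModel(0.5),
                         ScalarField(fine, q1, Quantity.power_Wm3),
                         SolverConfig(tol=2e-6))
        diff = np.abs(T1.values[::2, ::2, ::2] - T2.values).max()
        assert diff < 0.5
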
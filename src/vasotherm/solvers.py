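"""Steady-state bioheat solvers: Pennes, effective-conductivity, and the
fully conjugated countercurrent vessel-network model.

All three models share a node-centered 7-point conduction stencil on the
uniform grid with 37 C Dirichlet conditions on the six faces, relaxed with
red-black successive over-relaxation (SOR).  Metabolic heating is neglected.

* Pennes (PBHTE):      div(k grad T) + w_b c_b (T_a - T) + q = 0
* Effective K (K_eff): div(K_eff grad T) + q = 0
* CBVN:                the tissue equation conjugately coupled to 1-D
  advective energy equations for the blood,
  mdot c_b dT_b/ds = U (T_t - T_b) + q A,  marched with first-order
  upwinding along the flow direction of every vessel segment.

In the CBVN model vessel-path nodes are blood cells embedded in the grid:
they are excluded from the tissue unknowns, power deposited on them is
absorbed entirely by the blood, and each neighboring tissue node exchanges
heat with the blood through a conductance that combines the intravascular
film (constant Nusselt number: h pi D = pi Nu k_b per unit length,
independent of diameter) in series with the logarithmic conduction
resistance ln(r_t/R)/(2 pi k_t) between the vessel wall and the tissue
sample point at r_t (one grid spacing by default).  This replaces the plain
conduction link of the 7-point stencil, so a large fast vessel pins the
local temperature to the blood temperature while a slow one barely perturbs
the field.  The tissue keeps the same Pennes-form perfusion sink
w c_b (37 - T) as the PBHTE; each terminal artery delivers its blood to one
subvolume, and the draining vein collects it at the delivery temperature
plus the subvolume's mean tissue pickup, so the blood stream carries exactly
the heat the sink removed and the discrete energy balance of the control
volume is exact up to solver tolerance.  Vein junctions mix enthalpy
conservatively.  Segments carrying zero flow are thermally inert (not
embedded), so a no-flow network reduces exactly to pure conduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    Grid3D,
    Quantity,
    ScalarField,
    TissueProperties,
    node_volume_weights,
)
from .vasculature import ARTERY, VEIN, VesselNetwork

__all__ = [
    "PerfusionModel",
    "SolverConfig",
    "CBVNSolution",
    "CBVNSystem",
    "SolverError",
    "solve_pbhte",
    "solve_keff",
    "solve_cbvn",
    "energy_balance",
    "blood_path_profile",
    "tumor_midplane_paths",
]


class SolverError(RuntimeError):
    """Raised on non-convergence; carries the residual (max-update) history."""

    def __init__(self, msg: str, history: list[float]):
        super().__init__(msg)
        self.residual_history = history


@dataclass(frozen=True)
class PerfusionModel:
    """Uniform Pennes perfusion: rate w_b (kg m^-3 s^-1), supply temp T_a."""

    w_b: float = 0.5
    T_a: float = 37.0

    def __post_init__(self) -> None:
        if self.w_b < 0:
            raise ConfigurationError("perfusion rate must be non-negative")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters shared by the three solvers.

    omega : SOR relaxation factor (1 <= omega < 2).
    tol : convergence tolerance on the max node update per sweep, C.
    max_iters : maximum number of SOR sweeps (or coupling cycles for CBVN).
    keff : effective conductivity for the K_eff model, W m^-1 C^-1.
    r_t_factor : tissue sample radius of the logarithmic vessel-wall
        resistance, as a fraction of the grid spacing.  The default 0
        identifies the wall temperature with the adjacent tissue nodes, so
        the constant-Nusselt film alone governs the exchange; positive
        values reinstate an explicit wall-to-node conduction resistance
        ln(r_t/R)/(2 pi k_t) in series for sensitivity studies.
    coupling_sweeps : tissue SOR sweeps between consecutive blood marches.
    """

    omega: float = 1.8
    tol: float = 1e-6
    max_iters: int = 100_000
    keff: float = 0.5
    r_t_factor: float = 0.0
    coupling_sweeps: int = 2

    def __post_init__(self) -> None:
        if not 1.0 <= self.omega < 2.0:
            raise ConfigurationError("omega must satisfy 1 <= omega < 2")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")


class _TissueSOR:
    """Vectorized red-black SOR for the 7-point stencil with Dirichlet faces.

    Normalized interior equation:  diag*T = (k/h^2) * nb_sum + b.
    ``frozen`` marks interior nodes excluded from the update (blood cells).
    """

    def __init__(self, grid: Grid3D, k: float, diag_extra, T_boundary: float,
                 frozen: np.ndarray | None = None):
        self.grid = grid
        self.h = grid.spacing_m
        self.coef = k / self.h**2
        nx, ny, nz = grid.shape
        ii, jj, kk = np.meshgrid(
            np.arange(1, nx - 1), np.arange(1, ny - 1), np.arange(1, nz - 1),
            indexing="ij")
        free = np.ones(ii.shape, bool) if frozen is None else ~frozen
        self.red = ((ii + jj + kk) % 2 == 0) & free
        self.black = ((ii + jj + kk) % 2 == 1) & free
        self.diag = 6.0 * self.coef + diag_extra  # scalar or interior array
        self.T_boundary = T_boundary

    def new_field(self) -> np.ndarray:
        return np.full(self.grid.shape, self.T_boundary, dtype=float)

    def _nb_sum(self, T: np.ndarray) -> np.ndarray:
        return (T[:-2, 1:-1, 1:-1] + T[2:, 1:-1, 1:-1]
                + T[1:-1, :-2, 1:-1] + T[1:-1, 2:, 1:-1]
                + T[1:-1, 1:-1, :-2] + T[1:-1, 1:-1, 2:])

    def sweep(self, T: np.ndarray, b: np.ndarray, omega: float) -> float:
        """One red-black SOR sweep in place; returns the max node update."""
        dmax = 0.0
        Tin = T[1:-1, 1:-1, 1:-1]
        for mask in (self.red, self.black):
            target = (self.coef * self._nb_sum(T) + b) / self.diag
            dT = omega * (target - Tin)
            Tin[mask] += dT[mask]
            dmax = max(dmax, float(np.max(np.abs(dT[mask]), initial=0.0)))
        return dmax


def _interior(q: ScalarField) -> np.ndarray:
    return q.values[1:-1, 1:-1, 1:-1]


def solve_pbhte(
    grid: Grid3D,
    props: TissueProperties,
    perfusion: PerfusionModel,
    q: ScalarField,
    config: SolverConfig = SolverConfig(),
    T0: ScalarField | None = None,
) -> ScalarField:
    """Steady Pennes solution with 37 C Dirichlet faces.

    ``T0`` optionally warm-starts the iteration.  Raises
    :class:`SolverError` (with the update history) on non-convergence.
    """
    s = perfusion.w_b * props.c_b
    sor = _TissueSOR(grid, props.k_t, s, props.T_body)
    b = _interior(q) + s * perfusion.T_a
    T = sor.new_field() if T0 is None else T0.values.copy()
    history: list[float] = []
    for _ in range(config.max_iters):
        d = sor.sweep(T, b, config.omega)
        history.append(d)
        if d < config.tol:
            return ScalarField(grid, T, Quantity.temperature_C)
    raise SolverError(
        f"PBHTE SOR did not converge in {config.max_iters} sweeps "
        f"(last update {history[-1]:.3g} C)", history)


def solve_keff(
    grid: Grid3D,
    props: TissueProperties,
    config: SolverConfig = SolverConfig(),
    q: ScalarField | None = None,
    T0: ScalarField | None = None,
) -> ScalarField:
    """Effective-conductivity solution: pure conduction with K_eff."""
    if q is None:
        raise ConfigurationError("solve_keff requires a power field")
    sor = _TissueSOR(grid, config.keff, 0.0, props.T_body)
    b = _interior(q).astype(float)
    T = sor.new_field() if T0 is None else T0.values.copy()
    history: list[float] = []
    for _ in range(config.max_iters):
        d = sor.sweep(T, b, config.omega)
        history.append(d)
        if d < config.tol:
            return ScalarField(grid, T, Quantity.temperature_C)
    raise SolverError(
        f"K_eff SOR did not converge in {config.max_iters} sweeps", history)


# ---------------------------------------------------------------------------
# CBVN


@dataclass
class CBVNSolution:
    """Converged conjugate solution.

    ``tissue`` holds the grid temperature field; at embedded vessel nodes the
    stored value is the local blood temperature (the temperature of the
    medium occupying that cell).  ``blood``/``wall`` map segment id to the
    per-path-node blood and vessel-wall temperatures.
    """

    tissue: ScalarField
    blood: dict[int, np.ndarray]
    wall: dict[int, np.ndarray]
    T_exit: np.ndarray        # terminal-artery exit temp per subvolume
    T_coll: np.ndarray        # terminal-vein collection temp per subvolume
    iterations: int = 0
    converged: bool = True


class _SegData:
    """March-ready arrays for one active (flow-carrying) segment.

    ``a_prev``/``den`` implement the upwind cell recurrence
    T[j] = (a_prev[j] T[j-1] + rhs[j]) / den[j]; terminal segments carry the
    distributed bleed-off (arteries) or collection (veins) of their
    subvolume's perfusion along their length, so their advective capacity
    tapers linearly to zero at the tip.
    """

    __slots__ = ("seg", "path_idx", "own_pos", "own_idx", "K", "nb_idx",
                 "nb_w", "nb_ptr", "mc", "sv", "a_prev", "den", "coll_coef")

    def __init__(self, seg, path_idx, own_pos, own_idx, K, nb_idx, nb_w,
                 nb_ptr, mc, sv):
        self.seg = seg
        self.path_idx = path_idx
        self.own_pos = own_pos
        self.own_idx = own_idx
        self.K = K
        self.nb_idx = nb_idx
        self.nb_w = nb_w
        self.nb_ptr = nb_ptr
        self.mc = mc
        self.sv = sv
        n = own_pos.size
        if sv >= 0 and seg.kind == ARTERY:
            frac = (n - np.arange(n)) / n
            self.a_prev = mc * frac
            self.den = self.a_prev + K
            self.coll_coef = np.zeros(n)
        elif sv >= 0 and seg.kind == VEIN:
            self.a_prev = mc * np.arange(n) / n
            self.coll_coef = np.full(n, mc / n)
            self.den = self.a_prev + self.coll_coef + K
        else:
            self.a_prev = np.full(n, mc)
            self.den = self.a_prev + K
            self.coll_coef = np.zeros(n)


_NB_OFFSETS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]])


class CBVNSystem:
    """Precomputed conjugate system for one network on one grid.

    Reusable across solves with different power fields (the optimizer calls
    :meth:`solve` once per outer iteration, warm-starting from the previous
    solution).
    """

    def __init__(self, grid: Grid3D, props: TissueProperties,
                 network: VesselNetwork, config: SolverConfig = SolverConfig()):
        if network.grid.shape != grid.shape:
            raise ConfigurationError("network was built on a different grid")
        if network.w_b is None:
            raise ConfigurationError("assign_flows must be called first")
        self.grid, self.props, self.net, self.config = grid, props, network, config
        h = grid.spacing_m
        self.h = h
        self.film = np.pi * props.Nu * props.k_b     # W m^-1 K^-1
        shape = grid.shape
        n_nodes = int(np.prod(shape))

        art_topo = network.topological_order(ARTERY)
        vein_topo = list(reversed(network.topological_order(VEIN)))
        active = lambda s: s.mass_flow > 0.0
        self.inert = [s for s in art_topo + vein_topo if not active(s)]

        # every path node of an active segment is a blood cell
        vessel = np.zeros(shape, bool)
        for s in art_topo + vein_topo:
            if active(s):
                vessel[tuple(s.path.T)] = True
        self.vessel3d = vessel
        vessel_flat = vessel.ravel()
        boundary = np.ones(shape, bool)
        boundary[1:-1, 1:-1, 1:-1] = False
        self.boundary_flat = boundary.ravel()

        corr_t, corr_v, corr_w = [], [], []          # tissue-side corrections
        self.bexch_val_slots: list[tuple[int, float]] = []  # (flat own slot, kappa)
        k_cond = props.k_t * h                        # plain conduction link, W/K

        owned_seen = np.zeros(n_nodes, bool)

        def build(seg):
            R = seg.diameter / 2
            r_t = config.r_t_factor * h
            log_res = (np.log(r_t / R) / (2 * np.pi * props.k_t)
                       if r_t > R else 0.0)
            U = 1.0 / (1.0 / self.film + log_res)
            G = U * h                                 # per blood cell, W/K
            path = seg.path
            m = path.shape[0] - 1
            if seg.kind == ARTERY:
                own_pos = np.arange(1, m + 1)
            else:
                own_pos = np.arange(0, m) if seg.parent is not None \
                    else np.arange(0, m + 1)
            path_idx = np.ravel_multi_index(path.T, shape)
            own_idx = path_idx[own_pos]
            if np.any(owned_seen[own_idx]):
                raise ConfigurationError("vessel node owned twice")
            owned_seen[own_idx] = True

            K = np.zeros(own_pos.size)
            nb_idx, nb_w, ptr = [], [], []
            for j, pos in enumerate(own_pos):
                ptr.append(len(nb_idx))
                node = path[pos]
                if self.boundary_flat[own_idx[j]]:
                    nb_idx.append(0)                 # dummy, weight 0
                    nb_w.append(0.0)
                    continue
                links = []
                for off in _NB_OFFSETS:
                    nb = node + off
                    fi = int(np.ravel_multi_index(nb, shape))
                    if not vessel_flat[fi]:
                        links.append(fi)
                if not links:
                    nb_idx.append(0)
                    nb_w.append(0.0)
                    continue
                kappa = G / len(links)
                K[j] = G
                for fi in links:
                    nb_idx.append(fi)
                    nb_w.append(kappa)
                    if self.boundary_flat[fi]:
                        self.bexch_val_slots.append((len(self.own_all) + j, kappa))
                    else:
                        corr_t.append(fi)
                        corr_v.append(own_idx[j])
                        corr_w.append(kappa - k_cond)
            sv = self._sv_of.get(seg.id, -1)
            return _SegData(seg, path_idx, own_pos, own_idx, K,
                            np.array(nb_idx), np.array(nb_w),
                            np.array(ptr), seg.mass_flow * props.c_b, sv)

        self._sv_of = {sv.feeding_artery: sv.index - 1 for sv in network.subvolumes}
        self._sv_of.update({sv.draining_vein: sv.index - 1
                            for sv in network.subvolumes})
        self.own_all: list[int] = []                  # flat idx, march order
        self.art: list[_SegData] = []
        self.vein: list[_SegData] = []
        for s in art_topo:
            if active(s):
                sd = build(s)
                self.art.append(sd)
                self.own_all.extend(sd.own_idx.tolist())
        for s in vein_topo:
            if active(s):
                sd = build(s)
                self.vein.append(sd)
                self.own_all.extend(sd.own_idx.tolist())
        self.own_all = np.array(self.own_all, dtype=np.intp)
        own_interior = ~self.boundary_flat[self.own_all]
        self.scatter_idx = self.own_all[own_interior]
        self.scatter_sel = np.nonzero(own_interior)[0]

        self.corr_t = np.array(corr_t, dtype=np.intp)
        self.corr_v = np.array(corr_v, dtype=np.intp)
        self.corr_w = np.array(corr_w)
        diag_corr = np.zeros(n_nodes)
        np.add.at(diag_corr, self.corr_t, self.corr_w)

        self.parent = {s.id: s.parent for s in network.segments.values()}

        # perfusion sink: per-box trapezoidal node shares, blood cells excluded
        sv_idx_l, sv_share_l, sv_vol = [], [], []
        for sv in network.subvolumes:
            w = node_volume_weights(grid, sv.box).ravel()
            w[vessel_flat] = 0.0
            nz = np.nonzero(w)[0]
            sv_idx_l.append(nz)
            sv_share_l.append(w[nz])
            sv_vol.append(sv.box.volume_m3())
        self.sv_vol = np.array(sv_vol)
        self.svcat_idx = np.concatenate(sv_idx_l)
        self.svcat_share = np.concatenate(sv_share_l)
        self.svcat_svid = np.repeat(
            np.arange(len(sv_idx_l)), [a.size for a in sv_idx_l])
        self.sv_share0 = np.bincount(
            self.svcat_svid, self.svcat_share, minlength=self.sv_vol.size)
        self.sink_w = np.zeros(n_nodes)
        np.add.at(self.sink_w, self.svcat_idx, self.svcat_share)
        self.s_perf = network.w_b * props.c_b

        frozen = vessel[1:-1, 1:-1, 1:-1]
        self.sor = _TissueSOR(
            grid, props.k_t,
            self.s_perf + diag_corr.reshape(shape)[1:-1, 1:-1, 1:-1] / h**3,
            props.T_body, frozen=frozen)

    # -- blood march --------------------------------------------------------

    def _march_tree(self, tree: list[_SegData], T_flat, q_flat,
                    blood: dict[int, np.ndarray], exit_val: dict[int, float],
                    inlet_of, coll_of=None) -> float:
        h3 = self.h**3
        dmax = 0.0
        for sd in tree:
            T0 = inlet_of(sd)
            S = np.add.reduceat(sd.nb_w * T_flat[sd.nb_idx], sd.nb_ptr) \
                if sd.nb_idx.size else np.zeros(0)
            rhs = S + q_flat[sd.own_idx] * h3
            if coll_of is not None and sd.sv >= 0:
                rhs = rhs + sd.coll_coef * coll_of(sd)
            a, den = sd.a_prev, sd.den
            out = np.empty(sd.own_pos.size)
            prev = T0
            for j in range(out.size):
                prev = (a[j] * prev + rhs[j]) / den[j]
                out[j] = prev
            m = sd.path_idx.size - 1
            full = np.empty(m + 1)
            full[sd.own_pos] = out
            if sd.own_pos[0] != 0:
                full[0] = T0                          # artery junction inlet
            if sd.own_pos[-1] != m:
                full[m] = out[-1]                     # vein junction handoff
            old = blood.get(sd.seg.id)
            dmax = (np.inf if old is None
                    else max(dmax, float(np.max(np.abs(full - old)))))
            blood[sd.seg.id] = full
            # terminal arteries bleed uniformly along their length: the
            # delivery temperature is the mean over their cells
            exit_val[sd.seg.id] = (float(out.mean())
                                   if sd.sv >= 0 and sd.seg.kind == ARTERY
                                   else prev)
        return dmax

    def march(self, T_flat, q_flat, blood: dict[int, np.ndarray]):
        """March arteries, update subvolume temps, then veins (in place).

        Writes the owned blood temperatures back into the grid field and
        returns (max blood update, T_exit, T_coll).
        """
        Tb37 = self.props.T_body
        exit_val: dict[int, float] = {}

        def art_inlet(sd):
            pid = self.parent[sd.seg.id]
            return Tb37 if pid is None else exit_val[pid]

        d1 = self._march_tree(self.art, T_flat, q_flat, blood, exit_val,
                              art_inlet)
        T_exit = np.full(self.sv_vol.size, Tb37)
        for sd in self.art:
            if sd.sv >= 0:
                T_exit[sd.sv] = exit_val[sd.seg.id]

        S1 = np.bincount(self.svcat_svid,
                         self.svcat_share * T_flat[self.svcat_idx],
                         minlength=self.sv_vol.size)
        # veins collect blood at the surrounding tissue temperature
        T_coll = np.where(self.sv_share0 > 0, S1 / np.where(
            self.sv_share0 > 0, self.sv_share0, 1.0), Tb37)

        inflow: dict[int, tuple[float, float]] = {}

        def vein_inlet(sd):
            if sd.sv >= 0:
                return float(T_coll[sd.sv])
            if sd.seg.id in inflow:
                mT, m = inflow[sd.seg.id]
                return mT / m if m > 0 else Tb37
            return Tb37                               # through-flow inlet

        # accumulate junction mixing as children finish
        d2 = 0.0
        for sd in self.vein:
            T0 = vein_inlet(sd)
            d2 = max(d2, self._march_tree(
                [sd], T_flat, q_flat, blood, exit_val, lambda _sd: T0,
                coll_of=lambda s: float(T_coll[s.sv])))
            pid = self.parent[sd.seg.id]
            if pid is not None:
                mT, m = inflow.get(pid, (0.0, 0.0))
                inflow[pid] = (mT + sd.seg.mass_flow * exit_val[sd.seg.id],
                               m + sd.seg.mass_flow)

        # embed blood temperatures into the grid field (interior cells only)
        vals = np.concatenate([blood[sd.seg.id][sd.own_pos]
                               for sd in self.art + self.vein]) \
            if self.art or self.vein else np.zeros(0)
        if self.scatter_idx.size:
            T_flat[self.scatter_idx] = vals[self.scatter_sel]
        self._last_exch_vals = vals
        return max(d1, d2), T_exit, T_coll

    def _source(self, q_int, T_flat, T_exit) -> np.ndarray:
        """Interior source term b: power + Pennes-form perfusion supply at
        body temperature + blood-cell coupling corrections."""
        n = self.sink_w.size
        b_corr = np.zeros(n)
        if self.corr_t.size:
            np.add.at(b_corr, self.corr_t, self.corr_w * T_flat[self.corr_v])
        shp = self.grid.shape
        return (q_int + self.s_perf * self.props.T_body
                + _to_interior(b_corr.reshape(shp)) / self.h**3)

    def solve(self, q: ScalarField,
              init: CBVNSolution | None = None) -> CBVNSolution:
        cfg = self.config
        if init is not None:
            T = init.tissue.values.copy()
            blood = {k: v.copy() for k, v in init.blood.items()
                     if k in {sd.seg.id for sd in self.art + self.vein}}
        else:
            T = self.sor.new_field()
            blood = {}
        T_flat = T.ravel()
        q_flat = q.values.ravel()
        q_int = _interior(q)
        d_b, T_exit, T_coll = self.march(T_flat, q_flat, blood)
        history: list[float] = []
        for it in range(cfg.max_iters):
            b = self._source(q_int, T_flat, T_exit)
            d_t = 0.0
            for _ in range(cfg.coupling_sweeps):
                d_t = self.sor.sweep(T, b, cfg.omega)
            d_b, T_exit, T_coll = self.march(T_flat, q_flat, blood)
            history.append(max(d_t, d_b))
            if d_t < cfg.tol and d_b < cfg.tol:
                return self._package(T, blood, T_exit, T_coll, it + 1)
        raise SolverError(
            f"CBVN coupling did not converge in {cfg.max_iters} cycles "
            f"(last update {history[-1]:.3g} C)", history)

    def _package(self, T, blood, T_exit, T_coll, iters) -> CBVNSolution:
        T_flat = T.ravel()
        wall: dict[int, np.ndarray] = {}
        for sd in self.art + self.vein:
            Tb = blood[sd.seg.id]
            S = np.add.reduceat(sd.nb_w * T_flat[sd.nb_idx], sd.nb_ptr) \
                if sd.nb_idx.size else np.zeros(0)
            w = Tb.copy()
            own = Tb[sd.own_pos]
            # wall temperature from the film temperature drop
            q_exch = S - sd.K * own
            w[sd.own_pos] = own + q_exch / (self.film * self.h)
            wall[sd.seg.id] = w
        for seg in self.inert:
            idx = np.ravel_multi_index(seg.path.T, self.grid.shape)
            blood[seg.id] = T_flat[idx].copy()
            wall[seg.id] = T_flat[idx].copy()
        return CBVNSolution(
            tissue=ScalarField(self.grid, T, Quantity.temperature_C),
            blood=blood, wall=wall, T_exit=T_exit, T_coll=T_coll,
            iterations=iters, converged=True)


def _to_interior(arr3d: np.ndarray) -> np.ndarray:
    return arr3d[1:-1, 1:-1, 1:-1]


def solve_cbvn(
    grid: Grid3D,
    props: TissueProperties,
    network: VesselNetwork,
    q: ScalarField,
    config: SolverConfig = SolverConfig(),
    init: CBVNSolution | None = None,
    system: CBVNSystem | None = None,
) -> CBVNSolution:
    """Solve the conjugate tissue/vessel-network problem for one power field."""
    if system is None:
        system = CBVNSystem(grid, props, network, config)
    return system.solve(q, init=init)


# ---------------------------------------------------------------------------
# Diagnostics


def energy_balance(solution: CBVNSolution, q: ScalarField,
                   network: VesselNetwork,
                   props: TissueProperties = TissueProperties(),
                   config: SolverConfig = SolverConfig(),
                   system: CBVNSystem | None = None) -> float:
    """Relative energy imbalance |P_in - P_out| / P_in of a converged run.

    P_in is the absorbed power (the blood enthalpy inflow is zero relative to
    the 37 C reference since all inlets enter at 37 C); P_out collects the
    conduction flux through the six faces, the enthalpy of the two blood
    outlets, the blood exchange with clamped boundary nodes, and the net
    heat routed through the perfusion bleed-off channel (the Pennes-form
    sink absorbs w c_b (T - 37) from tissue while the veins recover the
    collected-minus-delivered enthalpy; the difference leaves the model at
    the terminal ends and is reported here as an outflow).  Returns 0 by
    convention when no power is absorbed.
    """
    grid = q.grid
    h = grid.spacing_m
    T = solution.tissue.values
    Tb37 = props.T_body
    P_in = float(np.sum(q.values[1:-1, 1:-1, 1:-1])) * h**3
    if P_in == 0:
        return 0.0

    sys_ = system or CBVNSystem(grid, props, network, config)
    vessel = sys_.vessel3d

    k = props.k_t
    cond = 0.0
    for ax in range(3):
        for side in (0, -1):
            b_ = np.take(T, side, axis=ax)
            i_ = np.take(T, 1 if side == 0 else -2, axis=ax)
            iv = np.take(vessel, 1 if side == 0 else -2, axis=ax)
            sl = (slice(1, -1), slice(1, -1))
            ok = ~iv[sl]                      # links from tissue cells only
            cond += float(np.sum((i_[sl] - b_[sl])[ok]))
    P_cond = k * h * cond

    # blood exchange with clamped boundary neighbours
    P_vessel_bnd = 0.0
    if sys_.bexch_val_slots:
        all_own = np.concatenate([solution.blood[sd.seg.id][sd.own_pos]
                                  for sd in sys_.art + sys_.vein])
        for slot, kappa in sys_.bexch_val_slots:
            P_vessel_bnd += kappa * (all_own[slot] - Tb37)

    H_out = 0.0
    c_b = props.c_b
    for seg in network.iter_segments(ARTERY, level=1):
        if not any(network.segments[c].level == 1 for c in seg.children):
            H_out += seg.mass_flow * c_b * (solution.blood[seg.id][-1] - Tb37)
    for seg in network.iter_segments(VEIN, level=1):
        if seg.parent is None:
            H_out += seg.mass_flow * c_b * (solution.blood[seg.id][-1] - Tb37)

    # perfusion bleed-off channel: tissue sink minus blood enthalpy recovery
    T_flat = T.ravel()
    sink_total = sys_.s_perf * float(np.sum(
        sys_.svcat_share * (T_flat[sys_.svcat_idx] - Tb37)))
    mdot_I = network.w_b * sys_.sv_vol
    subvol_gain = float(np.sum(
        mdot_I * c_b * (solution.T_coll - solution.T_exit)))
    P_bleed = sink_total - subvol_gain

    P_out = P_cond + H_out + P_vessel_bnd + P_bleed
    return abs(P_in - P_out) / P_in


def blood_path_profile(solution: CBVNSolution, level_path: Sequence[int],
                       network: VesselNetwork) -> pd.DataFrame:
    """Arc-length-parameterized blood temperatures along contiguous segments.

    ``level_path`` lists segment ids in traversal order; consecutive segments
    must share a junction node.  Returns columns segment_id, level, kind,
    s_m, T_C.
    """
    rows = []
    s = 0.0
    h = network.grid.spacing_m
    prev_end = None
    for sid in level_path:
        if sid not in solution.blood:
            raise ConfigurationError(f"segment {sid} not in solution")
        seg = network.segments[sid]
        Tb = solution.blood[sid]
        if prev_end is not None and not np.array_equal(seg.path[0], prev_end):
            raise ConfigurationError("path segments are not contiguous")
        start = 1 if prev_end is not None else 0
        if start:
            s += h                # step from the shared junction node
        for n in range(start, seg.path.shape[0]):
            rows.append({"segment_id": sid, "level": seg.level,
                         "kind": seg.kind, "s_m": s, "T_C": float(Tb[n])})
            if n < seg.path.shape[0] - 1:
                s += h
        prev_end = seg.path[-1]
    return pd.DataFrame(rows)


def tumor_midplane_paths(network: VesselNetwork) -> tuple[list[int], list[int]]:
    """Canonical level-5 + level-6 routes at the tumor mid-plane (x = 52 mm).

    Returns (arterial segment ids, venous segment ids).  The arterial route
    runs from the station junction (52, 60, 60) to the level 6-7 corner
    (52, 50, 50); the venous route is the countercurrent mirror traversed in
    its flow direction (from the corner back toward the junction).
    """
    g = network.grid

    def find(kind, level, a_mm, b_mm):
        a = np.array(g.mm_to_node(a_mm))
        b = np.array(g.mm_to_node(b_mm))
        for seg in network.iter_segments(kind, level):
            if (np.array_equal(seg.path[0], a)
                    and np.array_equal(seg.path[-1], b)):
                return seg.id
        raise ConfigurationError(f"no {kind} level-{level} segment {a_mm}->{b_mm}")

    art = [find(ARTERY, 5, (52, 60, 60), (52, 60, 50)),
           find(ARTERY, 6, (52, 60, 50), (52, 50, 50))]
    ven = [find(VEIN, 6, (54, 52, 52), (54, 62, 52)),
           find(VEIN, 5, (54, 62, 52), (54, 62, 62))]
    return art, ven
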
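"""Plane extraction, summary metrics, and the full reproduction driver.

The canonical views are the five cross-section planes x = 38, 42, 52, 62
and 66 mm: 4 mm before the treated region, its front face, its mid-plane,
its back face, and 4 mm behind it.  Contour-ready slices carry the standard
iso-level sets used for temperature and power fields.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    Grid3D,
    Quantity,
    ScalarField,
    absorbed_power,
    region_mask,
    write_csv,
    write_vtk,
)
from .optimizer import (
    OptimizerConfig,
    Scene,
    gamma_sweep,
    optimize,
    perfusion_sweep,
)
from .solvers import (
    CBVNSystem,
    blood_path_profile,
    energy_balance,
    tumor_midplane_paths,
)
from .vasculature import assign_flows, build_network, vessel_speed

__all__ = [
    "PlaneSlice",
    "extract_plane",
    "plane_max",
    "TEMP_LEVELS_C",
    "POWER_LEVELS_WM3",
    "TEMP_LEVELS_FINE_C",
    "POWER_LEVELS_FINE_WM3",
    "DEFAULT_VIEW_PLANES_MM",
    "reproduce_results",
]

#: Standard 6-level iso-contour sets for plane views
TEMP_LEVELS_C = [38, 39, 40, 41, 42, 43]
POWER_LEVELS_WM3 = [30_000, 60_000, 90_000, 120_000, 150_000, 180_000]
#: Fine 13/15-level sets used for the low-perfusion views
TEMP_LEVELS_FINE_C = [37, 37.5, 38, 38.5, 39, 39.5, 40, 40.5, 41, 41.5,
                      42, 42.5, 43]
POWER_LEVELS_FINE_WM3 = [3.0e4, 2.3e5, 4.3e5, 6.3e5, 8.3e5, 1.0e6, 1.2e6,
                         1.4e6, 1.6e6, 1.8e6, 2.0e6, 2.2e6, 2.4e6, 2.6e6,
                         2.8e6]
DEFAULT_VIEW_PLANES_MM = (38.0, 42.0, 52.0, 62.0, 66.0)

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class PlaneSlice:
    axis: str
    coordinate_mm: float
    values: np.ndarray
    contour_levels: list[float] = field(default_factory=list)

    def to_frame(self, grid: Grid3D) -> pd.DataFrame:
        other = [a for a in "xyz" if a != self.axis]
        idx = grid.axis_coords_mm(_AXES[other[0]])
        cols = grid.axis_coords_mm(_AXES[other[1]])
        return pd.DataFrame(self.values, index=pd.Index(idx, name=f"{other[0]}_mm"),
                            columns=pd.Index(cols, name=f"{other[1]}_mm"))


def extract_plane(field_: ScalarField, axis: str,
                  coordinate_mm: float) -> PlaneSlice:
    """Slice a field at a grid plane; errors on off-grid coordinates."""
    if axis not in _AXES:
        raise ConfigurationError(f"axis must be x, y or z, got {axis!r}")
    ax = _AXES[axis]
    g = field_.grid
    i = coordinate_mm / g.spacing_mm
    if abs(i - round(i)) > 1e-9 or not 0 <= round(i) < g.shape[ax]:
        raise ConfigurationError(
            f"{coordinate_mm} mm is not a grid plane along {axis}")
    values = np.take(field_.values, int(round(i)), axis=ax)
    levels = (TEMP_LEVELS_C if field_.quantity is Quantity.temperature_C
              else POWER_LEVELS_WM3)
    return PlaneSlice(axis, float(coordinate_mm), values, list(levels))


def plane_max(field_: ScalarField, axis: str, coordinate_mm: float) -> float:
    """Maximum node value on a plane of the field."""
    return float(extract_plane(field_, axis, coordinate_mm).values.max())


# ---------------------------------------------------------------------------
# Reproduction driver


_REFERENCE_VALUES = {
    "level1_speed_w0.5_mm_s": 320.0,
    "level1_speed_w0.01_mm_s": 6.0,
    "pbhte_opt_x38_max_C": 41.0,
    "pbhte_opt_x66_max_C": 40.8,
    "pbhte_opt_region_mean_C": 43.0,
    "cbvn_cross_x38_max_C": 39.0,
    "cbvn_cross_x66_max_C": 39.6,
    "cbvn_cross_x42_max_C": 40.9,
    "cbvn_opt_total_gamma0.6_W": 2.387,
    "cbvn_opt_total_gamma0.7_W": 2.366,
    "cbvn_over_pbhte_power_ratio_min": 2.0,
}


def _save_field(field_: ScalarField, outdir: Path, name: str) -> None:
    write_vtk(field_, outdir / f"{name}.vtk", name)
    write_csv(field_, outdir / f"{name}.csv")


def reproduce_results(outdir: str | Path,
                    blocks: tuple[str, ...] = ("speeds", "pbhte", "cross",
                                               "gamma", "perfusion"),
                    scene: Scene | None = None,
                    config: OptimizerConfig | None = None,
                    save_fields: bool = True) -> dict:
    """Run the full set of reported experiments and write a report.

    ``blocks`` selects which experiment groups run ("pbhte" alone finishes
    in a few minutes); failures of individual blocks are recorded in the
    report and do not abort the run.  Everything is deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene = scene or Scene(grid=_default_grid())
    config = config or OptimizerConfig()
    report: dict = {"computed": {}, "reference": dict(_REFERENCE_VALUES),
                    "errors": {}, "timings_s": {}}
    comp = report["computed"]
    res_p = None

    def run_block(name, fn):
        t0 = time.time()
        try:
            fn()
        except Exception as exc:              # record, continue
            report["errors"][name] = repr(exc)
        report["timings_s"][name] = round(time.time() - t0, 2)

    def block_speeds():
        for w, key in ((0.5, "level1_speed_w0.5_mm_s"),
                       (0.01, "level1_speed_w0.01_mm_s")):
            net = assign_flows(build_network(scene.grid, scene.gamma,
                                             scene.d1), w, scene.props.rho)
            comp[key] = 1e3 * vessel_speed(net.level1_inlet(), scene.props.rho)

    def block_pbhte():
        nonlocal res_p
        res_p = optimize("pbhte", scene, config)
        T = res_p.temperature
        comp["pbhte_opt_x38_max_C"] = plane_max(T, "x", 38)
        comp["pbhte_opt_x66_max_C"] = plane_max(T, "x", 66)
        mask = region_mask(scene.grid, scene.tumor)
        comp["pbhte_opt_region_mean_C"] = float(T.values[mask].mean())
        comp["pbhte_opt_total_W"] = absorbed_power(res_p.power, scene.tumor)
        comp["pbhte_opt_iterations"] = res_p.iterations
        if save_fields:
            _save_field(res_p.power, outdir, "pbhte_opt_power")
            _save_field(T, outdir, "pbhte_opt_temperature")
            for x in DEFAULT_VIEW_PLANES_MM:
                extract_plane(T, "x", x).to_frame(scene.grid).to_csv(
                    outdir / f"pbhte_T_x{int(x)}mm.csv")

    def block_cross():
        if res_p is None:
            raise RuntimeError("pbhte block must run first")
        net = scene.get_network()
        system = CBVNSystem(scene.grid, scene.props, net, scene.solver)
        sol = system.solve(res_p.power)
        T = sol.tissue
        comp["cbvn_cross_x38_max_C"] = plane_max(T, "x", 38)
        comp["cbvn_cross_x66_max_C"] = plane_max(T, "x", 66)
        comp["cbvn_cross_x42_max_C"] = plane_max(T, "x", 42)
        comp["cbvn_cross_energy_imbalance"] = energy_balance(
            sol, res_p.power, net, scene.props, scene.solver, system=system)
        art, ven = tumor_midplane_paths(net)
        prof_a = blood_path_profile(sol, art, net)
        prof_v = blood_path_profile(sol, ven, net)
        if save_fields:
            _save_field(T, outdir, "cbvn_cross_temperature")
            prof_a.to_csv(outdir / "cross_midplane_arterial.csv", index=False)
            prof_v.to_csv(outdir / "cross_midplane_venous.csv", index=False)

    def block_gamma():
        table = gamma_sweep(scene, [0.6, 0.7, 0.8, 0.9], config)
        table.to_csv(outdir / "gamma_sweep.csv", index=False)
        for _, row in table.iterrows():
            comp[f"cbvn_opt_total_gamma{row.gamma:.1f}_W"] = row.total_power_W
        p6 = table.loc[table.gamma == 0.6, "total_power_W"].iloc[0]
        p7 = table.loc[table.gamma == 0.7, "total_power_W"].iloc[0]
        comp["gamma_0.6_to_0.7_rel_decrease_pct"] = 100 * (p6 - p7) / p6
        if "pbhte_opt_total_W" in comp:
            comp["cbvn_over_pbhte_power_ratio"] = (
                p7 / comp["pbhte_opt_total_W"])

    def block_perfusion():
        table, results = perfusion_sweep(scene, [0.5, 0.1, 0.05, 0.01], config)
        table.to_csv(outdir / "perfusion_sweep.csv", index=False)
        comp["perfusion_T_std_monotone"] = bool(
            table.sort_values("w_b", ascending=False)
            .T_std_C.is_monotonic_decreasing)
        for w, res in results.items():
            comp[f"cbvn_opt_total_w{w}_W"] = absorbed_power(
                res.power, scene.tumor)

    dispatch = {"speeds": block_speeds, "pbhte": block_pbhte,
                "cross": block_cross, "gamma": block_gamma,
                "perfusion": block_perfusion}
    for name in blocks:
        run_block(name, dispatch[name])

    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    _write_markdown(report, outdir / "report.md")
    return report


def _default_grid() -> Grid3D:
    from .core import make_grid
    return make_grid()


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Reproduction report", "",
             "| quantity | computed | reference |", "|---|---|---|"]
    ref = report["reference"]
    for key, val in report["computed"].items():
        r = ref.get(key, "")
        v = f"{val:.4g}" if isinstance(val, float) else str(val)
        lines.append(f"| {key} | {v} | {r} |")
    if report["errors"]:
        lines += ["", "## Errors", ""]
        lines += [f"- {k}: {v}" for k, v in report["errors"].items()]
    lines += ["", "## Timings (s)", ""]
    lines += [f"- {k}: {v}" for k, v in report["timings_s"].items()]
    path.write_text("\n".join(lines) + "\n")
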
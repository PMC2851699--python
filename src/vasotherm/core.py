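"""Grids, regions, scalar fields and tissue properties shared by all solvers.

The simulation domain is a parallelepiped control volume (default
82 x 80 x 80 mm) discretized on a uniform node-centered Cartesian lattice.
Nodes sit on the boundary faces, so Dirichlet temperature nodes are ordinary
grid nodes.  All public interfaces use millimetres for coordinates; physical
quantities are SI (W, m, kg, s) with temperatures in degrees Celsius.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Grid3D",
    "TissueProperties",
    "Quantity",
    "ScalarField",
    "BoxRegion",
    "DEFAULT_TUMOR_BOX",
    "ConfigurationError",
    "make_grid",
    "region_mask",
    "absorbed_power",
    "node_volume_weights",
    "integrate_power",
    "write_vtk",
    "write_csv",
    "read_csv_field",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent grid / region / network configuration."""


@dataclass(frozen=True)
class Grid3D:
    """Uniform node-centered Cartesian grid over the control volume.

    Node ``(i, j, k)`` lies at ``(i*h, j*h, k*h)`` mm with ``h`` the spacing;
    ``(0, 0, 0)`` is the corner at which the level-1 artery enters the volume
    at mm-coordinates ``(0, W/2, H/2)``.
    """

    extent_mm: tuple[float, float, float]
    spacing_mm: float

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ConfigurationError("grid spacing must be positive")
        for axis, ext in zip("xyz", self.extent_mm):
            n = ext / self.spacing_mm
            if ext <= 0 or abs(n - round(n)) > 1e-9:
                raise ConfigurationError(
                    f"extent {ext} mm along {axis} is not divisible by "
                    f"spacing {self.spacing_mm} mm"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(e / self.spacing_mm)) + 1 for e in self.extent_mm
        )

    @property
    def spacing_m(self) -> float:
        return self.spacing_mm * 1e-3

    def node_to_mm(self, ijk: Sequence[int]) -> tuple[float, float, float]:
        return tuple(float(i) * self.spacing_mm for i in ijk)

    def mm_to_node(self, xyz_mm: Sequence[float]) -> tuple[int, int, int]:
        """Map mm coordinates to a node index; the point must be on a node."""
        idx = []
        for axis, (x, n) in enumerate(zip(xyz_mm, self.shape)):
            i = x / self.spacing_mm
            if abs(i - round(i)) > 1e-9:
                raise ConfigurationError(
                    f"coordinate {x} mm is not on a grid node (axis {axis})"
                )
            i = int(round(i))
            if not 0 <= i < n:
                raise ConfigurationError(
                    f"coordinate {x} mm lies outside the grid (axis {axis})"
                )
            idx.append(i)
        return tuple(idx)

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        return np.arange(self.shape[axis]) * self.spacing_mm


@dataclass(frozen=True)
class TissueProperties:
    """Thermal properties of tissue and blood.

    Defaults: conductivity 0.5 W/m/C for both tissue and blood, blood
    specific heat 4000 J/kg/C, density 1000 kg/m^3, Nusselt number 4 for all
    vessel levels, and a 37 C core/boundary temperature.
    """

    k_t: float = 0.5          # tissue conductivity, W m^-1 C^-1
    k_b: float = 0.5          # blood conductivity, W m^-1 C^-1
    c_b: float = 4000.0       # blood specific heat, J kg^-1 C^-1
    rho: float = 1000.0       # density, kg m^-3
    Nu: float = 4.0           # Nusselt number, dimensionless
    T_body: float = 37.0      # boundary / arterial supply temperature, C

    def __post_init__(self) -> None:
        for name in ("k_t", "k_b", "c_b", "rho", "Nu"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")


class Quantity(str, Enum):
    temperature_C = "temperature_C"
    power_Wm3 = "power_Wm3"


@dataclass
class ScalarField:
    """A node-indexed scalar quantity (temperature or power density)."""

    grid: Grid3D
    values: np.ndarray
    quantity: Quantity = Quantity.temperature_C

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError(
                f"field shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("field values must be finite")
        if self.quantity is Quantity.power_Wm3 and np.any(self.values < 0):
            raise ConfigurationError("power density must be non-negative")

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(), self.quantity)


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box with corners on grid nodes, in mm coordinates."""

    lo_mm: tuple[float, float, float]
    hi_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.lo_mm, self.hi_mm):
            if lo > hi:
                raise ConfigurationError("box requires lo <= hi on every axis")

    def volume_m3(self) -> float:
        return float(
            np.prod([(h - l) * 1e-3 for l, h in zip(self.lo_mm, self.hi_mm)])
        )

    def contains_mm(self, xyz: Sequence[float]) -> bool:
        return all(
            l - 1e-9 <= x <= h + 1e-9
            for x, l, h in zip(xyz, self.lo_mm, self.hi_mm)
        )


#: Default treated (tumor) region: the 20-mm cube on the back half of the
#: control volume, with the level-1 artery running along one of its edges.
DEFAULT_TUMOR_BOX = BoxRegion((42.0, 40.0, 40.0), (62.0, 60.0, 60.0))


def make_grid(
    extent_mm: Sequence[float] = (82.0, 80.0, 80.0), spacing_mm: float = 2.0
) -> Grid3D:
    """Create the uniform grid; errors if spacing does not divide an extent."""
    return Grid3D(tuple(float(e) for e in extent_mm), float(spacing_mm))


def box_slices(grid: Grid3D, box: BoxRegion) -> tuple[slice, slice, slice]:
    lo = grid.mm_to_node(box.lo_mm)
    hi = grid.mm_to_node(box.hi_mm)
    return tuple(slice(l, h + 1) for l, h in zip(lo, hi))


def region_mask(grid: Grid3D, box: BoxRegion) -> np.ndarray:
    """Boolean node mask of all nodes inside ``box`` (inclusive bounds)."""
    mask = np.zeros(grid.shape, dtype=bool)
    mask[box_slices(grid, box)] = True
    return mask


def node_volume_weights(grid: Grid3D, box: BoxRegion | None = None) -> np.ndarray:
    """Trapezoidal control-volume share of each node, in m^3.

    Interior nodes of the (sub)box carry a full cell volume h^3; nodes on
    box faces/edges/corners carry 1/2, 1/4, 1/8 of it.  Summed over a box the
    weights equal its geometric volume exactly; weights are zero outside it.
    """
    if box is None:
        box = BoxRegion((0.0, 0.0, 0.0), grid.extent_mm)
    h = grid.spacing_m
    w = np.zeros(grid.shape, dtype=float)
    sl = box_slices(grid, box)
    axis_w = []
    for s, n in zip(sl, grid.shape):
        a = np.zeros(n)
        a[s] = 1.0
        if s.stop - s.start > 1:
            a[s.start] = 0.5
            a[s.stop - 1] = 0.5
        else:  # degenerate (zero-thickness) axis
            a[s.start] = 0.0
        axis_w.append(a)
    w = axis_w[0][:, None, None] * axis_w[1][None, :, None] * axis_w[2][None, None, :]
    return w * h**3


def absorbed_power(q: ScalarField, region: "BoxRegion | np.ndarray") -> float:
    """Discrete power deposition in a region: sum of q times the full cell
    volume h^3 of every region node.

    This is the power the finite-difference model actually absorbs (each
    node equation deposits q over its full cell) and the quantity reported
    as the total absorbed power of an optimized treatment; it differs from
    :func:`integrate_power`, whose trapezoidal weights give the geometric
    volume integral of the node field.
    """
    if q.quantity is not Quantity.power_Wm3:
        raise ConfigurationError("absorbed_power expects a power field")
    mask = region if isinstance(region, np.ndarray) else region_mask(q.grid, region)
    return float(q.values[mask].sum()) * q.grid.spacing_m**3


def integrate_power(q: ScalarField, region: BoxRegion | Iterable[BoxRegion]) -> float:
    """Total power (W) deposited in a region: sum of q * node volume share.

    ``region`` may be a single box or an iterable of disjoint boxes (summed).
    The trapezoidal weights make the integral exact for fields uniform over
    the box.
    """
    if q.quantity is not Quantity.power_Wm3:
        raise ConfigurationError("integrate_power expects a power field")
    boxes = [region] if isinstance(region, BoxRegion) else list(region)
    if not boxes:
        raise ConfigurationError("empty region")
    total = 0.0
    for box in boxes:
        w = node_volume_weights(q.grid, box)
        if not np.any(w > 0):
            raise ConfigurationError("region contains no volume")
        total += float(np.sum(q.values * w))
    return total


# ---------------------------------------------------------------------------
# Field export / import


def write_vtk(field: ScalarField, path: str | Path, name: str | None = None) -> None:
    """Write a legacy-ASCII VTK STRUCTURED_POINTS file of the field."""
    g = field.grid
    nx, ny, nz = g.shape
    name = name or field.quantity.value
    lines = [
        "# vtk DataFile Version 3.0",
        "vasotherm scalar field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {g.spacing_mm} {g.spacing_mm} {g.spacing_mm}",
        f"POINT_DATA {nx * ny * nz}",
        f"SCALARS {name} double 1",
        "LOOKUP_TABLE default",
    ]
    # VTK expects x fastest
    flat = field.values.transpose(2, 1, 0).ravel()
    body = "\n".join(" ".join(f"{v:.9g}" for v in flat[i : i + 6])
                     for i in range(0, flat.size, 6))
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def write_csv(field: ScalarField, path: str | Path) -> None:
    """Flat CSV export: i,j,k,x_mm,y_mm,z_mm,value (one row per node)."""
    g = field.grid
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j", "k", "x_mm", "y_mm", "z_mm", "value"])
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                for k in range(g.shape[2]):
                    x, y, z = g.node_to_mm((i, j, k))
                    w.writerow([i, j, k, x, y, z,
                                repr(float(field.values[i, j, k]))])


def read_csv_field(
    path: str | Path, grid: Grid3D, quantity: Quantity = Quantity.temperature_C
) -> ScalarField:
    """Read a field written by :func:`write_csv` back onto ``grid``."""
    values = np.full(grid.shape, np.nan)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            values[int(row["i"]), int(row["j"]), int(row["k"])] = float(row["value"])
    if np.any(np.isnan(values)):
        raise ConfigurationError("CSV does not cover every grid node")
    return ScalarField(grid, values, quantity)
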
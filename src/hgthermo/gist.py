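"""Energy-based GIST maps and spatial heat-capacity decomposition.

Grid inhomogeneous solvation theory attributes solvation quantities to
voxels of a 3-D grid around a solute.  Here each water is assigned to
the voxel containing its oxygen and carries two per-water energies:
E_sw (interaction with the solute) and E_ww (its half-share of
water-water interactions).  Waters falling outside the grid accumulate
in a far-field bucket so ensemble totals are conserved exactly.

Differencing the *bound-minus-free* solvation-energy map between two
temperatures gives a spatial map of the solvent part of the binding
heat-capacity change; integrating the map over the cavity and portal
regions localizes where the heat-capacity signal comes from.  The maps
are enthalpic only (no orientational-entropy estimators).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from .regions import CylinderRegion, PortalSlabs

__all__ = [
    "VoxelGrid",
    "GistMap",
    "CpMap",
    "accumulate",
    "normalize",
    "difference_map",
    "heat_capacity_map",
    "integrate_region",
    "write_dx",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular orthogonal grid: origin (A), cubic spacing (A), voxel counts."""

    origin: tuple[float, float, float]
    spacing: float = 0.5
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must all be >= 1")

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_indices(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Flat voxel index per point and a mask of points inside the grid."""
        rel = (np.atleast_2d(points) - np.asarray(self.origin)) / self.spacing
        ijk = np.floor(rel).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.asarray(self.dims)), axis=1)
        flat = np.ravel_multi_index(
            tuple(ijk[inside].T), self.dims
        ) if inside.any() else np.empty(0, dtype=int)
        return flat, inside

    def centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-center coordinates."""
        axes = [
            self.origin[k] + self.spacing * (np.arange(self.dims[k]) + 0.5)
            for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    @classmethod
    def covering(cls, lo, hi, spacing: float = 0.5) -> "VoxelGrid":
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        dims = tuple(max(1, int(np.ceil((b - a) / spacing))) for a, b in zip(lo, hi))
        return cls(origin=tuple(lo), spacing=spacing, dims=dims)


@dataclass
class GistMap:
    """Accumulated per-voxel water occupancy and energies at one temperature.

    ``occupancy`` counts water-oxygen visits; ``e_sw`` / ``e_ww`` are
    summed per-water energies (kcal/mol).  ``g`` (density ratio) is
    populated by :func:`normalize`.
    """

    grid: VoxelGrid
    T: float
    n_frames: int = 0
    occupancy: np.ndarray = field(default=None)  # type: ignore[assignment]
    e_sw: np.ndarray = field(default=None)  # type: ignore[assignment]
    e_ww: np.ndarray = field(default=None)  # type: ignore[assignment]
    far_occupancy: float = 0.0
    far_e_sw: float = 0.0
    far_e_ww: float = 0.0
    g: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.grid.n_voxels
        if self.occupancy is None:
            self.occupancy = np.zeros(n)
        if self.e_sw is None:
            self.e_sw = np.zeros(n)
        if self.e_ww is None:
            self.e_ww = np.zeros(n)
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    def solvation_energy(self) -> np.ndarray:
        """Per-voxel mean solvation energy per frame, E_sw + E_ww (kcal/mol)."""
        if self.n_frames == 0:
            return np.zeros_like(self.e_sw)
        return (self.e_sw + self.e_ww) / self.n_frames

    def total_solvation_energy(self, include_far_field: bool = True) -> float:
        tot = float(self.e_sw.sum() + self.e_ww.sum())
        if include_far_field:
            tot += self.far_e_sw + self.far_e_ww
        return tot / max(self.n_frames, 1)


@dataclass
class CpMap:
    """Voxelized heat-capacity change, cal/(mol K per A^3) density."""

    grid: VoxelGrid
    dcp_density: np.ndarray
    T1: float
    T2: float

    def region_integrals(
        self, cavity: CylinderRegion, portal: PortalSlabs
    ) -> dict[str, float]:
        """Integrals over cavity, portal and the whole grid, cal/(mol K)."""
        total = integrate_region(self, "all")
        cav = integrate_region(self, cavity)
        por = integrate_region(self, portal)
        return {
            "dCp_cavity": cav,
            "dCp_portal": por,
            "dCp_total": total,
            "dCp_remainder": total - cav - por,
        }


def accumulate(
    frames: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    grid: VoxelGrid,
    T: float,
) -> GistMap:
    """Bin per-water positions and energies into a GIST map.

    ``frames`` is a sequence of (oxygen positions (M,3), E_sw (M,),
    E_ww (M,)) triples; M may vary per frame.  Each water's energies
    are attributed wholly to the voxel containing its oxygen; waters
    outside the grid go to the far-field bucket, so grand totals are
    conserved.
    """
    m = GistMap(grid=grid, T=T)
    for pos, e_sw, e_ww in frames:
        pos = np.atleast_2d(np.asarray(pos, float))
        e_sw = np.asarray(e_sw, float)
        e_ww = np.asarray(e_ww, float)
        if pos.shape[0] != e_sw.size or pos.shape[0] != e_ww.size:
            raise ValueError("positions and per-water energies differ in length")
        flat, inside = grid.voxel_indices(pos)
        np.add.at(m.occupancy, flat, 1.0)
        np.add.at(m.e_sw, flat, e_sw[inside])
        np.add.at(m.e_ww, flat, e_ww[inside])
        m.far_occupancy += float(np.count_nonzero(~inside))
        m.far_e_sw += float(e_sw[~inside].sum())
        m.far_e_ww += float(e_ww[~inside].sum())
        m.n_frames += 1
    return m


def normalize(m: GistMap, rho0: float, bulk_e_ww_per_water: float = 0.0) -> GistMap:
    """Reference a map to bulk: density ratio g and bulk-subtracted E_ww.

    g = observed number density / rho0.  The water-water energy of each
    observed water is re-referenced by subtracting the bulk per-water
    value, so bulk-like voxels carry ~zero excess energy.  Empty voxels
    have g = 0 and zero energy contribution.
    """
    if rho0 <= 0:
        raise ValueError("bulk density must be positive")
    out = GistMap(
        grid=m.grid,
        T=m.T,
        n_frames=m.n_frames,
        occupancy=m.occupancy.copy(),
        e_sw=m.e_sw.copy(),
        e_ww=m.e_ww - m.occupancy * bulk_e_ww_per_water,
        far_occupancy=m.far_occupancy,
        far_e_sw=m.far_e_sw,
        far_e_ww=m.far_e_ww - m.far_occupancy * bulk_e_ww_per_water,
    )
    denom = max(m.n_frames, 1) * m.grid.voxel_volume * rho0
    out.g = m.occupancy / denom
    return out


def difference_map(bound: GistMap, free: GistMap) -> GistMap:
    """Bound-minus-free map (same grid and temperature): the on-binding change."""
    if bound.grid != free.grid:
        raise ValueError("grids do not match")
    if bound.T != free.T:
        raise ValueError("temperatures do not match")
    if bound.n_frames != free.n_frames:
        # normalize both to per-frame before differencing
        scale_b = 1.0 / max(bound.n_frames, 1)
        scale_f = 1.0 / max(free.n_frames, 1)
    else:
        scale_b = scale_f = 1.0 / max(bound.n_frames, 1)
    return GistMap(
        grid=bound.grid,
        T=bound.T,
        n_frames=1,
        occupancy=bound.occupancy * scale_b - free.occupancy * scale_f,
        e_sw=bound.e_sw * scale_b - free.e_sw * scale_f,
        e_ww=bound.e_ww * scale_b - free.e_ww * scale_f,
        far_occupancy=bound.far_occupancy * scale_b - free.far_occupancy * scale_f,
        far_e_sw=bound.far_e_sw * scale_b - free.far_e_sw * scale_f,
        far_e_ww=bound.far_e_ww * scale_b - free.far_e_ww * scale_f,
    )


def heat_capacity_map(map_T1: GistMap, map_T2: GistMap) -> CpMap:
    """Finite-difference heat-capacity map from two difference maps.

    Both inputs must be bound-minus-free solvation-energy maps of the
    same complex on the same grid; the per-voxel heat-capacity density
    is (dE_solv(T2) - dE_solv(T1)) / (T2 - T1) per voxel volume,
    converted to cal/(mol K).
    """
    if map_T1.grid != map_T2.grid:
        raise ValueError("grids do not match")
    if map_T2.T <= map_T1.T:
        raise ValueError("need T2 > T1")
    dT = map_T2.T - map_T1.T
    dcp_per_voxel = (map_T2.solvation_energy() - map_T1.solvation_energy()) / dT * 1000.0
    return CpMap(
        grid=map_T1.grid,
        dcp_density=dcp_per_voxel / map_T1.grid.voxel_volume,
        T1=map_T1.T,
        T2=map_T2.T,
    )


def integrate_region(
    m: CpMap | GistMap,
    region: CylinderRegion | PortalSlabs | str = "all",
) -> float:
    """Integrate a map over a region (sum of voxel values at centers inside).

    For a :class:`CpMap` the integrand is the heat-capacity density
    (result in cal/(mol K)); for a :class:`GistMap` it is the
    per-frame solvation energy (kcal/mol).  ``region="all"`` integrates
    the whole grid.
    """
    if isinstance(m, CpMap):
        values = m.dcp_density * m.grid.voxel_volume
    else:
        values = m.solvation_energy()
    if isinstance(region, str):
        if region != "all":
            raise ValueError(f"unknown region {region!r}")
        return float(values.sum())
    mask = region.contains(m.grid.centers())
    if not mask.any():
        warnings.warn("region contains no voxel centers; partial/empty integral")
    return float(values[mask].sum())


def write_dx(path, grid: VoxelGrid, values: np.ndarray, comment: str = "hgthermo map") -> None:
    """Write a scalar field as an OpenDX regular grid (text format)."""
    v = np.asarray(values, float).reshape(grid.dims)
    nx, ny, nz = grid.dims
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {v.size} data follows\n"
        )
        flat = v.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{x:.6e}" for x in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
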
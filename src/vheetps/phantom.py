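"""Synthetic voxel phantoms with structure sets.

Four recipes: a uniform water box, a pelvis-like phantom (PTV with abutting
rectum/bladder tubes) and two thorax-like phantoms with low-density lungs and
either a midline PTV overlapping the heart projection or a lateral PTV
against the chest wall.  Geometry is fully deterministic given the spec.

Coordinate convention: x = right->left, y = anterior->posterior,
z = inferior->superior; origin at the grid corner; voxel (i,j,k) has its
centre at origin + (i+0.5, j+0.5, k+0.5) * spacing; masks are voxel-centre
membership.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, Tuple, Union

import numpy as np

from .nrrdio import NrrdError, read_nrrd, write_nrrd

__all__ = [
    "ImageGrid",
    "Structure",
    "StructureSet",
    "PhantomSpec",
    "make_phantom",
    "structure_volume",
    "save_phantom",
    "load_phantom",
]

RECIPES = ("water_box", "pelvis", "thorax_midline", "thorax_chestwall")

#: Median PTV volumes (cm^3) of the two thorax sub-groups used as defaults.
MIDLINE_PTV_CM3 = 206.7
CHESTWALL_PTV_CM3 = 271.5


@dataclass(frozen=True)
class ImageGrid:
    """Voxel grid of relative-to-water density."""

    shape: Tuple[int, int, int]
    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float]
    density: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.density.shape) != tuple(self.shape):
            raise ValueError("density array shape does not match grid shape")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.density)) or np.any(self.density < 0):
            raise ValueError("density must be finite and non-negative")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def voxel_centers(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D centre coordinate arrays per axis (mm)."""
        return tuple(
            self.origin_mm[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing_mm[a]
            for a in range(3)
        )

    def center_mm(self) -> np.ndarray:
        return np.array(
            [self.origin_mm[a] + self.shape[a] * self.spacing_mm[a] / 2.0 for a in range(3)]
        )


@dataclass(frozen=True)
class Structure:
    name: str
    mask: np.ndarray
    role: str  # target | oar | external

    def __post_init__(self) -> None:
        if self.role not in ("target", "oar", "external"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if self.role == "target" and not self.mask.any():
            raise ValueError(f"target structure {self.name!r} is empty")


@dataclass(frozen=True)
class StructureSet:
    grid: ImageGrid
    structures: Dict[str, Structure]

    def __post_init__(self) -> None:
        ext = None
        for name, s in self.structures.items():
            if name != s.name:
                raise ValueError("structure dict key must equal structure name")
            if tuple(s.mask.shape) != tuple(self.grid.shape):
                raise ValueError(f"mask of {name!r} is not aligned to the grid")
            if s.role == "external":
                ext = s
        if ext is not None:
            for s in self.structures.values():
                if s.role == "target" and np.any(s.mask & ~ext.mask):
                    raise ValueError(f"target {s.name!r} extends outside the body")

    def __getitem__(self, name: str) -> Structure:
        return self.structures[name]

    @property
    def target(self) -> Structure:
        targets = [s for s in self.structures.values() if s.role == "target"]
        if len(targets) != 1:
            raise ValueError(f"expected exactly one target, found {len(targets)}")
        return targets[0]

    @property
    def external(self) -> Structure:
        for s in self.structures.values():
            if s.role == "external":
                return s
        raise KeyError("no external structure")


@dataclass(frozen=True)
class PhantomSpec:
    recipe: str
    size_mm: Tuple[float, float, float] | None = None
    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_density: float = 0.3
    ptv_volume_cm3: float | None = None
    params: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ValueError(f"unknown recipe {self.recipe!r}; choose from {RECIPES}")


def structure_volume(s: Structure, grid: ImageGrid) -> float:
    """Structure volume in cm^3 (voxel count times voxel volume)."""
    if tuple(s.mask.shape) != tuple(grid.shape):
        raise ValueError("mask is not aligned to the grid")
    return float(s.mask.sum()) * grid.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# geometry primitives (voxel-centre membership)
# ---------------------------------------------------------------------------


def _grids(shape, spacing, origin):
    ax = [origin[a] + (np.arange(shape[a]) + 0.5) * spacing[a] for a in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid(xx, yy, zz, center, half_axes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = half_axes
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0


def _zcylinder(xx, yy, zz, center_xy, radii_xy, z_range) -> np.ndarray:
    cx, cy = center_xy
    rx, ry = radii_xy if isinstance(radii_xy, tuple) else (radii_xy, radii_xy)
    lateral = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    return lateral & (zz >= z_range[0]) & (zz <= z_range[1])


def _cuboid(xx, yy, zz, center, half_sizes) -> np.ndarray:
    m = np.ones(xx.shape, dtype=bool)
    for coord, c, h in zip((xx, yy, zz), center, half_sizes):
        m &= np.abs(coord - c) <= h
    return m


def _calibrated_ellipsoid(xx, yy, zz, center, half_axes, target_cm3, voxel_mm3):
    """Scale an ellipsoid isotropically until its voxelised volume matches
    target_cm3 to <=0.5% (bisection on the scale factor)."""
    target_vox = target_cm3 * 1000.0 / voxel_mm3
    lo, hi = 0.7, 1.4
    best = None
    for _ in range(60):
        s = 0.5 * (lo + hi)
        m = _ellipsoid(xx, yy, zz, center, tuple(a * s for a in half_axes))
        n = int(m.sum())
        if best is None or abs(n - target_vox) < abs(best[1] - target_vox):
            best = (m, n)
        if abs(n - target_vox) / target_vox <= 0.005:
            return m
        if n < target_vox:
            lo = s
        else:
            hi = s
    return best[0]


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------


def _make_water_box(spec: PhantomSpec):
    size = spec.size_mm or (200.0, 200.0, 200.0)
    spacing = spec.spacing_mm
    shape = tuple(int(round(size[a] / spacing[a])) for a in range(3))
    density = np.ones(shape, dtype=np.float64)
    grid = ImageGrid(shape, spacing, (0.0, 0.0, 0.0), density)
    xx, yy, zz = _grids(shape, spacing, (0.0, 0.0, 0.0))
    c = grid.center_mm()
    half = tuple(spec.params.get("ptv_half_size_mm", (30.0, 30.0, 30.0)))
    ptv = _cuboid(xx, yy, zz, c, half)
    body = np.ones(shape, dtype=bool)
    return grid, {
        "body": Structure("body", body, "external"),
        "ptv": Structure("ptv", ptv, "target"),
    }


def _make_pelvis(spec: PhantomSpec):
    size = spec.size_mm or (320.0, 220.0, 160.0)
    spacing = spec.spacing_mm
    shape = tuple(int(round(size[a] / spacing[a])) for a in range(3))
    xx, yy, zz = _grids(shape, spacing, (0.0, 0.0, 0.0))
    cx, cy, cz = (size[0] / 2, size[1] / 2, size[2] / 2)
    p = spec.params
    body_ax = p.get("body_half_axes_mm", (min(150.0, cx - 5), min(100.0, cy - 5)))
    body = _zcylinder(xx, yy, zz, (cx, cy), tuple(body_ax), (0.0, size[2]))

    density = np.zeros(shape, dtype=np.float64)
    density[body] = 1.0
    grid = ImageGrid(shape, spacing, (0.0, 0.0, 0.0), density)

    vol = spec.ptv_volume_cm3 or p.get("ptv_volume_cm3", 105.0)
    ptv_ax = p.get("ptv_half_axes_mm", (28.0, 28.0, 32.0))
    ptv = _calibrated_ellipsoid(
        xx, yy, zz, (cx, cy, cz), ptv_ax, vol, grid.voxel_volume_mm3
    )
    # abutting tubes: rectum posterior (+y), bladder anterior (-y)
    ptv_b = float(np.max(np.abs(yy[ptv] - cy))) if ptv.any() else ptv_ax[1]
    rect_r = p.get("rectum_radius_mm", 15.0)
    blad_r = p.get("bladder_radius_mm", 25.0)
    zr = (cz - 60.0, cz + 60.0)
    rectum = _zcylinder(xx, yy, zz, (cx, cy + ptv_b + rect_r + 2.0), rect_r, zr)
    bladder = _zcylinder(xx, yy, zz, (cx, cy - ptv_b - blad_r - 2.0), blad_r, zr)
    rectum &= body
    bladder &= body

    if np.any(ptv & ~body):
        raise ValueError("pelvis PTV extends outside the body")
    return grid, {
        "body": Structure("body", body, "external"),
        "ptv": Structure("ptv", ptv, "target"),
        "rectum": Structure("rectum", rectum, "oar"),
        "bladder": Structure("bladder", bladder, "oar"),
    }


def _make_thorax(spec: PhantomSpec, midline: bool):
    size = spec.size_mm or (340.0, 210.0, 160.0)
    spacing = spec.spacing_mm
    shape = tuple(int(round(size[a] / spacing[a])) for a in range(3))
    xx, yy, zz = _grids(shape, spacing, (0.0, 0.0, 0.0))
    cx, cy, cz = (size[0] / 2, size[1] / 2, size[2] / 2)
    p = spec.params
    body_ax = p.get("body_half_axes_mm", (min(160.0, cx - 5), min(95.0, cy - 5)))
    body = _zcylinder(xx, yy, zz, (cx, cy), tuple(body_ax), (0.0, size[2]))

    lung_ax = p.get("lung_half_axes_mm", (0.34 * body_ax[0], 0.66 * body_ax[1]))
    lung_dx = p.get("lung_offset_mm", 0.52 * body_ax[0])
    zcap = p.get("lung_z_cap_mm", 10.0)
    zr = (zcap, size[2] - zcap)
    lung_l = _zcylinder(xx, yy, zz, (cx + lung_dx, cy), tuple(lung_ax), zr) & body
    lung_r = _zcylinder(xx, yy, zz, (cx - lung_dx, cy), tuple(lung_ax), zr) & body

    heart = _zcylinder(xx, yy, zz, (cx + 15.0, cy - 18.0), 32.0, (cz - 45.0, cz + 45.0)) & body
    oesophagus = _zcylinder(xx, yy, zz, (cx, cy + 18.0), 8.0, (0.0, size[2])) & body
    cord = _zcylinder(xx, yy, zz, (cx, cy + 0.62 * body_ax[1]), 6.0, (0.0, size[2])) & body

    voxel_mm3 = float(np.prod(spacing))
    if midline:
        vol = spec.ptv_volume_cm3 or MIDLINE_PTV_CM3
        center = (cx + 12.0, cy - 6.0, cz)
        ptv_ax = p.get("ptv_half_axes_mm", (33.0, 33.0, 43.0))
    else:
        vol = spec.ptv_volume_cm3 or CHESTWALL_PTV_CM3
        center = (cx + lung_dx + 0.35 * lung_ax[0], cy, cz)
        ptv_ax = p.get("ptv_half_axes_mm", (36.0, 36.0, 46.0))
    ptv = _calibrated_ellipsoid(xx, yy, zz, center, ptv_ax, vol, voxel_mm3)
    if np.any(ptv & ~body):
        raise ValueError("thorax PTV extends outside the body")

    # PTV is unit-density tumour; lungs exclude it
    lung_l &= ~ptv
    lung_r &= ~ptv
    heart &= ~(lung_l | lung_r)
    oesophagus &= ~(lung_l | lung_r)
    cord &= ~(lung_l | lung_r)

    density = np.zeros(shape, dtype=np.float64)
    density[body] = 1.0
    density[lung_l | lung_r] = spec.lung_density
    grid = ImageGrid(shape, spacing, (0.0, 0.0, 0.0), density)

    return grid, {
        "body": Structure("body", body, "external"),
        "ptv": Structure("ptv", ptv, "target"),
        "lung": Structure("lung", lung_l | lung_r, "oar"),
        "heart": Structure("heart", heart, "oar"),
        "oesophagus": Structure("oesophagus", oesophagus, "oar"),
        "spinal_cord": Structure("spinal_cord", cord, "oar"),
    }


def make_phantom(spec: PhantomSpec) -> StructureSet:
    """Build the structure set for a phantom spec (deterministic)."""
    if spec.recipe == "water_box":
        grid, structures = _make_water_box(spec)
    elif spec.recipe == "pelvis":
        grid, structures = _make_pelvis(spec)
    elif spec.recipe == "thorax_midline":
        grid, structures = _make_thorax(spec, midline=True)
    else:
        grid, structures = _make_thorax(spec, midline=False)
    return StructureSet(grid=grid, structures=structures)


# ---------------------------------------------------------------------------
# persistence: density.nrrd + mask_<name>.nrrd + phantom.json manifest
# ---------------------------------------------------------------------------


def save_phantom(structure_set: StructureSet, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = structure_set.grid
    write_nrrd(directory / "density.nrrd", grid.density, grid.spacing_mm, grid.origin_mm)
    manifest = {"structures": {}}
    for name, s in structure_set.structures.items():
        write_nrrd(
            directory / f"mask_{name}.nrrd",
            s.mask.astype(np.uint8),
            grid.spacing_mm,
            grid.origin_mm,
        )
        manifest["structures"][name] = {"role": s.role}
    (directory / "phantom.json").write_text(json.dumps(manifest, indent=2))


def load_phantom(directory: Union[str, Path]) -> StructureSet:
    directory = Path(directory)
    manifest_path = directory / "phantom.json"
    if not manifest_path.exists():
        raise NrrdError(f"missing manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    density, spacing, origin = read_nrrd(directory / "density.nrrd")
    grid = ImageGrid(tuple(density.shape), tuple(spacing), tuple(origin), density.astype(np.float64))
    structures = {}
    for name, info in manifest["structures"].items():
        mask, mspacing, _ = read_nrrd(directory / f"mask_{name}.nrrd")
        if tuple(mask.shape) != tuple(grid.shape):
            raise NrrdError(
                f"mask_{name}.nrrd shape {mask.shape} does not match density shape {grid.shape}"
            )
        structures[name] = Structure(name, mask.astype(bool), info["role"])
    return StructureSet(grid=grid, structures=structures)
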
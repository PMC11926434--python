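"""Beam geometry: gantry arrangements, BEV projection, spot lattices, WEPL.

Gantry convention: parallel-beam (infinite SAD) pencil geometry.  At 0 deg the
beam enters anteriorly and travels +y; angles increase toward patient-left
entry, so the beam direction is d(g) = (-sin g, cos g, 0).  The beam's-eye-view
(BEV) basis is u = (cos g, sin g, 0), v = (0, 0, 1); both are orthonormal to d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from numba import njit

from .phantom import ImageGrid, Structure

__all__ = [
    "FieldGeometry",
    "BEVFootprint",
    "SpotGrid",
    "arrange_beams",
    "single_beam",
    "parallel_opposed",
    "make_field",
    "radiological_depth",
    "project_to_bev",
    "place_spots",
]


# ---------------------------------------------------------------------------
# beam arrangements
# ---------------------------------------------------------------------------


def arrange_beams(n: int, span_deg: float, center_deg: float = 0.0) -> List[float]:
    """Equidistant gantry angles (degrees, mod 360) centred on `center_deg`.

    For a partial arc (span < 360) the endpoints are included and the pitch is
    span/(n-1); a full 360 deg arc uses pitch 360/n with no duplicate endpoint.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < span_deg <= 360):
        raise ValueError("span must be in (0, 360]")
    if n == 1:
        return [center_deg % 360.0]
    if span_deg == 360.0:
        pitch = 360.0 / n
        offsets = [i * pitch for i in range(n)]
        start = center_deg - (n - 1) * pitch / 2.0
    else:
        pitch = span_deg / (n - 1)
        offsets = [i * pitch for i in range(n)]
        start = center_deg - span_deg / 2.0
    return [(start + o) % 360.0 for o in offsets]


def single_beam(gantry_deg: float) -> List[float]:
    return [gantry_deg % 360.0]


def parallel_opposed(gantry_deg: float) -> List[float]:
    return [gantry_deg % 360.0, (gantry_deg + 180.0) % 360.0]


# ---------------------------------------------------------------------------
# fields and BEV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldGeometry:
    gantry_deg: float
    isocenter_mm: np.ndarray
    direction: np.ndarray
    bev_u: np.ndarray
    bev_v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("direction", "bev_u", "bev_v"):
            vec = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, vec)
            if not math.isclose(float(np.linalg.norm(vec)), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must be a unit vector")
        if abs(float(self.direction @ self.bev_u)) > 1e-9 or abs(
            float(self.direction @ self.bev_v)
        ) > 1e-9:
            raise ValueError("BEV basis must be orthogonal to the beam axis")
        object.__setattr__(self, "isocenter_mm", np.asarray(self.isocenter_mm, dtype=float))


def make_field(gantry_deg: float, isocenter_mm: Sequence[float]) -> FieldGeometry:
    g = math.radians(gantry_deg)
    direction = np.array([-math.sin(g), math.cos(g), 0.0])
    u = np.array([math.cos(g), math.sin(g), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    return FieldGeometry(gantry_deg % 360.0, np.asarray(isocenter_mm, float), direction, u, v)


@dataclass(frozen=True)
class BEVFootprint:
    """Rasterised 2-D footprint in the BEV plane (cell-centre coordinates)."""

    mask: np.ndarray  # (nu, nv) bool
    u_coords_mm: np.ndarray
    v_coords_mm: np.ndarray
    resolution_mm: float

    def __post_init__(self) -> None:
        if self.mask.shape != (len(self.u_coords_mm), len(self.v_coords_mm)):
            raise ValueError("footprint mask shape does not match coordinate arrays")

    def centroid(self) -> Tuple[float, float]:
        iu, iv = np.nonzero(self.mask)
        return float(self.u_coords_mm[iu].mean()), float(self.v_coords_mm[iv].mean())


@dataclass(frozen=True)
class SpotGrid:
    field: FieldGeometry
    positions_mm: np.ndarray  # (n, 2) BEV (u, v)
    spacing_mm: float
    margin_mm: float
    sigma0_mm: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "positions_mm", pos)
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if len(pos) != len({(round(u, 6), round(v, 6)) for u, v in pos}):
            raise ValueError("spot positions must be unique")

    def __len__(self) -> int:
        return len(self.positions_mm)


# ---------------------------------------------------------------------------
# water-equivalent path length (Siddon/Amanatides-Woo traversal, numba)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _wepl_kernel(density, sx, sy, sz, ox, oy, oz, dx, dy, dz, out):  # pragma: no cover
    nx, ny, nz = density.shape
    bx0, by0, bz0 = ox, oy, oz
    bx1 = ox + nx * sx
    by1 = oy + ny * sy
    bz1 = oz + nz * sz
    big = 1e30
    for i in range(nx):
        px = ox + (i + 0.5) * sx
        for j in range(ny):
            py = oy + (j + 0.5) * sy
            for k in range(nz):
                pz = oz + (k + 0.5) * sz
                # line x(t) = p + t*d; find entry parameter tlo (<= 0)
                tlo = -big
                thi = big
                if dx != 0.0:
                    t1 = (bx0 - px) / dx
                    t2 = (bx1 - px) / dx
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > tlo:
                        tlo = t1
                    if t2 < thi:
                        thi = t2
                if dy != 0.0:
                    t1 = (by0 - py) / dy
                    t2 = (by1 - py) / dy
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > tlo:
                        tlo = t1
                    if t2 < thi:
                        thi = t2
                if dz != 0.0:
                    t1 = (bz0 - pz) / dz
                    t2 = (bz1 - pz) / dz
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > tlo:
                        tlo = t1
                    if t2 < thi:
                        thi = t2
                # march from entry (tlo) to the voxel centre (t = 0)
                t = tlo
                eps = 1e-9 * (sx + sy + sz)
                xs = px + (t + eps) * dx
                ys = py + (t + eps) * dy
                zs = pz + (t + eps) * dz
                ix = int((xs - ox) / sx)
                iy = int((ys - oy) / sy)
                iz = int((zs - oz) / sz)
                if ix < 0:
                    ix = 0
                if ix > nx - 1:
                    ix = nx - 1
                if iy < 0:
                    iy = 0
                if iy > ny - 1:
                    iy = ny - 1
                if iz < 0:
                    iz = 0
                if iz > nz - 1:
                    iz = nz - 1
                # parametric distance to the next crossing per axis
                if dx > 0.0:
                    tmx = (ox + (ix + 1) * sx - px) / dx
                    tdx = sx / dx
                    stx = 1
                elif dx < 0.0:
                    tmx = (ox + ix * sx - px) / dx
                    tdx = -sx / dx
                    stx = -1
                else:
                    tmx = big
                    tdx = big
                    stx = 0
                if dy > 0.0:
                    tmy = (oy + (iy + 1) * sy - py) / dy
                    tdy = sy / dy
                    sty = 1
                elif dy < 0.0:
                    tmy = (oy + iy * sy - py) / dy
                    tdy = -sy / dy
                    sty = -1
                else:
                    tmy = big
                    tdy = big
                    sty = 0
                if dz > 0.0:
                    tmz = (oz + (iz + 1) * sz - pz) / dz
                    tdz = sz / dz
                    stz = 1
                elif dz < 0.0:
                    tmz = (oz + iz * sz - pz) / dz
                    tdz = -sz / dz
                    stz = -1
                else:
                    tmz = big
                    tdz = big
                    stz = 0

                acc = 0.0
                while t < 0.0:
                    tnext = tmx
                    axis = 0
                    if tmy < tnext:
                        tnext = tmy
                        axis = 1
                    if tmz < tnext:
                        tnext = tmz
                        axis = 2
                    if tnext > 0.0:
                        tnext = 0.0
                        axis = -1
                    acc += density[ix, iy, iz] * (tnext - t)
                    t = tnext
                    if axis == 0:
                        ix += stx
                        tmx += tdx
                        if ix < 0 or ix >= nx:
                            break
                    elif axis == 1:
                        iy += sty
                        tmy += tdy
                        if iy < 0 or iy >= ny:
                            break
                    elif axis == 2:
                        iz += stz
                        tmz += tdz
                        if iz < 0 or iz >= nz:
                            break
                out[i, j, k] = acc


def radiological_depth(grid: ImageGrid, field: FieldGeometry) -> np.ndarray:
    """Water-equivalent path length (mm) to every voxel centre along the field.

    The line integral of relative density runs from the grid boundary to the
    voxel centre along ``field.direction``; with zero density outside the body
    this equals the integral from body entry.  Exact Amanatides-Woo voxel
    traversal (piecewise-constant density).
    """
    d = np.asarray(field.direction, dtype=float)
    if not math.isclose(float(np.linalg.norm(d)), 1.0, abs_tol=1e-9):
        raise ValueError("field.direction must be a unit vector")
    out = np.empty(grid.shape, dtype=np.float64)
    sx, sy, sz = grid.spacing_mm
    ox, oy, oz = grid.origin_mm
    _wepl_kernel(grid.density, sx, sy, sz, ox, oy, oz, d[0], d[1], d[2], out)
    return out


# ---------------------------------------------------------------------------
# BEV projection and spot placement
# ---------------------------------------------------------------------------


def bev_coordinates(grid: ImageGrid, field: FieldGeometry):
    """Per-voxel (u, v) BEV coordinates (mm) relative to the isocenter."""
    cx, cy, cz = grid.voxel_centers()
    xx, yy, zz = np.meshgrid(cx, cy, cz, indexing="ij")
    iso = field.isocenter_mm
    u = (
        (xx - iso[0]) * field.bev_u[0]
        + (yy - iso[1]) * field.bev_u[1]
        + (zz - iso[2]) * field.bev_u[2]
    )
    v = (
        (xx - iso[0]) * field.bev_v[0]
        + (yy - iso[1]) * field.bev_v[1]
        + (zz - iso[2]) * field.bev_v[2]
    )
    return u, v


def project_to_bev(
    structure: Structure,
    field: FieldGeometry,
    grid: ImageGrid,
    resolution_mm: float | None = None,
) -> BEVFootprint:
    """Orthographic projection of mask voxel centres onto the BEV plane.

    Rasterised at `resolution_mm` (default: min grid spacing); small raster
    holes from rotated projections are closed morphologically.
    """
    if not structure.mask.any():
        raise ValueError(f"structure {structure.name!r} is empty")
    res = resolution_mm if resolution_mm is not None else float(min(grid.spacing_mm))
    idx = np.nonzero(structure.mask)
    pts = np.stack(
        [grid.origin_mm[a] + (idx[a] + 0.5) * grid.spacing_mm[a] for a in range(3)], axis=1
    )
    rel = pts - field.isocenter_mm
    u = rel @ field.bev_u
    v = rel @ field.bev_v
    # cell-centre lattice anchored to the projected point cloud so projections
    # of axis-aligned voxel centres fall on cell centres, not edges
    u_min, v_min = u.min(), v.min()
    iu = np.round((u - u_min) / res).astype(int)
    iv = np.round((v - v_min) / res).astype(int)
    mask = np.zeros((iu.max() + 1, iv.max() + 1), dtype=bool)
    mask[iu, iv] = True
    from scipy.ndimage import binary_closing

    mask = binary_closing(mask, structure=np.ones((2, 2), dtype=bool)) | mask
    u_coords = u_min + np.arange(mask.shape[0]) * res
    v_coords = v_min + np.arange(mask.shape[1]) * res
    return BEVFootprint(mask, u_coords, v_coords, res)


def _distance_to_cells(points: np.ndarray, footprint: BEVFootprint) -> np.ndarray:
    """Euclidean distance from each point to the footprint region, treating
    each footprint cell as an axis-aligned square of side `resolution`."""
    iu, iv = np.nonzero(footprint.mask)
    cu = footprint.u_coords_mm[iu]
    cv = footprint.v_coords_mm[iv]
    half = footprint.resolution_mm / 2.0
    du = np.maximum(np.abs(points[:, 0:1] - cu[None, :]) - half, 0.0)
    dv = np.maximum(np.abs(points[:, 1:2] - cv[None, :]) - half, 0.0)
    return np.sqrt(du**2 + dv**2).min(axis=1)


def place_spots(
    footprint: BEVFootprint,
    spacing_mm: float,
    field: FieldGeometry,
    sigma0_mm: float,
    margin_mm: float = 5.0,
) -> SpotGrid:
    """Square spot lattice over the footprint dilated by `margin_mm`.

    The lattice is anchored at the footprint centroid; a lattice point is kept
    iff its Euclidean distance to the footprint region is <= margin (points
    exactly on the dilated boundary are kept).
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if not footprint.mask.any():
        raise ValueError("footprint is empty")
    c_u, c_v = footprint.centroid()
    half = footprint.resolution_mm / 2.0
    u_lo = footprint.u_coords_mm.min() - half - margin_mm
    u_hi = footprint.u_coords_mm.max() + half + margin_mm
    v_lo = footprint.v_coords_mm.min() - half - margin_mm
    v_hi = footprint.v_coords_mm.max() + half + margin_mm
    ku = np.arange(math.floor((u_lo - c_u) / spacing_mm), math.ceil((u_hi - c_u) / spacing_mm) + 1)
    kv = np.arange(math.floor((v_lo - c_v) / spacing_mm), math.ceil((v_hi - c_v) / spacing_mm) + 1)
    uu, vv = np.meshgrid(c_u + ku * spacing_mm, c_v + kv * spacing_mm, indexing="ij")
    candidates = np.column_stack([uu.ravel(), vv.ravel()])
    dist = np.empty(len(candidates))
    chunk = 4096
    for start in range(0, len(candidates), chunk):
        dist[start : start + chunk] = _distance_to_cells(
            candidates[start : start + chunk], footprint
        )
    keep = dist <= margin_mm + 1e-9
    return SpotGrid(
        field=field,
        positions_mm=candidates[keep],
        spacing_mm=spacing_mm,
        margin_mm=margin_mm,
        sigma0_mm=sigma0_mm,
    )
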
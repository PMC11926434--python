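"""Pencil-beam dose-to-water calculation and sparse influence matrix.

Per-voxel dose for one spot is the product of the depth-dose lookup at the
voxel's radiological depth and a lateral Gaussian evaluated at the voxel's
BEV offset from the pencil axis:

    dose_i = IDD(d_i) * exp(-r_i^2 / (2 sigma_tot(d_i)^2)) / (2 pi sigma_tot(d_i)^2)

The lateral Gaussian is normalised to unit integral over the lateral plane
(units mm^-2), so the IDD carries all longitudinal information and per-slice
lateral mass is conserved up to the cutoff.  Both the IDD lookup and
sigma_tot use radiological depth; voxels beyond `cutoff_sigmas * sigma_tot`
laterally receive exactly zero.  A single energy layer is used per field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .base_data import BeamBaseData, idd_at, sigma_total
from .geometry import FieldGeometry, SpotGrid, bev_coordinates, radiological_depth
from .phantom import ImageGrid

__all__ = [
    "PencilBeam",
    "InfluenceMatrix",
    "DoseDistribution",
    "spot_dose",
    "compute_influence",
    "total_dose",
    "save_influence",
    "load_influence",
]

DEFAULT_CUTOFF_SIGMAS = 3.5


@dataclass(frozen=True)
class PencilBeam:
    spot_index: int
    field: FieldGeometry
    u_mm: float
    v_mm: float
    energy_mev: float
    sigma0_mm: float


@dataclass(frozen=True)
class DoseDistribution:
    values: np.ndarray  # 3-D, grid-shaped
    grid: ImageGrid

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError("dose shape does not match grid shape")
        if np.any(self.values < 0):
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class InfluenceMatrix:
    """Sparse (n_voxels x n_spots) dose-per-unit-weight operator.

    Voxels are flattened in C order over the grid shape.  Spot ordering is
    field-major, then row-major over each field's lattice positions.
    """

    matrix: sp.csc_matrix
    grid: ImageGrid
    spot_table: List[dict]  # one entry per column: field, gantry_deg, u_mm, v_mm

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[1]


class _FieldDoseContext:
    """Cached per-field voxel quantities shared by all spots of the field."""

    def __init__(
        self,
        grid: ImageGrid,
        field: FieldGeometry,
        base: BeamBaseData,
        sigma0_mm: float,
        depth_map: np.ndarray | None = None,
    ):
        if depth_map is None:
            depth_map = radiological_depth(grid, field)
        u, v = bev_coordinates(grid, field)
        self.u = u.ravel()
        self.v = v.ravel()
        d = depth_map.ravel()
        self.idd = idd_at(base, d)
        self.sigma = sigma_total(sigma0_mm, d, base)
        self.sigma_max = float(self.sigma.max())

    def column(self, u0: float, v0: float, cutoff_sigmas: float):
        cut_max = cutoff_sigmas * self.sigma_max
        near = (np.abs(self.u - u0) <= cut_max) & (np.abs(self.v - v0) <= cut_max)
        idx = np.nonzero(near)[0]
        du = self.u[idx] - u0
        dv = self.v[idx] - v0
        r2 = du * du + dv * dv
        sig = self.sigma[idx]
        inside = r2 <= (cutoff_sigmas * sig) ** 2
        idx = idx[inside]
        vals = self.idd[idx] * np.exp(-r2[inside] / (2.0 * sig[inside] ** 2)) / (
            2.0 * np.pi * sig[inside] ** 2
        )
        keep = vals > 0.0
        return idx[keep], vals[keep]


def spot_dose(
    pb: PencilBeam,
    grid: ImageGrid,
    depth_map: np.ndarray,
    base: BeamBaseData,
    cutoff_sigmas: float = DEFAULT_CUTOFF_SIGMAS,
) -> sp.csc_matrix:
    """Sparse dose column (n_voxels x 1) for one pencil beam."""
    if base is None:
        raise ValueError(f"missing base data for field energy {pb.energy_mev} MeV")
    ctx = _FieldDoseContext(grid, pb.field, base, pb.sigma0_mm, depth_map=depth_map)
    idx, vals = ctx.column(pb.u_mm, pb.v_mm, cutoff_sigmas)
    n = int(np.prod(grid.shape))
    return sp.csc_matrix((vals, (idx, np.zeros_like(idx))), shape=(n, 1))


def compute_influence(
    spot_grids: Sequence[SpotGrid],
    grid: ImageGrid,
    bases: Sequence[BeamBaseData],
    cutoff_sigmas: float = DEFAULT_CUTOFF_SIGMAS,
) -> InfluenceMatrix:
    """Assemble the influence matrix, one column per spot of every field."""
    if len(spot_grids) != len(bases):
        raise ValueError("need one BeamBaseData per field")
    n_vox = int(np.prod(grid.shape))
    indices: list[np.ndarray] = []
    values: list[np.ndarray] = []
    indptr = [0]
    spot_table: list[dict] = []
    for f_idx, (sg, base) in enumerate(zip(spot_grids, bases)):
        pos = sg.positions_mm
        if len(pos) != len({(round(u, 6), round(v, 6)) for u, v in pos}):
            raise ValueError(f"duplicate spot positions in field {f_idx}")
        ctx = _FieldDoseContext(grid, sg.field, base, sg.sigma0_mm)
        # row-major lattice ordering: sort by (v desc? no) -- sort by (u, v)
        order = np.lexsort((pos[:, 1], pos[:, 0]))
        for s in order:
            u0, v0 = pos[s]
            idx, vals = ctx.column(float(u0), float(v0), cutoff_sigmas)
            indices.append(idx)
            values.append(vals)
            indptr.append(indptr[-1] + len(idx))
            spot_table.append(
                {
                    "field": f_idx,
                    "gantry_deg": sg.field.gantry_deg,
                    "u_mm": float(u0),
                    "v_mm": float(v0),
                    "energy_mev": base.spec.energy_mev,
                    "sigma0_mm": sg.sigma0_mm,
                }
            )
    if indices:
        data = np.concatenate(values)
        rows = np.concatenate(indices)
    else:
        data = np.empty(0)
        rows = np.empty(0, dtype=np.int64)
    matrix = sp.csc_matrix(
        (data, rows, np.asarray(indptr, dtype=np.int64)), shape=(n_vox, len(spot_table))
    )
    return InfluenceMatrix(matrix=matrix, grid=grid, spot_table=spot_table)


def total_dose(infl: InfluenceMatrix, weights: np.ndarray) -> DoseDistribution:
    """Dose distribution from spot weights (matrix-vector product)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (infl.n_spots,):
        raise ValueError(f"expected {infl.n_spots} weights, got shape {weights.shape}")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    dose = infl.matrix @ weights
    return DoseDistribution(values=dose.reshape(infl.grid.shape), grid=infl.grid)


# ---------------------------------------------------------------------------
# HDF5 persistence (CSC layout: data / indices / indptr + grid and spot maps)
# ---------------------------------------------------------------------------


def save_influence(infl: InfluenceMatrix, path: Union[str, Path]) -> None:
    import h5py
    import json

    with h5py.File(path, "w") as fh:
        m = infl.matrix
        fh.create_dataset("data", data=m.data)
        fh.create_dataset("indices", data=m.indices)
        fh.create_dataset("indptr", data=m.indptr)
        fh.attrs["shape"] = m.shape
        fh.attrs["grid_shape"] = infl.grid.shape
        fh.attrs["grid_spacing_mm"] = infl.grid.spacing_mm
        fh.attrs["grid_origin_mm"] = infl.grid.origin_mm
        fh.attrs["spot_table"] = json.dumps(infl.spot_table)
        fh.create_dataset("density", data=infl.grid.density)


def load_influence(path: Union[str, Path]) -> InfluenceMatrix:
    import h5py
    import json

    with h5py.File(path, "r") as fh:
        matrix = sp.csc_matrix(
            (fh["data"][()], fh["indices"][()], fh["indptr"][()]),
            shape=tuple(fh.attrs["shape"]),
        )
        grid = ImageGrid(
            shape=tuple(int(s) for s in fh.attrs["grid_shape"]),
            spacing_mm=tuple(float(s) for s in fh.attrs["grid_spacing_mm"]),
            origin_mm=tuple(float(s) for s in fh.attrs["grid_origin_mm"]),
            density=fh["density"][()],
        )
        spot_table = json.loads(fh.attrs["spot_table"])
    return InfluenceMatrix(matrix=matrix, grid=grid, spot_table=spot_table)
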
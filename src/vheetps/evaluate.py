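"""DVH computation and plan-quality metrics.

Quantile convention: Dx% is the minimum dose received by the hottest x% of
the structure volume, evaluated by sorting voxel doses in descending order
and taking the value at rank ceil(x/100 * n) (no interpolation).  The
homogeneity index is HI = (D2% - D98%) / D50% (ICRU-83 style; lower is more
homogeneous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

import numpy as np

from .dose_engine import DoseDistribution
from .phantom import Structure, StructureSet, structure_volume

__all__ = [
    "DVHCurve",
    "compute_dvh",
    "dose_at_volume",
    "dose_at_absolute_volume",
    "volume_at_dose",
    "mean_dose",
    "homogeneity_index",
    "compute_metrics",
]


@dataclass(frozen=True)
class DVHCurve:
    structure: str
    dose_edges_gy: np.ndarray
    volume_fraction: np.ndarray  # fraction of volume receiving >= edge dose

    def __post_init__(self) -> None:
        v = self.volume_fraction
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("DVH must be non-increasing in dose")
        if not math.isclose(float(v[0]), 1.0):
            raise ValueError("DVH must start at 1 at dose 0")


def _structure_doses(dose: DoseDistribution, s: Structure) -> np.ndarray:
    if not s.mask.any():
        raise ValueError(f"structure {s.name!r} is empty")
    if tuple(s.mask.shape) != tuple(dose.values.shape):
        raise ValueError("structure mask is not aligned to the dose grid")
    return dose.values[s.mask]


def compute_dvh(dose: DoseDistribution, s: Structure, bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= each edge dose."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    d = _structure_doses(dose, s)
    n_bins = int(math.ceil(float(d.max()) / bin_width_gy)) + 1 if d.max() > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width_gy
    frac = (d[None, :] >= edges[:, None]).mean(axis=1) if len(d) < 200_000 else np.array(
        [(d >= e).mean() for e in edges]
    )
    frac[0] = 1.0  # every voxel receives >= 0
    return DVHCurve(s.name, edges, frac)


def dose_at_volume(dose: DoseDistribution, s: Structure, x_percent: float) -> float:
    """Dx%: minimum dose to the hottest x% of the structure."""
    if not (0 < x_percent <= 100):
        raise ValueError("x must be in (0, 100]")
    d = np.sort(_structure_doses(dose, s))[::-1]
    rank = int(math.ceil(x_percent / 100.0 * len(d)))
    return float(d[rank - 1])


def dose_at_absolute_volume(
    dose: DoseDistribution, s: Structure, v_cm3: float, grid=None
) -> float:
    """D_v: minimum dose to the hottest v cm^3 of the structure."""
    grid = grid or dose.grid
    vol = structure_volume(s, grid)
    if v_cm3 <= 0:
        raise ValueError("v must be positive")
    if v_cm3 > vol * (1 + 1e-9):
        raise ValueError(f"v = {v_cm3} cm^3 exceeds structure volume {vol:.3f} cm^3")
    d = np.sort(_structure_doses(dose, s))[::-1]
    rank = int(math.ceil(v_cm3 * 1000.0 / grid.voxel_volume_mm3))
    rank = min(rank, len(d))
    return float(d[rank - 1])


def volume_at_dose(dose: DoseDistribution, s: Structure, x_gy: float) -> float:
    """V_x: percentage of structure volume receiving >= x Gy."""
    if x_gy < 0:
        raise ValueError("dose level must be non-negative")
    d = _structure_doses(dose, s)
    return 100.0 * float((d >= x_gy).mean())


def mean_dose(dose: DoseDistribution, s: Structure) -> float:
    return float(_structure_doses(dose, s).mean())


def homogeneity_index(dose: DoseDistribution, s: Structure) -> float:
    """HI = (D2% - D98%) / D50%; lower is more homogeneous."""
    d50 = dose_at_volume(dose, s, 50.0)
    if d50 == 0:
        raise ValueError("D50% is zero; HI undefined")
    return (dose_at_volume(dose, s, 2.0) - dose_at_volume(dose, s, 98.0)) / d50


def compute_metrics(dose: DoseDistribution, structure_set: StructureSet) -> Dict[str, Dict[str, float]]:
    """Standard metric suite per structure.

    Targets get D50%, D98%, D95%, D2%, D_1cm3, Dmean and HI; OARs and the
    external get Dmean, D_1cm3 (when the structure holds >= 1 cm^3), V20Gy
    and V5Gy.
    """
    grid = structure_set.grid
    out: Dict[str, Dict[str, float]] = {}
    for name, s in structure_set.structures.items():
        if not s.mask.any():
            continue
        m: Dict[str, float] = {"Dmean": mean_dose(dose, s)}
        vol = structure_volume(s, grid)
        if vol >= 1.0:
            m["D_1cm3"] = dose_at_absolute_volume(dose, s, 1.0)
        if s.role == "target":
            m["D50%"] = dose_at_volume(dose, s, 50.0)
            m["D98%"] = dose_at_volume(dose, s, 98.0)
            m["D95%"] = dose_at_volume(dose, s, 95.0)
            m["D2%"] = dose_at_volume(dose, s, 2.0)
            m["HI"] = homogeneity_index(dose, s)
        else:
            m["V20Gy"] = volume_at_dose(dose, s, 20.0)
            m["V5Gy"] = volume_at_dose(dose, s, 5.0)
        out[name] = m
    return out
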
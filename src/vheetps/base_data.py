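"""Beam base data for VHEE pencil beams.

Per-energy tables of laterally integrated depth dose (IDD) and multiple-
scattering lateral spread sigma as a function of depth in water.  Tables can
be generated from an analytic model (build-up times quasi-exponential IDD;
Highland scattering power integrated through the Fermi-Eyges second moment)
or imported from CSV, and are consumed interchangeably by the dose engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "BeamEnergySpec",
    "DepthDoseTable",
    "LateralSpreadTable",
    "AnalyticModelParams",
    "BeamBaseData",
    "generate_analytic_base_data",
    "sigma_total",
    "idd_at",
    "fwhm_from_sigma",
    "save_base_data",
    "load_base_data",
]

#: FWHM / sigma for a Gaussian profile.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Energies (MeV) and initial spot sigmas (mm) of the reference study grid.
STANDARD_ENERGIES_MEV = (70.0, 110.0, 150.0, 200.0, 240.0)
STANDARD_SIGMAS_MM = (2.0, 4.0, 11.0, 21.0, 42.0)


@dataclass(frozen=True)
class BeamEnergySpec:
    """Nominal beam energy (MeV) and initial Gaussian spot sigma (mm)."""

    energy_mev: float
    sigma0_mm: float = 4.0

    def __post_init__(self) -> None:
        if not (self.energy_mev > 0):
            raise ValueError(f"energy must be positive, got {self.energy_mev}")
        if not (self.sigma0_mm > 0):
            raise ValueError(f"sigma0 must be positive, got {self.sigma0_mm}")


@dataclass(frozen=True)
class DepthDoseTable:
    """Integrated depth dose vs depth; idd is normalised so max(idd) == 1."""

    depths_mm: np.ndarray
    idd: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_mm, dtype=float)
        v = np.asarray(self.idd, dtype=float)
        object.__setattr__(self, "depths_mm", d)
        object.__setattr__(self, "idd", v)
        if d.ndim != 1 or v.shape != d.shape:
            raise ValueError("depths and idd must be 1-D arrays of equal length")
        if d[0] != 0 or np.any(np.diff(d) <= 0):
            raise ValueError("depths must start at 0 and be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("idd must be finite and non-negative")
        if not math.isclose(float(v.max()), 1.0, rel_tol=1e-9):
            raise ValueError("idd must be normalised to max 1")


@dataclass(frozen=True)
class LateralSpreadTable:
    """Multiple-scattering sigma (mm) vs depth; zero at the surface."""

    depths_mm: np.ndarray
    sigma_scatter_mm: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_mm, dtype=float)
        s = np.asarray(self.sigma_scatter_mm, dtype=float)
        object.__setattr__(self, "depths_mm", d)
        object.__setattr__(self, "sigma_scatter_mm", s)
        if d.ndim != 1 or s.shape != d.shape:
            raise ValueError("depths and sigma must be 1-D arrays of equal length")
        if d[0] != 0 or np.any(np.diff(d) <= 0):
            raise ValueError("depths must start at 0 and be strictly increasing")
        if s[0] != 0:
            raise ValueError("sigma_scatter must be 0 at depth 0")
        if np.any(np.diff(s) < 0) or np.any(s < 0):
            raise ValueError("sigma_scatter must be non-negative and non-decreasing")


@dataclass(frozen=True)
class AnalyticModelParams:
    """Constants of the analytic base-data model.

    The scattering power is the Highland form T(z) = (E_s / E(z))^2 / X0 with
    the depth-local mean energy E(z) = max(E0 - S*z, E_min) from a constant
    collisional stopping power S.  The IDD shape is
    (1 - exp(-z / z_b(E))) * exp(-mu(E) * z) with a build-up length
    z_b(E) = buildup_mm_per_mev * E (non-decreasing in E) and attenuation
    mu(E) = S / E (strictly decreasing in E, i.e. 1 / CSDA-like range).
    """

    radiation_length_water_mm: float = 360.8
    highland_constant_mev: float = 14.1
    collisional_stopping_power_mev_per_mm: float = 0.2
    buildup_mm_per_mev: float = 0.05
    min_energy_mev: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "radiation_length_water_mm",
            "highland_constant_mev",
            "collisional_stopping_power_mev_per_mm",
            "buildup_mm_per_mev",
            "min_energy_mev",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")

    def buildup_length_mm(self, energy_mev: float) -> float:
        return self.buildup_mm_per_mev * energy_mev

    def attenuation_per_mm(self, energy_mev: float) -> float:
        return self.collisional_stopping_power_mev_per_mm / energy_mev

    def local_energy_mev(self, energy_mev: float, depth_mm) -> np.ndarray:
        e = energy_mev - self.collisional_stopping_power_mev_per_mm * np.asarray(
            depth_mm, dtype=float
        )
        return np.maximum(e, self.min_energy_mev)

    def scattering_power_per_mm(self, energy_mev: float, depth_mm) -> np.ndarray:
        """Highland scattering power T(z) in rad^2/mm at local mean energy."""
        e = self.local_energy_mev(energy_mev, depth_mm)
        return (self.highland_constant_mev / e) ** 2 / self.radiation_length_water_mm


@dataclass(frozen=True)
class BeamBaseData:
    """Depth-dose and lateral-spread tables for one beam energy/spot size."""

    spec: BeamEnergySpec
    depth_dose: DepthDoseTable
    lateral_spread: LateralSpreadTable
    provenance: str = "analytic"
    generation_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.provenance not in ("analytic", "tabulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        dd, ls = self.depth_dose, self.lateral_spread
        if dd.depths_mm[-1] != ls.depths_mm[-1] or dd.depths_mm[0] != ls.depths_mm[0]:
            raise ValueError("depth-dose and lateral-spread tables must cover a common depth range")

    @property
    def max_depth_mm(self) -> float:
        return float(self.depth_dose.depths_mm[-1])


def generate_analytic_base_data(
    spec: BeamEnergySpec,
    params: AnalyticModelParams | None = None,
    max_depth_mm: float = 400.0,
    step_mm: float = 1.0,
) -> BeamBaseData:
    """Generate base data from the analytic model on a uniform depth lattice.

    The Fermi-Eyges second moment
    ``sigma^2(z) = int_0^z T(z') (z - z')^2 dz'``
    is evaluated by expanding the square and reusing three cumulative
    trapezoid integrals of T, T*z' and T*z'^2 (exact to quadrature error).
    """
    params = params or AnalyticModelParams()
    if step_mm <= 0:
        raise ValueError("step must be positive")
    if step_mm > 1.0:
        raise ValueError("step must be <= 1 mm")
    if max_depth_mm < 300.0:
        raise ValueError("max_depth must be >= 300 mm")

    n = int(round(max_depth_mm / step_mm))
    z = np.linspace(0.0, n * step_mm, n + 1)

    zb = params.buildup_length_mm(spec.energy_mev)
    mu = params.attenuation_per_mm(spec.energy_mev)
    idd = (1.0 - np.exp(-z / zb)) * np.exp(-mu * z)
    idd = idd / idd.max()

    t = params.scattering_power_per_mm(spec.energy_mev, z)
    i0 = cumulative_trapezoid(t, z, initial=0.0)
    i1 = cumulative_trapezoid(t * z, z, initial=0.0)
    i2 = cumulative_trapezoid(t * z * z, z, initial=0.0)
    var = z * z * i0 - 2.0 * z * i1 + i2
    sigma = np.sqrt(np.maximum(var, 0.0))
    sigma[0] = 0.0

    return BeamBaseData(
        spec=spec,
        depth_dose=DepthDoseTable(z, idd),
        lateral_spread=LateralSpreadTable(z, sigma),
        provenance="analytic",
        generation_params={
            "radiation_length_water_mm": params.radiation_length_water_mm,
            "highland_constant_mev": params.highland_constant_mev,
            "collisional_stopping_power_mev_per_mm": params.collisional_stopping_power_mev_per_mm,
            "buildup_mm_per_mev": params.buildup_mm_per_mev,
            "min_energy_mev": params.min_energy_mev,
            "max_depth_mm": max_depth_mm,
            "step_mm": step_mm,
        },
    )


def sigma_scatter_at(base: BeamBaseData, depth_mm) -> np.ndarray:
    """Scattering sigma at depth, linearly interpolated, clamped at both ends."""
    ls = base.lateral_spread
    return np.interp(depth_mm, ls.depths_mm, ls.sigma_scatter_mm)


def sigma_total(sigma0_mm, depth_mm, base: BeamBaseData) -> np.ndarray:
    """Total lateral sigma: quadrature sum of initial spot size and scattering."""
    sigma0 = np.asarray(sigma0_mm, dtype=float)
    if np.any(sigma0 < 0):
        raise ValueError("sigma0 must be non-negative")
    ss = sigma_scatter_at(base, depth_mm)
    return np.sqrt(sigma0**2 + ss**2)


def idd_at(base: BeamBaseData, depth_mm) -> np.ndarray:
    """IDD at depth: linear interpolation inside the table, 0 beyond the end."""
    depth = np.asarray(depth_mm, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    dd = base.depth_dose
    return np.interp(depth, dd.depths_mm, dd.idd, right=0.0)


def fwhm_from_sigma(sigma_mm: float) -> float:
    """FWHM of a Gaussian with standard deviation sigma: 2*sqrt(2 ln 2)*sigma."""
    if sigma_mm < 0:
        raise ValueError("sigma must be non-negative")
    return FWHM_PER_SIGMA * sigma_mm


# ---------------------------------------------------------------------------
# Persistence: CSV table `depth_mm,idd,sigma_scatter_mm` + JSON metadata sidecar
# ---------------------------------------------------------------------------

_CSV_HEADER = "depth_mm,idd,sigma_scatter_mm"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_base_data(base: BeamBaseData, path: Union[str, Path]) -> None:
    path = Path(path)
    data = np.column_stack(
        [base.depth_dose.depths_mm, base.depth_dose.idd, base.lateral_spread.sigma_scatter_mm]
    )
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER + "\n")
        for row in data:
            fh.write(f"{row[0]:.10g},{row[1]:.12g},{row[2]:.12g}\n")
    meta = {
        "energy_mev": base.spec.energy_mev,
        "sigma0_mm": base.spec.sigma0_mm,
        "provenance": base.provenance,
        "generation_params": base.generation_params,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


class BaseDataParseError(ValueError):
    """Malformed base-data file (names the offending row/field)."""


def load_base_data(path: Union[str, Path]) -> BeamBaseData:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise BaseDataParseError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())

    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _CSV_HEADER:
        raise BaseDataParseError(
            f"{path}: expected header {_CSV_HEADER!r}, got {lines[0]!r}" if lines else f"{path}: empty file"
        )
    depths, idd, sig = [], [], []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise BaseDataParseError(f"{path}:{i}: expected 3 fields, got {len(parts)}")
        try:
            depths.append(float(parts[0]))
            idd.append(float(parts[1]))
            sig.append(float(parts[2]))
        except ValueError as exc:
            raise BaseDataParseError(f"{path}:{i}: non-numeric field ({exc})") from exc
    try:
        dd = DepthDoseTable(np.array(depths), np.array(idd))
        ls = LateralSpreadTable(np.array(depths), np.array(sig))
    except ValueError as exc:
        raise BaseDataParseError(f"{path}: {exc}") from exc
    return BeamBaseData(
        spec=BeamEnergySpec(meta["energy_mev"], meta["sigma0_mm"]),
        depth_dose=dd,
        lateral_spread=ls,
        provenance=meta.get("provenance", "tabulated"),
        generation_params=meta.get("generation_params", {}),
    )
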
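"""Automated planning pipeline and parameter sweeps.

`run_plan` chains the full three-stage workflow — beam configuration, dose
calculation (influence matrix), fluence optimisation — followed by
prescription normalisation and metric extraction.  `run_sweep` runs the
Cartesian product of configured factors and collects a long-format table;
per-plan failures are recorded rather than fatal.  A pseudo-reference plan
(12-beam full-arc VHEE) stands in for clinical arc-therapy references, which
are out of scope; `compare_to_reference` joins any externally supplied
reference metric table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .base_data import (
    AnalyticModelParams,
    BeamBaseData,
    BeamEnergySpec,
    generate_analytic_base_data,
)
from .dose_engine import compute_influence, total_dose
from .evaluate import compute_metrics
from .geometry import arrange_beams, make_field, place_spots, project_to_bev
from .optimizer import ObjectiveSpec, OptimizationProblem, normalize_plan, solve
from .phantom import PhantomSpec, StructureSet, make_phantom, structure_volume

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "PlanRecord",
    "default_objectives",
    "run_plan",
    "run_sweep",
    "compare_to_reference",
    "pseudo_reference",
    "PROSTATE_PRESCRIPTION_GY",
    "LUNG_PRESCRIPTION_GY",
]

#: Protocol prescriptions: 60 Gy / 20 fx (prostate), 55 Gy / 20 fx (lung).
PROSTATE_PRESCRIPTION_GY = 60.0
LUNG_PRESCRIPTION_GY = 55.0
PROSTATE_FRACTIONS = 20
LUNG_FRACTIONS = 20

RESULT_COLUMNS = [
    "phantom",
    "n_beams",
    "arc_span",
    "energy_MeV",
    "sigma0_mm",
    "spacing_k",
    "structure",
    "metric",
    "value",
]


def default_objectives(protocol: str, prescription_gy: float) -> List[ObjectiveSpec]:
    """Editable default objective sets per cohort protocol.

    Constraint values are package defaults, not authoritative clinical
    protocol numbers.
    """
    # OAR mean-dose references are 0 so the quadratic penalty always pushes
    # the mean down; a nonzero reference would pin the mean at that value.
    if protocol == "prostate":
        return [
            ObjectiveSpec("ptv", "uniform_target", prescription_gy, 100.0),
            ObjectiveSpec("rectum", "max_dose", 0.95 * prescription_gy, 10.0),
            ObjectiveSpec("rectum", "mean_dose", 0.0, 1.0),
            ObjectiveSpec("bladder", "max_dose", 0.95 * prescription_gy, 5.0),
            ObjectiveSpec("bladder", "mean_dose", 0.0, 1.0),
            ObjectiveSpec("body", "max_dose", 1.05 * prescription_gy, 5.0),
        ]
    if protocol == "lung":
        return [
            ObjectiveSpec("ptv", "uniform_target", prescription_gy, 100.0),
            ObjectiveSpec("lung", "mean_dose", 0.0, 0.5),
            ObjectiveSpec("heart", "max_dose", 0.7 * prescription_gy, 5.0),
            ObjectiveSpec("heart", "mean_dose", 0.0, 0.25),
            ObjectiveSpec("oesophagus", "max_dose", 0.8 * prescription_gy, 5.0),
            ObjectiveSpec("spinal_cord", "max_dose", 0.55 * prescription_gy, 10.0),
            ObjectiveSpec("body", "max_dose", 1.05 * prescription_gy, 5.0),
        ]
    raise ValueError(f"unknown protocol {protocol!r}")


@dataclass
class PlanRecord:
    phantom: str
    n_beams: int
    arc_span: float
    arc_center: float
    energy_mev: float
    sigma0_mm: float
    spacing_k: float
    prescription_gy: float
    seed: int
    n_spots: int
    spots_per_100cm3: float
    converged: bool
    iterations: int
    final_objective: float
    metrics: Dict[str, Dict[str, float]]

    def to_rows(self) -> List[dict]:
        rows = []
        for structure, mm in self.metrics.items():
            for metric, value in mm.items():
                rows.append(
                    {
                        "phantom": self.phantom,
                        "n_beams": self.n_beams,
                        "arc_span": self.arc_span,
                        "energy_MeV": self.energy_mev,
                        "sigma0_mm": self.sigma0_mm,
                        "spacing_k": self.spacing_k,
                        "structure": structure,
                        "metric": metric,
                        "value": value,
                    }
                )
        return rows

    def record_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in asdict(self).items()}, sort_keys=True, default=float
        )
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class StudyConfig:
    phantoms: Dict[str, PhantomSpec]
    beam_counts: Sequence[int]
    arc_span_deg: float
    arc_center_deg: float
    energies_mev: Sequence[float]
    sigma0_mm: float
    spacing_multipliers: Sequence[float]
    protocol: str
    prescription_gy: float
    fractions: int = 20
    margin_mm: float = 5.0
    cutoff_sigmas: float = 3.5
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lst in (
            ("phantoms", self.phantoms),
            ("beam_counts", self.beam_counts),
            ("energies_mev", self.energies_mev),
            ("spacing_multipliers", self.spacing_multipliers),
        ):
            if not lst:
                raise ValueError(f"{name} must be non-empty")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        phantoms = {
            name: PhantomSpec(
                recipe=p["recipe"],
                spacing_mm=tuple(p.get("spacing_mm", (2.0, 2.0, 2.0))),
                size_mm=tuple(p["size_mm"]) if "size_mm" in p else None,
                lung_density=p.get("lung_density", 0.3),
                ptv_volume_cm3=p.get("ptv_volume_cm3"),
                params=p.get("params", {}),
                seed=p.get("seed", 0),
            )
            for name, p in raw["phantoms"].items()
        }
        return cls(
            phantoms=phantoms,
            beam_counts=raw["beam_counts"],
            arc_span_deg=raw.get("arc_span_deg", 360.0),
            arc_center_deg=raw.get("arc_center_deg", 0.0),
            energies_mev=raw["energies_mev"],
            sigma0_mm=raw.get("sigma0_mm", 4.0),
            spacing_multipliers=raw.get("spacing_multipliers", [1.5]),
            protocol=raw["protocol"],
            prescription_gy=raw["prescription_gy"],
            fractions=raw.get("fractions", 20),
            margin_mm=raw.get("margin_mm", 5.0),
            cutoff_sigmas=raw.get("cutoff_sigmas", 3.5),
            max_iter=raw.get("max_iter", 300),
            seed=raw.get("seed", 0),
        )


def run_plan(
    structure_set: StructureSet,
    n_beams: int,
    arc_span_deg: float,
    energy_mev: float,
    sigma0_mm: float,
    spacing_k: float,
    objectives: List[ObjectiveSpec],
    prescription_gy: float,
    arc_center_deg: float = 0.0,
    margin_mm: float = 5.0,
    cutoff_sigmas: float = 3.5,
    max_iter: int = 300,
    seed: int = 0,
    phantom_name: str = "phantom",
    base_params: Optional[AnalyticModelParams] = None,
    return_dose: bool = False,
):
    """Run one full plan: beams -> spots -> influence -> optimise -> normalise."""
    grid = structure_set.grid
    target = structure_set.target
    iso = _mask_centroid(structure_set, target)

    stage = "beam configuration"
    try:
        angles = arrange_beams(n_beams, arc_span_deg, arc_center_deg)
        spot_grids = []
        bases = []
        base = generate_analytic_base_data(
            BeamEnergySpec(energy_mev, sigma0_mm), base_params or AnalyticModelParams()
        )
        for g in angles:
            fld = make_field(g, iso)
            footprint = project_to_bev(target, fld, grid)
            sg = place_spots(
                footprint,
                spacing_mm=spacing_k * sigma0_mm,
                field=fld,
                sigma0_mm=sigma0_mm,
                margin_mm=margin_mm,
            )
            spot_grids.append(sg)
            bases.append(base)

        stage = "dose calculation"
        infl = compute_influence(spot_grids, grid, bases, cutoff_sigmas=cutoff_sigmas)

        stage = "plan optimisation"
        problem = OptimizationProblem(infl, structure_set, objectives)
        result = solve(problem, max_iter=max_iter, seed=seed)
        dose = total_dose(infl, result.weights)
        weights, dose = normalize_plan(result.weights, dose, target, prescription_gy)
    except Exception as exc:
        raise RuntimeError(f"plan failed during {stage}: {exc}") from exc

    metrics = compute_metrics(dose, structure_set)
    n_spots = sum(len(sg) for sg in spot_grids)
    target_vol = structure_volume(target, grid)
    record = PlanRecord(
        phantom=phantom_name,
        n_beams=n_beams,
        arc_span=arc_span_deg,
        arc_center=arc_center_deg,
        energy_mev=energy_mev,
        sigma0_mm=sigma0_mm,
        spacing_k=spacing_k,
        prescription_gy=prescription_gy,
        seed=seed,
        n_spots=n_spots,
        spots_per_100cm3=100.0 * n_spots / target_vol,
        converged=result.converged,
        iterations=result.iterations,
        final_objective=float(result.trace[-1]),
        metrics=metrics,
    )
    if return_dose:
        return record, dose, weights
    return record


def _mask_centroid(structure_set: StructureSet, target) -> np.ndarray:
    grid = structure_set.grid
    idx = np.nonzero(target.mask)
    return np.array(
        [
            grid.origin_mm[a] + (idx[a].mean() + 0.5) * grid.spacing_mm[a]
            for a in range(3)
        ]
    )


def run_sweep(cfg: StudyConfig) -> pd.DataFrame:
    """Run the Cartesian sweep; failures are logged and recorded, not fatal."""
    rows: List[dict] = []
    failures: List[dict] = []
    for phantom_name, spec in cfg.phantoms.items():
        structure_set = make_phantom(spec)
        for n_beams in cfg.beam_counts:
            for energy in cfg.energies_mev:
                for k in cfg.spacing_multipliers:
                    try:
                        record = run_plan(
                            structure_set,
                            n_beams=n_beams,
                            arc_span_deg=cfg.arc_span_deg,
                            energy_mev=energy,
                            sigma0_mm=cfg.sigma0_mm,
                            spacing_k=k,
                            objectives=default_objectives(cfg.protocol, cfg.prescription_gy),
                            prescription_gy=cfg.prescription_gy,
                            arc_center_deg=cfg.arc_center_deg,
                            margin_mm=cfg.margin_mm,
                            cutoff_sigmas=cfg.cutoff_sigmas,
                            max_iter=cfg.max_iter,
                            seed=cfg.seed,
                            phantom_name=phantom_name,
                        )
                        rows.extend(record.to_rows())
                    except Exception as exc:  # recorded outcome, sweep continues
                        logger.warning(
                            "plan failed (%s, %s beams, %s MeV, %.1f sigma): %s",
                            phantom_name, n_beams, energy, k, exc,
                        )
                        failures.append(
                            {
                                "phantom": phantom_name,
                                "n_beams": n_beams,
                                "energy_MeV": energy,
                                "spacing_k": k,
                                "error": str(exc),
                            }
                        )
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    table.attrs["failures"] = failures
    return table


def pseudo_reference(
    structure_set: StructureSet,
    cfg: StudyConfig,
    phantom_name: str,
    energy_mev: Optional[float] = None,
) -> pd.DataFrame:
    """Self-contained pseudo-reference: a 12-beam full-arc VHEE plan.

    This approximates an arc delivery for difference plots; it is NOT a
    clinical arc-therapy reference plan.
    """
    record = run_plan(
        structure_set,
        n_beams=12,
        arc_span_deg=360.0,
        energy_mev=energy_mev or max(cfg.energies_mev),
        sigma0_mm=cfg.sigma0_mm,
        spacing_k=1.5,
        objectives=default_objectives(cfg.protocol, cfg.prescription_gy),
        prescription_gy=cfg.prescription_gy,
        arc_center_deg=cfg.arc_center_deg,
        margin_mm=cfg.margin_mm,
        cutoff_sigmas=cfg.cutoff_sigmas,
        max_iter=cfg.max_iter,
        seed=cfg.seed,
        phantom_name=phantom_name,
    )
    return pd.DataFrame(record.to_rows(), columns=RESULT_COLUMNS)


def compare_to_reference(table: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Join plan metrics against a reference table.

    Adds `ref_value`, `abs_diff` = value - ref_value and
    `rel_diff_pct` = 100 * (value - ref_value) / ref_value.  Rows without a
    matching (phantom, structure, metric) reference are reported in
    `result.attrs['unmatched']`.
    """
    keys = ["phantom", "structure", "metric"]
    ref = reference[keys + ["value"]].rename(columns={"value": "ref_value"})
    merged = table.merge(ref, on=keys, how="left")
    unmatched = merged[merged["ref_value"].isna()]
    merged["abs_diff"] = merged["value"] - merged["ref_value"]
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["rel_diff_pct"] = 100.0 * merged["abs_diff"] / merged["ref_value"]
    merged.attrs["unmatched"] = unmatched[keys].to_dict("records")
    return merged
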
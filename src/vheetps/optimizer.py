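"""Non-negative fluence-map optimisation of spot weights.

Objectives are quadratic penalties averaged over structure voxels:

* ``uniform_target``: p * mean_i (D_i - d)^2
* ``max_dose``:      p * mean_i max(0, D_i - d)^2
* ``mean_dose``:     p * (mean_i D_i - d)^2
* ``dvh_max``:       p * mean_i max(0, D_i - d)^2 restricted to hot voxels
  outside the allowed hottest volume fraction (re-sorted every evaluation,
  hence non-convex)

The solver is projected bound-constrained quasi-Newton (L-BFGS-B) with
weights >= 0, a uniform positive initial point scaled to put the mean target
dose at the target reference, and a documented stopping rule
(projected-gradient tolerance or max_iter).  Fully deterministic given the
problem; `seed` is recorded for provenance only.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .dose_engine import DoseDistribution, InfluenceMatrix, total_dose
from .phantom import Structure, StructureSet

__all__ = [
    "ObjectiveSpec",
    "OptimizationProblem",
    "OptimizationResult",
    "objective_value",
    "solve",
    "normalize_plan",
]

KINDS = ("uniform_target", "max_dose", "mean_dose", "dvh_max")


@dataclass(frozen=True)
class ObjectiveSpec:
    structure: str
    kind: str
    dose_gy: float
    weight: float = 1.0
    volume_fraction: Optional[float] = None  # dvh_max only

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.dose_gy < 0 or self.weight < 0:
            raise ValueError("reference dose and penalty weight must be >= 0")
        if self.kind == "dvh_max":
            if self.volume_fraction is None or not (0 <= self.volume_fraction <= 1):
                raise ValueError("dvh_max requires volume_fraction in [0, 1]")


class OptimizationProblem:
    def __init__(
        self,
        influence: InfluenceMatrix,
        structures: StructureSet,
        objectives: List[ObjectiveSpec],
    ):
        self.influence = influence
        self.structures = structures
        self.objectives = objectives
        self._voxel_idx: Dict[str, np.ndarray] = {}
        for obj in objectives:
            if obj.structure not in structures.structures:
                raise KeyError(f"objective references unknown structure {obj.structure!r}")
            mask = structures[obj.structure].mask
            if not mask.any():
                raise ValueError(f"objective structure {obj.structure!r} is empty")
            if obj.structure not in self._voxel_idx:
                self._voxel_idx[obj.structure] = np.nonzero(mask.ravel())[0]
        targets = [o for o in objectives if o.kind == "uniform_target"]
        if len(targets) != 1:
            raise ValueError("exactly one uniform_target objective is required")
        self.target_objective = targets[0]

    def voxel_indices(self, structure: str) -> np.ndarray:
        return self._voxel_idx[structure]


def objective_value(
    weights: np.ndarray, problem: OptimizationProblem
) -> Tuple[float, np.ndarray]:
    """Composite objective and its gradient w.r.t. the spot weights."""
    weights = np.asarray(weights, dtype=float)
    a = problem.influence.matrix
    dose = a @ weights
    g_dose = np.zeros_like(dose)
    f = 0.0
    for obj in problem.objectives:
        idx = problem.voxel_indices(obj.structure)
        d = dose[idx]
        n = len(idx)
        if obj.kind == "uniform_target":
            diff = d - obj.dose_gy
            f += obj.weight * float(diff @ diff) / n
            g_dose[idx] += obj.weight * 2.0 * diff / n
        elif obj.kind == "max_dose":
            over = np.maximum(d - obj.dose_gy, 0.0)
            f += obj.weight * float(over @ over) / n
            g_dose[idx] += obj.weight * 2.0 * over / n
        elif obj.kind == "mean_dose":
            diff = float(d.mean() - obj.dose_gy)
            f += obj.weight * diff * diff
            g_dose[idx] += obj.weight * 2.0 * diff / n
        else:  # dvh_max: penalise hot voxels outside the allowed hottest fraction
            n_allow = int(np.floor(obj.volume_fraction * n))
            order = np.argsort(d)[::-1]
            viol = order[n_allow:]
            over = np.maximum(d[viol] - obj.dose_gy, 0.0)
            f += obj.weight * float(over @ over) / n
            g_dose[idx[viol]] += obj.weight * 2.0 * over / n
    grad = a.T @ g_dose
    return f, grad


@dataclass
class OptimizationResult:
    weights: np.ndarray
    trace: List[float]
    converged: bool
    iterations: int
    seed: int
    message: str = ""

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("optimised weights must be non-negative")
        if self.trace and self.trace[-1] > self.trace[0] * (1 + 1e-12):
            raise ValueError("final objective exceeds initial objective")


def _initial_weights(problem: OptimizationProblem) -> np.ndarray:
    """Uniform positive start scaled so mean target dose equals the target
    reference dose."""
    a = problem.influence.matrix
    n_spots = a.shape[1]
    ones = np.ones(n_spots)
    idx = problem.voxel_indices(problem.target_objective.structure)
    mean_target = float((a @ ones)[idx].mean())
    if mean_target <= 0:
        raise ValueError(
            "target receives zero influence from all spots; "
            "check field geometry and spot placement"
        )
    d_ref = problem.target_objective.dose_gy
    scale = d_ref / mean_target if d_ref > 0 else 1.0 / mean_target
    return ones * scale


def solve(
    problem: OptimizationProblem,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> OptimizationResult:
    """Minimise the composite objective over weights >= 0 with L-BFGS-B."""
    w0 = _initial_weights(problem)
    trace: List[float] = [objective_value(w0, problem)[0]]

    def fun(w):
        return objective_value(w, problem)

    def callback(wk):
        trace.append(objective_value(wk, problem)[0])

    res = minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * len(w0),
        callback=callback,
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    weights = np.maximum(res.x, 0.0)
    return OptimizationResult(
        weights=weights,
        trace=trace,
        converged=bool(res.success),
        iterations=int(res.nit),
        seed=seed,
        message=str(res.message),
    )


def normalize_plan(
    weights: np.ndarray,
    dose: DoseDistribution,
    target: Structure,
    prescription_gy: float,
) -> Tuple[np.ndarray, DoseDistribution]:
    """Scale weights and dose so the mean target dose equals the prescription."""
    if prescription_gy < 0:
        raise ValueError("prescription must be non-negative")
    mean_target = float(dose.values[target.mask].mean())
    if mean_target <= 0:
        raise ValueError("cannot normalise: mean target dose is zero")
    s = prescription_gy / mean_target
    return np.asarray(weights) * s, DoseDistribution(dose.values * s, dose.grid)
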
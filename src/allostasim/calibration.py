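"""Calibration harness for the free constants of the reference ledger.

The constants printed in the study set-up (refractory interval, horizon,
availability day, ensemble size, schedules, stage linkage) are locked; the
remaining constants are tunable.  :func:`calibrate` runs a coordinate-descent
grid search that minimizes the maximum relative miss over a list of endpoint
targets, evaluated on reduced-replicate ensembles with fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import run_ensemble
from .params import ModelParameters
from .presets import preset

__all__ = ["CalibrationTarget", "CalibrationReport", "calibrate"]

#: ledger keys that calibration must never touch (main-text values)
LOCKED_KEYS = frozenset(
    {
        "refractory_min",
        "horizon_days",
        "availability_start_day",
        "n_runs",
        "learning_stage_cap",
        "alpha_intakes",
    }
)

DEFAULT_TOLERANCES = {
    "endpoint_intakes_per_day": 0.25,   # relative
    "endpoint_abstinence_pct": 5.0,     # absolute percentage points
}


@dataclass(frozen=True)
class CalibrationTarget:
    """One printed endpoint to reproduce."""

    case_study: int
    evaluation: int
    quantity: str                      # endpoint_intakes_per_day | endpoint_abstinence_pct
    target: float
    tolerance: float | None = None     # relative (intakes) or pp (abstinence)

    def resolved_tolerance(self) -> float:
        if self.tolerance is not None:
            return self.tolerance
        return DEFAULT_TOLERANCES[self.quantity]

    def miss(self, value: float) -> float:
        """Miss in units of the tolerance (<= 1 means within tolerance)."""
        tol = self.resolved_tolerance()
        if self.quantity == "endpoint_abstinence_pct":
            return abs(value - self.target) / tol
        denom = max(abs(self.target), 1e-9)
        return abs(value - self.target) / denom / tol


@dataclass
class CalibrationReport:
    params: ModelParameters
    misses: dict
    evaluations_used: int
    converged: bool

    def worst_miss(self) -> float:
        return max(self.misses.values(), default=0.0)


def _evaluate(
    params: ModelParameters,
    targets: list[CalibrationTarget],
    n_runs: int,
    base_seed: int,
) -> dict:
    misses = {}
    cache: dict[tuple[int, int], object] = {}
    for target in targets:
        key = (target.case_study, target.evaluation)
        if key not in cache:
            _, schedule, mode = preset(*key, params=params)
            cache[key] = run_ensemble(params, schedule, mode, n_runs=n_runs, base_seed=base_seed)
        ensemble = cache[key]
        value = getattr(ensemble, target.quantity)()
        misses[(key, target.quantity)] = target.miss(value)
    return misses


def calibrate(
    params: ModelParameters,
    free_params: dict[str, list[float]],
    targets: list[CalibrationTarget],
    budget: int = 50,
    n_runs: int = 20,
    base_seed: int = 0,
) -> CalibrationReport:
    """Coordinate-descent grid search over ``free_params`` candidate values.

    Minimizes the maximum tolerance-normalized target miss; returns the best
    ledger found plus a per-target miss report.  Raises ValueError if a free
    parameter is locked; returns the input unchanged for already-met or empty
    targets.
    """
    locked = LOCKED_KEYS & set(free_params)
    if locked:
        raise ValueError(f"cannot calibrate locked parameters: {sorted(locked)}")

    misses = _evaluate(params, targets, n_runs, base_seed) if targets else {}
    best = params
    best_loss = max(misses.values(), default=0.0)
    evaluations = 1 if targets else 0
    if not targets or best_loss <= 1.0:
        return CalibrationReport(best, misses, evaluations, converged=True)

    improved = True
    while improved and evaluations < budget:
        improved = False
        for key, candidates in free_params.items():
            for value in candidates:
                if evaluations >= budget:
                    break
                if value == getattr(best, key):
                    continue
                trial = best.replace(**{key: value})
                trial_misses = _evaluate(trial, targets, n_runs, base_seed)
                evaluations += 1
                loss = max(trial_misses.values())
                if loss < best_loss:
                    best, best_loss, misses = trial, loss, trial_misses
                    improved = True
                if best_loss <= 1.0:
                    return CalibrationReport(best, misses, evaluations, converged=True)
    return CalibrationReport(best, misses, evaluations, converged=best_loss <= 1.0)
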
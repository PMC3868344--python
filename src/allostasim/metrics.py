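"""Summary metrics: abstinence index, dependence staging, sweeps, slopes."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .params import EvaluationMode, ModelParameters, Schedule

__all__ = [
    "abstinence_index",
    "difranza_stage",
    "DIFRANZA_STAGE_RATES",
    "DIFRANZA_STAGE_BOUNDARIES",
    "mood_slope",
    "probability_sweep",
]

# Clinical staging of nicotine dependence: mean consumption rates
# (cigarettes per smoking day) for stages none / wanting / craving / needing.
DIFRANZA_STAGE_RATES = (2.2, 4.4, 8.6, 13.2)
# nearest-stage assignment via midpoints between consecutive stage means,
# rounded to the printed precision so a rate exactly on a midpoint rounds up
DIFRANZA_STAGE_BOUNDARIES = tuple(
    round((a + b) / 2.0, 1)
    for a, b in zip(DIFRANZA_STAGE_RATES, DIFRANZA_STAGE_RATES[1:])
)  # (3.3, 6.5, 10.9)


def abstinence_index(daily_intakes: np.ndarray) -> np.ndarray:
    """Percentage of runs with no intake, per day.

    ``daily_intakes`` has shape (n_runs, n_days); returns shape (n_days,).
    """
    daily = np.atleast_2d(daily_intakes)
    return 100.0 * (daily == 0).mean(axis=0)


def difranza_stage(mean_intakes_per_day):
    """Dependence stage 1-4 by nearest stage mean (midpoint boundaries,
    ties rounding up to the later stage).  Accepts scalars or arrays."""
    rate = np.asarray(mean_intakes_per_day, dtype=float)
    if (rate < 0).any():
        raise ValueError("mean_intakes_per_day must be nonnegative")
    stage = np.digitize(rate, DIFRANZA_STAGE_BOUNDARIES) + 1
    if stage.ndim == 0:
        return int(stage)
    return stage


def mood_slope(daily_mood_mean: np.ndarray, day_range: tuple[int, int]) -> float:
    """Least-squares slope (mood units/day) of an ensemble-mean daily mood
    series over ``day_range`` = (start_day, end_day), end exclusive."""
    start, end = day_range
    segment = np.asarray(daily_mood_mean)[start:end]
    days = np.arange(start, end)
    return float(np.polyfit(days, segment, 1)[0])


def probability_sweep(
    params: ModelParameters,
    schedule: Schedule,
    mode: EvaluationMode,
    grid: dict[str, list],
    n_runs: int | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Endpoint summaries over a grid of weight-dynamics probabilities.

    ``grid`` maps parameter names (e.g. ``p_learn_per_hour``,
    ``p_heal_per_hour``, ``p_persist``) to value lists; one ensemble is run
    per grid point with shared seeds, and one endpoint row returned per
    point.
    """
    from .engine import run_ensemble

    keys = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, values))
        ensemble = run_ensemble(
            params.replace(**point), schedule, mode, n_runs=n_runs, base_seed=base_seed
        )
        row = dict(point)
        row["endpoint_intakes_per_day"] = ensemble.endpoint_intakes_per_day()
        row["endpoint_abstinence_pct"] = ensemble.endpoint_abstinence_pct()
        row["endpoint_stage"] = ensemble.endpoint_stage()
        rows.append(row)
    return pd.DataFrame(rows)
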
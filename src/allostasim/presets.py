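"""Case-study presets: the shared tobacco experimental set-up.

All presets share one parameter ledger (160-day horizon, drug available from
day 5, 100-run ensembles, 30-min refractory) and differ only in the healing
schedule and the evaluation mode:

* Case 1 -- escalation baseline, no healing interventions;
* Case 2 -- replacement-therapy emulation: two 120-h healing windows starting
  at hours 1920 and 2280 (10 days of active H in total);
* Case 3 -- meditation-like emulation: eight 15-h healing windows starting at
  hours 1920, 1960, 2000, 2040, 2280, 2320, 2360, 2400 (5 days in total).

Evaluations 1/2/3 map to both-dynamic / T_S-constant / T_0-constant modes.
"""

from __future__ import annotations

from .params import (
    HOURS_PER_DAY,
    EvaluationMode,
    ModelParameters,
    ParameterError,
    Schedule,
    reference_parameters,
)

__all__ = ["preset", "CASE2_HEALING_STARTS", "CASE3_HEALING_STARTS"]

CASE2_HEALING_STARTS = (1920, 2280)
CASE2_HEALING_DURATION_H = 120
CASE3_HEALING_STARTS = (1920, 1960, 2000, 2040, 2280, 2320, 2360, 2400)
CASE3_HEALING_DURATION_H = 15


def _healing_windows(case_study: int) -> list[tuple[int, int]]:
    if case_study == 1:
        return []
    if case_study == 2:
        return [(s, s + CASE2_HEALING_DURATION_H) for s in CASE2_HEALING_STARTS]
    return [(s, s + CASE3_HEALING_DURATION_H) for s in CASE3_HEALING_STARTS]


def preset(
    case_study: int,
    evaluation: int,
    params: ModelParameters | None = None,
) -> tuple[ModelParameters, Schedule, EvaluationMode]:
    """Return (parameters, schedule, mode) for a case study and evaluation.

    ``params`` overrides the packaged reference calibration (the schedule and
    mode are never affected by it, keeping the three case studies on the same
    experimental set-up).
    """
    if case_study not in (1, 2, 3):
        raise ParameterError(f"case_study must be 1, 2 or 3, got {case_study!r}")
    mode = EvaluationMode.from_evaluation_index(evaluation)
    params = reference_parameters() if params is None else params
    # "available on the fifth day": days are 1-indexed, so day 5 starts after
    # four full drug-free days.
    availability_start_h = (params.availability_start_day - 1) * HOURS_PER_DAY
    schedule = Schedule(
        availability_windows=[(availability_start_h, params.horizon_hours)],
        healing_windows=_healing_windows(case_study),
        trigger_events=[],
    )
    return params, schedule, mode
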
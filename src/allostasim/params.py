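"""Parameter ledger, schedules, and evaluation modes.

Single source of truth for every constant of the simulator: pharmacokinetic
and pharmacodynamic constants, the within-system (reward set point) and
between-system (baseline reward threshold) adaptation rates, cognitive weight
dynamics, neuropsychological drift rates, healing-intervention probabilities,
mood-pulse shape, and the experimental set-up (horizon, availability, runs).

Parameters load from / save to a flat YAML mapping so that the whole ledger
is auditable at a glance; time units are spelled out in key names
(``*_per_hour``, ``*_per_min``, ``*_h``, ``*_min``, ``*_day``).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ModelParameters",
    "Schedule",
    "EvaluationMode",
    "ParameterError",
    "load_parameters",
    "save_parameters",
    "load_schedule",
    "save_schedule",
    "reference_parameters",
]

MINUTES_PER_HOUR = 60
HOURS_PER_DAY = 24
MINUTES_PER_DAY = MINUTES_PER_HOUR * HOURS_PER_DAY

TRIGGER_KINDS = ("AS", "AP", "AD", "AQ")


class ParameterError(ValueError):
    """A parameter or schedule constraint violation, naming the offending key."""


class EvaluationMode(enum.Enum):
    """Which reward adaptations are live in a run.

    ``both_dynamic``  -- set point T_S and baseline threshold T_0 both evolve;
    ``ts_constant``   -- T_S frozen at its initial value (between-system only);
    ``t0_constant``   -- T_0 frozen at its initial value (within-system only).
    """

    BOTH_DYNAMIC = "both_dynamic"
    TS_CONSTANT = "ts_constant"
    T0_CONSTANT = "t0_constant"

    @classmethod
    def from_evaluation_index(cls, evaluation: int) -> "EvaluationMode":
        mapping = {1: cls.BOTH_DYNAMIC, 2: cls.TS_CONSTANT, 3: cls.T0_CONSTANT}
        if evaluation not in mapping:
            raise ParameterError(f"evaluation index must be 1, 2 or 3, got {evaluation!r}")
        return mapping[evaluation]


@dataclass
class ModelParameters:
    """The complete constant ledger of the model.

    Field defaults constitute the packaged reference calibration: main-text
    values (refractory interval, horizon, availability day, ensemble size,
    DiFranza stage linkage) are fixed; the remaining constants are the
    package's reference calibration tuned so the shipped presets reproduce
    the documented case-study endpoints.  Units are arbitrary ("model units")
    except where a key name states a time unit.
    """

    # --- pharmacokinetics (minute scale) ------------------------------------
    pk_volume: float = 1.0                 # apparent volume of distribution [L, model units]
    pk_elimination_per_min: float = 0.005776  # first-order elimination rate (t1/2 ~ 2 h)
    dose_unit: float = 1.0                 # drug amount absorbed per intake
    refractory_min: int = 30               # minimum spacing of consecutive intakes [min]

    # --- pharmacodynamics ----------------------------------------------------
    t50: float = 5.0                       # drug potency index (half-effect concentration)
    t0_init: float = 5.0                   # initial baseline reward threshold T_0(0)
    ts_init: float = 4.5                   # initial reward set point T_S(0)

    # --- within-system adaptation, reward set point T_S (hour scale) ---------
    lambda_ts: float = 8.0                 # asymptotic recovery gain per healthy stretch
    beta_ts_per_hour: float = 0.015         # recovery rate of T_S
    gamma_ts_per_hour: float = 0.001       # decay rate of T_S under maladaptive behavior

    # --- between-system adaptation, baseline threshold T_0 (hour scale) ------
    delta_t0: float = 0.0045               # step size of T_0 drift per hour
    alpha_intakes: int = 20                # cumulative-intake gate (craving stage)

    # --- mood (minute scale) --------------------------------------------------
    gamma_m: float = 5.0                   # temporal-difference gain in cognitive distortion
    rc_amplitude: float = 1.0              # rush/comedown pulse amplitude
    rc_period_min: float = 30.0            # one full sinusoid period [min]
    rc_tail_rate_per_min: float = 0.05     # exponential damping of the pulse tail

    # --- behavioral scale -----------------------------------------------------
    compulsion_const: float = 1.0          # constant compulsion drive
    inhibition_const: float = 1.0          # constant inhibition drive

    # --- cognitive scale ------------------------------------------------------
    rd_baseline: float = -0.08             # rationality density of the drug-naive subject
    cs_scale: float = 0.3                  # sigmoid scale mapping rd -> cs in [0, 1]
    omega_q: float = 0.55                  # constant weight on cue magnitude Q
    omega_a: float = 0.5                   # constant weight on external triggers
    omega_h: float = 3.0                   # constant weight on an active healing signal
    omega_s_init: float = 0.6              # initial weight on stress S
    omega_p_init: float = 0.75              # initial weight on health worry P
    omega_d_init: float = 0.45              # initial weight on craving D
    omega_min: float = 0.0                 # lower bound of time-varying weights
    omega_max: float = 1.0                 # upper bound of time-varying weights
    weight_step: float = 0.05              # size of one stochastic weight adjustment
    p_learn_per_hour: float = 0.0065        # P(maladaptive step) per hour with recent pairing
    learning_pair_window_h: int = 3       # trailing window defining "recent pairing" [h]
    p_heal_per_hour: float = 0.3          # P(healthy step) per hour while H = 1
    p_persist: float = 0.13                # P(healing displacement locks in) per window offset
    heal_relax_per_hour: float = 0.005      # decay of non-persisted healing displacement
    learning_stage_cap: int = 4            # DiFranza stage at which associative learning stops

    # --- neuropsychological scale (hour scale, all processes in [0, 1]) ------
    s_rise_per_hour: float = 0.028         # stress growth rate during withdrawal
    s_relax_per_hour: float = 0.02         # stress relaxation rate otherwise
    withdrawal_onset_h: int = 12            # abstinence hours before withdrawal starts
    withdrawal_end_h: int = 720            # abstinence hours after which withdrawal abates
    p_rise_per_intake: float = 0.005        # health-worry growth per intake
    p_relax_per_hour: float = 0.0          # health-worry relaxation (worry is near-permanent)
    d_rise_per_intake: float = 0.02        # craving growth per intake
    d_relax_per_hour: float = 0.02         # craving decay during protracted abstinence
    d_floor_frac: float = 0.35             # cue-conditioned craving floor (fraction of Q)
    d_abstinence_onset_h: int = 2         # abstinence hours before craving starts decaying
    q_rise_per_intake: float = 0.00065        # cue-memory growth per intake
    q_relax_per_hour: float = 0.0          # cue memory persists

    # --- external trigger default magnitudes ---------------------------------
    trigger_as_magnitude: float = 0.3
    trigger_ap_magnitude: float = 0.3
    trigger_ad_magnitude: float = 0.3
    trigger_aq_magnitude: float = 0.3

    # --- experimental set-up --------------------------------------------------
    horizon_days: int = 160                # simulated horizon
    availability_start_day: int = 5        # drug becomes available on this day
    n_runs: int = 100                      # default ensemble size

    # ------------------------------------------------------------------ utils
    @property
    def horizon_hours(self) -> int:
        return self.horizon_days * HOURS_PER_DAY

    @property
    def horizon_minutes(self) -> int:
        return self.horizon_days * MINUTES_PER_DAY

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, values: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        params = cls(**values)
        params.validate()
        return params

    def replace(self, **changes) -> "ModelParameters":
        params = dataclasses.replace(self, **changes)
        params.validate()
        return params

    def validate(self) -> None:
        """Check every ledger constraint; raise ParameterError naming the key."""
        strictly_positive = [
            "pk_volume", "pk_elimination_per_min", "dose_unit", "t50",
            "lambda_ts", "beta_ts_per_hour", "gamma_ts_per_hour", "delta_t0",
            "rc_amplitude", "rc_period_min", "rc_tail_rate_per_min",
            "compulsion_const", "inhibition_const", "cs_scale", "weight_step",
            "horizon_days", "availability_start_day", "n_runs",
        ]
        nonnegative = [
            "t0_init", "ts_init", "heal_relax_per_hour",
            "s_rise_per_hour", "s_relax_per_hour", "p_rise_per_intake",
            "p_relax_per_hour", "d_rise_per_intake", "d_relax_per_hour",
            "q_rise_per_intake", "q_relax_per_hour",
            "trigger_as_magnitude", "trigger_ap_magnitude",
            "trigger_ad_magnitude", "trigger_aq_magnitude",
            "withdrawal_onset_h", "withdrawal_end_h", "d_abstinence_onset_h",
            "learning_pair_window_h",
        ]
        probabilities = ["p_learn_per_hour", "p_heal_per_hour", "p_persist", "d_floor_frac"]

        for key in strictly_positive:
            value = getattr(self, key)
            if not value > 0:
                raise ParameterError(f"{key} must be > 0, got {value!r}")
        for key in nonnegative:
            value = getattr(self, key)
            if value < 0:
                raise ParameterError(f"{key} must be >= 0, got {value!r}")
        for key in probabilities:
            value = getattr(self, key)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{key} must lie in [0, 1], got {value!r}")
        if self.refractory_min < 1:
            raise ParameterError(f"refractory_min must be >= 1, got {self.refractory_min!r}")
        if self.alpha_intakes < 1:
            raise ParameterError(f"alpha_intakes must be >= 1, got {self.alpha_intakes!r}")
        if not self.omega_min < self.omega_max:
            raise ParameterError(
                f"omega bounds must be a nonempty interval, got "
                f"[{self.omega_min!r}, {self.omega_max!r}]"
            )
        for key in ("omega_s_init", "omega_p_init", "omega_d_init"):
            value = getattr(self, key)
            if not self.omega_min <= value <= self.omega_max:
                raise ParameterError(
                    f"{key} must lie within omega bounds "
                    f"[{self.omega_min}, {self.omega_max}], got {value!r}"
                )
        if self.learning_stage_cap not in (1, 2, 3, 4):
            raise ParameterError(
                f"learning_stage_cap must be a DiFranza stage 1-4, got "
                f"{self.learning_stage_cap!r}"
            )
        if self.withdrawal_end_h < self.withdrawal_onset_h:
            raise ParameterError(
                "withdrawal_end_h must be >= withdrawal_onset_h, got "
                f"{self.withdrawal_end_h!r} < {self.withdrawal_onset_h!r}"
            )
        if self.availability_start_day > self.horizon_days:
            raise ParameterError(
                "availability_start_day exceeds horizon_days: "
                f"{self.availability_start_day!r} > {self.horizon_days!r}"
            )


def _check_windows(windows: Sequence[Sequence[float]], kind: str) -> list[tuple[int, int]]:
    cleaned: list[tuple[int, int]] = []
    for window in windows:
        if len(window) != 2:
            raise ParameterError(f"{kind} window must be [start_hour, end_hour), got {window!r}")
        start, end = window
        if not float(start).is_integer() or not float(end).is_integer():
            raise ParameterError(f"{kind} window bounds must be whole hours, got {window!r}")
        start, end = int(start), int(end)
        if start >= end:
            raise ParameterError(f"{kind} window must have start < end, got {window!r}")
        if start < 0:
            raise ParameterError(f"{kind} window start must be >= 0, got {window!r}")
        cleaned.append((start, end))
    cleaned.sort()
    for (s0, e0), (s1, _e1) in zip(cleaned, cleaned[1:]):
        if s1 < e0:
            raise ParameterError(f"{kind} windows overlap: [{s0}, {e0}) and starting {s1}")
    return cleaned


@dataclass
class Schedule:
    """Drug availability windows, healing windows, and trigger events (hours).

    ``availability_windows`` and ``healing_windows`` are half-open
    ``[start_hour, end_hour)`` intervals; ``trigger_events`` is a list of
    ``(hour, kind, magnitude)`` with kind one of AS, AP, AD, AQ.
    """

    availability_windows: list[tuple[int, int]] = field(default_factory=list)
    healing_windows: list[tuple[int, int]] = field(default_factory=list)
    trigger_events: list[tuple[int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.availability_windows = _check_windows(self.availability_windows, "availability")
        self.healing_windows = _check_windows(self.healing_windows, "healing")
        cleaned = []
        for event in self.trigger_events:
            if len(event) != 3:
                raise ParameterError(f"trigger event must be (hour, kind, magnitude), got {event!r}")
            hour, kind, magnitude = event
            if kind not in TRIGGER_KINDS:
                raise ParameterError(f"trigger kind must be one of {TRIGGER_KINDS}, got {kind!r}")
            if int(hour) != hour or hour < 0:
                raise ParameterError(f"trigger hour must be a nonnegative whole hour, got {hour!r}")
            cleaned.append((int(hour), str(kind), float(magnitude)))
        self.trigger_events = sorted(cleaned)

    def healing_active_hours(self) -> int:
        return sum(end - start for start, end in self.healing_windows)

    def to_dict(self) -> dict:
        return {
            "availability_windows": [list(w) for w in self.availability_windows],
            "healing_windows": [list(w) for w in self.healing_windows],
            "trigger_events": [list(e) for e in self.trigger_events],
        }

    @classmethod
    def from_dict(cls, values: dict) -> "Schedule":
        known = {"availability_windows", "healing_windows", "trigger_events"}
        unknown = set(values) - known
        if unknown:
            raise ParameterError(f"unknown schedule keys: {sorted(unknown)}")
        return cls(
            availability_windows=[tuple(w) for w in values.get("availability_windows", [])],
            healing_windows=[tuple(w) for w in values.get("healing_windows", [])],
            trigger_events=[tuple(e) for e in values.get("trigger_events", [])],
        )


# --------------------------------------------------------------------- file IO

def _load_yaml_mapping(path: str | Path) -> dict:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ParameterError(f"cannot read {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParameterError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError(f"{path} must contain a flat key/value mapping")
    return raw


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter ledger from a flat YAML file.

    Missing keys fall back to the packaged reference calibration; unknown keys
    and constraint violations raise :class:`ParameterError` naming the key.
    """
    return ModelParameters.from_dict(_load_yaml_mapping(path))


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=True, default_flow_style=False)
    )


def load_schedule(path: str | Path) -> Schedule:
    return Schedule.from_dict(_load_yaml_mapping(path))


def save_schedule(schedule: Schedule, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(schedule.to_dict(), sort_keys=True))


def reference_parameters() -> ModelParameters:
    """The packaged reference calibration (see ``data/reference_params.yaml``)."""
    with resources.as_file(
        resources.files("allostasim").joinpath("data/reference_params.yaml")
    ) as path:
        return load_parameters(path)
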
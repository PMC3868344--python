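"""Dual-clock orchestration: single runs and seeded Monte-Carlo ensembles.

One run iterates minutes 0 .. horizon-1.  At every hour boundary the hourly
cascade executes in a fixed order: neuropsychological update -> healing
bookkeeping (window-offset persistence draws) -> stochastic weight update ->
rationality density -> cognitive state -> behavioral tendency G (with
sign-change detection) -> reward set point -> baseline threshold -> delta-TSO
roll.  Within each hour, every minute performs: PK decay -> effect ->
intake decision -> bolus.  Mood (rush/comedown + cognitive distortion) does
not feed back into the dynamics and is assembled after the loop.

The implementation is vectorized across runs: all per-run state lives in
arrays of shape (n_runs,), and each run consumes its own pre-drawn random
stream (seed = base_seed + run index), so a run simulated alone is
bit-identical to the same run inside an ensemble.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cognition, healing, mood, neuroadaptation, pkpd
from .params import (
    HOURS_PER_DAY,
    MINUTES_PER_DAY,
    MINUTES_PER_HOUR,
    EvaluationMode,
    ModelParameters,
    Schedule,
)

__all__ = ["RunResult", "EnsembleResult", "run_simulation", "run_ensemble"]

HOURLY_COLUMNS = (
    "TS", "T0", "omega_s", "omega_p", "omega_d",
    "rd", "cs", "G", "S", "P", "D", "Q", "H", "delta_tso",
)


def _config_digest(params: ModelParameters, schedule: Schedule, mode: EvaluationMode) -> str:
    blob = yaml.safe_dump(
        {"params": params.to_dict(), "schedule": schedule.to_dict(), "mode": mode.value},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """Traces and aggregates of one seeded run."""

    seed: int
    config_digest: str
    minute: dict = field(repr=False)      # t_min, C, T, Z, rc, cd, M
    hourly: dict = field(repr=False)      # t_star + HOURLY_COLUMNS
    daily_intakes: np.ndarray = field(repr=False)

    @property
    def total_intakes(self) -> int:
        return int(self.daily_intakes.sum())

    def minute_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.minute)

    def hourly_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hourly)


@dataclass
class EnsembleResult:
    """Stacked seeded runs with means, 95% simulation envelopes and metrics."""

    n_runs: int
    seeds: np.ndarray
    config_digest: str
    daily_intakes: np.ndarray             # (n_runs, n_days)
    daily_mood: np.ndarray                # (n_runs, n_days) daily-mean mood
    daily_mood_spread: np.ndarray         # (n_runs, n_days) intraday mood std
    abstinence_index: np.ndarray          # (n_days,) percent of abstinent runs
    hourly_mean: pd.DataFrame             # mean hourly series
    hourly_low: pd.DataFrame              # 2.5th percentile envelope
    hourly_high: pd.DataFrame             # 97.5th percentile envelope
    minute_stride: int
    minute_mean: pd.DataFrame             # downsampled minute series (C, T, M)
    minute_low: pd.DataFrame
    minute_high: pd.DataFrame
    endpoint_window_days: int = 7

    @property
    def n_days(self) -> int:
        return self.daily_intakes.shape[1]

    def endpoint_intakes_per_day(self) -> float:
        """Ensemble-mean intakes/day over the final endpoint window."""
        w = self.endpoint_window_days
        return float(self.daily_intakes[:, -w:].mean())

    def endpoint_abstinence_pct(self) -> float:
        """Mean daily abstinence index (%) over the final endpoint window."""
        w = self.endpoint_window_days
        return float(self.abstinence_index[-w:].mean())

    def endpoint_stage(self) -> int:
        from .metrics import difranza_stage

        return difranza_stage(self.endpoint_intakes_per_day())

    def mean_daily_mood(self) -> np.ndarray:
        return self.daily_mood.mean(axis=0)

    def summary(self) -> pd.DataFrame:
        """Endpoint summary table (single row)."""
        return pd.DataFrame(
            {
                "n_runs": [self.n_runs],
                "endpoint_intakes_per_day": [self.endpoint_intakes_per_day()],
                "endpoint_abstinence_pct": [self.endpoint_abstinence_pct()],
                "endpoint_stage": [self.endpoint_stage()],
                "total_intakes_mean": [float(self.daily_intakes.sum(axis=1).mean())],
                "config_digest": [self.config_digest],
            }
        )


# ----------------------------------------------------------------- internals

def _availability_by_minute(schedule: Schedule, n_minutes: int) -> np.ndarray:
    avail = np.zeros(n_minutes, dtype=bool)
    for start_h, end_h in schedule.availability_windows:
        avail[start_h * MINUTES_PER_HOUR: end_h * MINUTES_PER_HOUR] = True
    return avail


def _trigger_arrays(schedule: Schedule, n_hours: int) -> dict[str, np.ndarray]:
    arrays = {kind: np.zeros(n_hours) for kind in ("AS", "AP", "AD", "AQ")}
    for hour, kind, magnitude in schedule.trigger_events:
        if hour < n_hours:
            arrays[kind][hour] += magnitude
    return arrays


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))
        run, t = (int(bad[0][0]), int(bad[0][1])) if arr.ndim == 2 else (0, int(bad[0][0]))
        raise FloatingPointError(
            f"non-finite value in {name} at run {run}, time index {t}"
        )


def _simulate(
    params: ModelParameters,
    schedule: Schedule,
    mode: EvaluationMode,
    seeds: np.ndarray,
) -> dict:
    """Vectorized simulation of len(seeds) runs; returns raw trace arrays."""
    params.validate()
    if not isinstance(mode, EvaluationMode):
        raise ValueError(f"invalid evaluation mode: {mode!r}")
    frozen_ts = mode is EvaluationMode.TS_CONSTANT
    frozen_t0 = mode is EvaluationMode.T0_CONSTANT

    n_runs = len(seeds)
    n_min = params.horizon_minutes
    n_h = params.horizon_hours
    n_days = params.horizon_days

    avail_min = _availability_by_minute(schedule, n_min)
    h_hour = healing.hourly_healing_signal(schedule, n_h)
    triggers = _trigger_arrays(schedule, n_h)
    offset_hours = np.flatnonzero(np.diff(h_hour.astype(np.int8)) == -1) + 1
    offset_index = {int(h): i for i, h in enumerate(offset_hours)}
    n_offsets = max(len(offset_hours), 1)

    # per-run random streams, pre-drawn so ensemble composition cannot matter
    u_weights = np.empty((n_runs, n_h, 3))
    u_persist = np.empty((n_runs, n_offsets, 3))
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(int(seed))
        u_weights[i] = rng.random((n_h, 3))
        u_persist[i] = rng.random((n_offsets, 3))

    # ---- state ----
    shape = (n_runs,)
    concentration = np.zeros(shape)
    last_intake = np.full(shape, -(10 ** 9), dtype=np.int64)
    cum_intakes = np.zeros(shape, dtype=np.int64)
    ts = np.full(shape, params.ts_init)
    t0 = np.full(shape, params.t0_init)
    ts_at_tc = ts.copy()
    d_counter = np.zeros(shape, dtype=np.int64)
    dtso_prev = ts - t0
    s = np.zeros(shape)
    p = np.zeros(shape)
    dproc = np.zeros(shape)
    q = np.zeros(shape)
    base = (
        np.full(shape, params.omega_s_init),
        np.full(shape, params.omega_p_init),
        np.full(shape, params.omega_d_init),
    )
    pending = (np.zeros(shape), np.zeros(shape), np.zeros(shape))
    learning_active = np.ones(shape, dtype=bool)

    # initial behavioral state (hour -1), defines sign_prev
    w_eff = cognition.effective_weights(base, pending, params)
    rd = cognition.rationality_density(
        s, p, dproc, q, *w_eff, healing_active=False, params=params
    )
    g = cognition.drug_seeking_tendency(cognition.cognitive_state(rd, params), params)
    sign_prev = g >= 0.0

    # ---- trace storage ----
    z_tr = np.zeros((n_runs, n_min), dtype=np.uint8)
    c_tr = np.empty((n_runs, n_min), dtype=np.float32)
    hourly = {name: np.empty((n_runs, n_h), dtype=np.float32) for name in HOURLY_COLUMNS}
    dtso_diff = np.empty((n_runs, n_h), dtype=np.float32)
    cum_by_hour = np.zeros((n_runs, n_h + 1), dtype=np.int64)

    pk_decay = np.exp(-params.pk_elimination_per_min)
    bolus = params.dose_unit / params.pk_volume
    pair_window = params.learning_pair_window_h
    stage_window_h = 7 * HOURS_PER_DAY

    from .metrics import difranza_stage  # local import to avoid a cycle

    for t_star in range(n_h):
        # -- hourly cascade ------------------------------------------------
        cum_by_hour[:, t_star] = cum_intakes
        intakes_last_hour = (
            cum_by_hour[:, t_star] - cum_by_hour[:, t_star - 1]
            if t_star >= 1
            else np.zeros(shape, dtype=np.int64)
        )
        t_min0 = t_star * MINUTES_PER_HOUR
        abstinent_h = np.minimum((t_min0 - last_intake) / 60.0, 1e9)
        dependent = cum_intakes >= params.alpha_intakes

        s, p, dproc, q = cognition.update_neuropsych(
            s, p, dproc, q,
            intakes_last_hour, abstinent_h, dependent,
            trigger_as=triggers["AS"][t_star],
            trigger_ap=triggers["AP"][t_star],
            trigger_ad=triggers["AD"][t_star],
            trigger_aq=triggers["AQ"][t_star],
            params=params,
        )

        lookback = max(t_star - stage_window_h, 0)
        trailing_rate = (cum_intakes - cum_by_hour[:, lookback]) / 7.0
        stage = difranza_stage(trailing_rate)
        learning_active &= stage < params.learning_stage_cap

        h_now = bool(h_hour[t_star])
        if t_star in offset_index:  # H just turned idle: persistence draws
            idx = offset_index[t_star]
            base, pending = healing.resolve_window_offset(
                base, pending, u_persist[:, idx, :].T, params
            )

        recent = cum_intakes - cum_by_hour[:, max(t_star - pair_window, 0)]
        eligible = learning_active & (recent > 0)
        base, pending = cognition.update_weights(
            base, pending, eligible, h_now, u_weights[:, t_star, :].T, params
        )
        w_eff = cognition.effective_weights(base, pending, params)

        rd = cognition.rationality_density(
            s, p, dproc, q, *w_eff,
            healing_active=h_now,
            trigger_as=triggers["AS"][t_star],
            trigger_ap=triggers["AP"][t_star],
            trigger_ad=triggers["AD"][t_star],
            trigger_aq=triggers["AQ"][t_star],
            params=params,
        )
        cs = cognition.cognitive_state(rd, params)
        g = cognition.drug_seeking_tendency(cs, params)

        sign_now = g >= 0.0
        changed = sign_now != sign_prev
        d_counter = np.where(changed, 0, d_counter + 1)
        ts_at_tc = np.where(changed, ts, ts_at_tc)
        if not frozen_ts:
            ts = neuroadaptation.update_reward_set_point(
                ts_at_tc, d_counter, g, cum_intakes, ts, params
            )
        sign_prev = sign_now

        if not frozen_t0:
            t0 = neuroadaptation.update_baseline_threshold(
                t0, *w_eff, h_now, cum_intakes, params
            )

        dtso_now, dtso_before = neuroadaptation.delta_tso(ts, t0, dtso_prev)
        dtso_diff[:, t_star] = dtso_now - dtso_before
        dtso_prev = dtso_now

        hourly["TS"][:, t_star] = ts
        hourly["T0"][:, t_star] = t0
        hourly["omega_s"][:, t_star] = w_eff[0]
        hourly["omega_p"][:, t_star] = w_eff[1]
        hourly["omega_d"][:, t_star] = w_eff[2]
        hourly["rd"][:, t_star] = rd
        hourly["cs"][:, t_star] = cs
        hourly["G"][:, t_star] = g
        hourly["S"][:, t_star] = s
        hourly["P"][:, t_star] = p
        hourly["D"][:, t_star] = dproc
        hourly["Q"][:, t_star] = q
        hourly["H"][:, t_star] = h_now
        hourly["delta_tso"][:, t_star] = dtso_now

        # -- minute loop within the hour ----------------------------------
        g_neg = g < 0.0
        gate_level = t0 - ts  # effect must stay below this for an intake
        for m in range(MINUTES_PER_HOUR):
            t = t_min0 + m
            concentration *= pk_decay
            if avail_min[t]:
                effect = t0 * concentration / (concentration + params.t50)
                z = (
                    g_neg
                    & (gate_level - effect > 0.0)
                    & (t - last_intake >= params.refractory_min)
                )
                if z.any():
                    z_tr[:, t] = z
                    concentration += np.where(z, bolus, 0.0)
                    last_intake = np.where(z, t, last_intake)
                    cum_intakes += z
            c_tr[:, t] = concentration

    cum_by_hour[:, n_h] = cum_intakes

    # ---- post-loop assembly (mood does not feed back) ---------------------
    t0_by_min = np.repeat(hourly["T0"], MINUTES_PER_HOUR, axis=1)
    effect_tr = (t0_by_min * c_tr / (c_tr + np.float32(params.t50))).astype(np.float32)
    del t0_by_min

    rc = mood.rc_trace(z_tr, params).astype(np.float32)
    first_intake = np.where(
        z_tr.any(axis=1), np.argmax(z_tr, axis=1), n_min
    )
    has_intake_yet = np.arange(n_min)[np.newaxis, :] >= first_intake[:, np.newaxis]
    # the pulse superposition is exactly zero before the first intake; clear
    # the FFT convolution's roundoff ripple so M == 0 holds identically there
    rc[~has_intake_yet] = 0.0
    diff_by_min = np.repeat(dtso_diff, MINUTES_PER_HOUR, axis=1)
    cd = np.where(
        has_intake_yet,
        -effect_tr + np.float32(params.gamma_m) * diff_by_min,
        np.float32(0.0),
    ).astype(np.float32)
    del diff_by_min, has_intake_yet
    m_tr = rc + cd

    for name in ("TS", "T0", "rd", "cs", "G"):
        _check_finite(name, hourly[name])
    _check_finite("C", c_tr)

    daily_intakes = (
        z_tr.reshape(n_runs, n_days, MINUTES_PER_DAY).sum(axis=2).astype(np.int64)
    )
    m_by_day = m_tr.reshape(n_runs, n_days, MINUTES_PER_DAY)
    daily_mood = m_by_day.mean(axis=2)
    daily_mood_spread = m_by_day.std(axis=2)
    del m_by_day

    return {
        "Z": z_tr,
        "C": c_tr,
        "T": effect_tr,
        "rc": rc,
        "cd": cd,
        "M": m_tr,
        "hourly": hourly,
        "dtso_diff": dtso_diff,
        "daily_intakes": daily_intakes,
        "daily_mood": daily_mood,
        "daily_mood_spread": daily_mood_spread,
    }


# ----------------------------------------------------------------- public API

def run_simulation(
    params: ModelParameters,
    schedule: Schedule,
    mode: EvaluationMode = EvaluationMode.BOTH_DYNAMIC,
    seed: int = 0,
) -> RunResult:
    """Simulate one seeded run and return its full minute/hour traces."""
    raw = _simulate(params, schedule, mode, np.asarray([seed]))
    n_min = params.horizon_minutes
    n_h = params.horizon_hours
    minute = {
        "t_min": np.arange(n_min),
        "C": raw["C"][0],
        "T": raw["T"][0],
        "Z": raw["Z"][0],
        "rc": raw["rc"][0],
        "cd": raw["cd"][0],
        "M": raw["M"][0],
    }
    hourly = {"t_star": np.arange(n_h)}
    hourly.update({name: raw["hourly"][name][0] for name in HOURLY_COLUMNS})
    return RunResult(
        seed=seed,
        config_digest=_config_digest(params, schedule, mode),
        minute=minute,
        hourly=hourly,
        daily_intakes=raw["daily_intakes"][0],
    )


def _envelope_frames(arrays: dict[str, np.ndarray], index: np.ndarray):
    mean = pd.DataFrame({k: v.mean(axis=0) for k, v in arrays.items()}, index=index)
    low = pd.DataFrame(
        {k: np.percentile(v, 2.5, axis=0) for k, v in arrays.items()}, index=index
    )
    high = pd.DataFrame(
        {k: np.percentile(v, 97.5, axis=0) for k, v in arrays.items()}, index=index
    )
    return mean, low, high


def run_ensemble(
    params: ModelParameters,
    schedule: Schedule,
    mode: EvaluationMode = EvaluationMode.BOTH_DYNAMIC,
    n_runs: int | None = None,
    base_seed: int = 0,
    minute_stride: int = 15,
) -> EnsembleResult:
    """Simulate ``n_runs`` independent runs (seeds base_seed + 0..n-1).

    Returns pointwise means and 95% simulation envelopes (empirical 2.5/97.5
    percentiles across runs), the daily abstinence index, and endpoint
    summaries.  Minute-scale envelope series are stored every
    ``minute_stride`` minutes.
    """
    if n_runs is None:
        n_runs = params.n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.asarray(base_seed) + np.arange(n_runs)
    raw = _simulate(params, schedule, mode, seeds)

    from .metrics import abstinence_index

    abstinence = abstinence_index(raw["daily_intakes"])
    hours = np.arange(params.horizon_hours)
    hourly_mean, hourly_low, hourly_high = _envelope_frames(raw["hourly"], hours)

    sl = slice(None, None, minute_stride)
    minutes = np.arange(params.horizon_minutes)[sl]
    minute_arrays = {k: raw[k][:, sl] for k in ("C", "T", "M")}
    minute_mean, minute_low, minute_high = _envelope_frames(minute_arrays, minutes)

    return EnsembleResult(
        n_runs=n_runs,
        seeds=seeds,
        config_digest=_config_digest(params, schedule, mode),
        daily_intakes=raw["daily_intakes"],
        daily_mood=raw["daily_mood"],
        daily_mood_spread=raw["daily_mood_spread"],
        abstinence_index=abstinence,
        hourly_mean=hourly_mean,
        hourly_low=hourly_low,
        hourly_high=hourly_high,
        minute_stride=minute_stride,
        minute_mean=minute_mean,
        minute_low=minute_low,
        minute_high=minute_high,
    )
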
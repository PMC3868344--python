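"""Hour-scale reward-system adaptation: set point T_S and baseline T_0.

Within-system neuroadaptation (reward set point, hourly):

    T_S(t*+1) = lambda * (1 - exp(-beta * d)) + T_S(t_c)   if G >= 0 and sum(Z) >= 1
                T_S(t_c) * exp(-gamma * d)                 if G <  0 and sum(Z) >= 1
                T_S(t*)                                    otherwise

where t_c is the last hour at which G changed sign and d counts hours since
then (reset to 0 on each sign change, which keeps T_S continuous).  Healthy
stretches therefore ratchet the set point upward by as much as ``lambda``
each, while sustained maladaptive behavior lets it decay geometrically.

Between-system neuroadaptation (baseline reward threshold, hourly), active
once the cumulative intake count reaches the craving-stage gate ``alpha``:

    T_0(t*+1) = T_0(t*) + delta_T0 * (-2*H + 1) * (omega_S - omega_P + omega_D)

so the cognitive-weight drift raises T_0 while the subject learns maladaptive
associations and the same weights *lower* it under an active healing signal
(opposite valence) or once healing has turned the weight balance negative.
T_0 is clamped at zero from below.

Functions are pure and accept scalars or aligned numpy arrays; the engine
owns the bookkeeping state (d counter, T_S(t_c), previous delta-TSO).
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters

__all__ = [
    "update_reward_set_point",
    "update_baseline_threshold",
    "delta_tso",
]


def update_reward_set_point(
    ts_at_tc,
    d,
    g,
    cum_intakes,
    ts_current,
    params: ModelParameters,
):
    """Evaluate the reward set point for counter value ``d`` since the last
    sign change of G.  ``ts_current`` is returned unchanged until the first
    intake has occurred."""
    d = np.asarray(d, dtype=float)
    healthy = params.lambda_ts * (1.0 - np.exp(-params.beta_ts_per_hour * d)) + ts_at_tc
    maladaptive = ts_at_tc * np.exp(-params.gamma_ts_per_hour * d)
    branch = np.where(np.asarray(g) >= 0.0, healthy, maladaptive)
    return np.where(np.asarray(cum_intakes) >= 1, branch, ts_current)


def update_baseline_threshold(
    t0,
    omega_s,
    omega_p,
    omega_d,
    healing_active,
    cum_intakes,
    params: ModelParameters,
):
    """One hourly step of the baseline reward threshold (clamped at >= 0)."""
    h = np.asarray(healing_active, dtype=float)
    drift = params.delta_t0 * (-2.0 * h + 1.0) * (omega_s - omega_p + omega_d)
    updated = np.maximum(t0 + drift, 0.0)
    return np.where(np.asarray(cum_intakes) >= params.alpha_intakes, updated, t0)


def delta_tso(ts, t0, previous):
    """Arithmetic difference T_S - T_0 and the value stored the hour before.

    Returns ``(current, previous)``; the caller rolls ``current`` into its
    stored previous value once per hour.
    """
    current = np.asarray(ts, dtype=float) - np.asarray(t0, dtype=float)
    return current, previous
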
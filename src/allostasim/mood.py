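"""Minute-scale mood output: rush/comedown pulses, cognitive distortion, M.

Each intake launches a rush/comedown pulse: one full sinusoid period (a
positive rush half followed by a negative comedown half) that then continues
as a damped sinusoid tail:

    k(u) = A * sin(2*pi*u / P)                         for 0 <= u < P
    k(u) = A * sin(2*pi*u / P) * exp(-r * (u - P))     for u >= P

rc(t) is the sum of k over all pulses started at past intake minutes; since
every pulse shares the kernel, a full-run rc trace is the convolution of the
intake train with k (truncated where the tail falls below 1e-6 * A).

Cognitive distortion combines the drug's current lowering effect with a
temporal-difference term on the set-point-minus-baseline gap, active only
once at least one intake has occurred:

    cd(t) = -T(t) + gamma_M * (dTSO(t*) - dTSO(t*-1))    when sum(Z) >= 1
    cd(t) = 0                                            otherwise

with dTSO = T_S - T_0 evaluated on the hourly grid and held constant within
each hour.  Mood is the plain sum M = rc + cd.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

from .params import ModelParameters

__all__ = [
    "rc_kernel",
    "rush_comedown",
    "rc_trace",
    "cognitive_distortion",
    "mood_value",
]


def rc_kernel(params: ModelParameters) -> np.ndarray:
    """Minute-sampled pulse kernel, truncated once the tail is negligible."""
    period = params.rc_period_min
    rate = params.rc_tail_rate_per_min
    # tail envelope A*exp(-r*(u-P)) < 1e-6*A  =>  u > P + ln(1e6)/r
    n = int(np.ceil(period + np.log(1e6) / rate)) + 1
    u = np.arange(n, dtype=float)
    kernel = params.rc_amplitude * np.sin(2.0 * np.pi * u / period)
    tail = u >= period
    kernel[tail] *= np.exp(-rate * (u[tail] - period))
    return kernel


def rush_comedown(pulse_starts, t, params: ModelParameters) -> float:
    """rc(t) as an explicit sum over pulses started at ``pulse_starts``.

    Reference form used by the tests; the engine uses the equivalent
    convolution in :func:`rc_trace`.
    """
    total = 0.0
    period = params.rc_period_min
    rate = params.rc_tail_rate_per_min
    for start in pulse_starts:
        u = t - start
        if u < 0:
            continue
        value = params.rc_amplitude * np.sin(2.0 * np.pi * u / period)
        if u >= period:
            damping = np.exp(-rate * (u - period))
            if damping < 1e-6:
                continue  # retired pulse
            value *= damping
        total += value
    return float(total)


def rc_trace(z, params: ModelParameters) -> np.ndarray:
    """Convolve the intake train (last axis = minutes) with the pulse kernel."""
    z = np.asarray(z, dtype=float)
    kernel = rc_kernel(params)
    if z.ndim == 1:
        out = _signal.oaconvolve(z, kernel)[: z.shape[0]]
    else:
        out = _signal.oaconvolve(z, kernel[np.newaxis, :], axes=-1)[..., : z.shape[-1]]
    return out


def cognitive_distortion(effect, dtso_current, dtso_previous, cum_intakes, params: ModelParameters):
    """cd = -T + gamma_M * (dTSO - dTSO_prev), gated on at least one intake."""
    cd = -np.asarray(effect, dtype=float) + params.gamma_m * (
        np.asarray(dtso_current, dtype=float) - np.asarray(dtso_previous, dtype=float)
    )
    return np.where(np.asarray(cum_intakes) >= 1, cd, 0.0)


def mood_value(rc, cd):
    """M = rc + cd."""
    return np.asarray(rc, dtype=float) + np.asarray(cd, dtype=float)
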
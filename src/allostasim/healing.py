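"""Healing-intervention semantics: the H signal and residual permanence.

A healing intervention is a binary exogenous signal H(t*) that is 1 exactly
when the hour lies inside a scheduled healing window.  Replacement-therapy
emulation (few long windows) and meditation-like emulation (many short
windows) share this single code path and differ only through the window list.

While H = 1 the signal acts through two channels: an additive
omega_H-weighted term inside the rationality density (immediate abstinence
pressure) and healthy-direction stochastic steps of the time-varying weights
(see :mod:`allostasim.cognition`), which accumulate in a *pending*
displacement.  At each H 1->0 transition (window offset) every weight's
pending displacement is independently made permanent with probability
``p_persist`` -- folded into the weight's base value -- and otherwise keeps
relaxing back toward its pre-window value at ``heal_relax_per_hour``.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters, Schedule

__all__ = ["healing_signal", "hourly_healing_signal", "resolve_window_offset"]


def healing_signal(t_star, schedule: Schedule):
    """Indicator of membership of hour ``t_star`` in any healing window."""
    t = np.asarray(t_star)
    active = np.zeros(t.shape, dtype=bool)
    for start, end in schedule.healing_windows:
        active |= (t >= start) & (t < end)
    if active.ndim == 0:
        return bool(active)
    return active


def hourly_healing_signal(schedule: Schedule, n_hours: int) -> np.ndarray:
    """Precomputed H(t*) for t* = 0 .. n_hours-1."""
    return healing_signal(np.arange(n_hours), schedule)


def resolve_window_offset(base, pending, uniforms, params: ModelParameters):
    """Persistence draw at an H 1->0 transition.

    For each weight j, with probability ``p_persist`` the pending healing
    displacement is locked into the permanent base (pending reset to 0);
    otherwise it is left pending and continues to relax.  ``uniforms``
    supplies one U(0,1) draw per weight.  Returns updated ``(base, pending)``.
    """
    new_base, new_pending = [], []
    for j in range(3):
        b = np.asarray(base[j], dtype=float)
        pend = np.asarray(pending[j], dtype=float)
        lock = np.asarray(uniforms[j]) < params.p_persist
        new_base.append(np.where(lock, b + pend, b))
        new_pending.append(np.where(lock, 0.0, pend))
    return tuple(new_base), tuple(new_pending)
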
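"""Minute-scale pharmacokinetics, pharmacodynamics, and the intake decision.

The PK component is a single brain compartment with first-order elimination
and an instantaneous bolus per intake:

    C(t+1) = C(t) * exp(-k_e) + Z(t) * dose / V

The PD component is a saturating Emax curve scaled by the baseline reward
threshold, with half-effect at the potency index T_50:

    T(t) = T_0 * C / (C + T_50)          (the drug's lowering effect)

The intake decision implements the negative-reinforcement loop: the current
reward threshold is the baseline lowered by the drug effect, T_0 - T, and a
dose is taken exactly when that net threshold exceeds the reward set point
T_S (the subject no longer "feels normal"), provided drug is available, the
behavioral tendency G is maladaptive (G < 0), and the refractory interval
since the previous intake has elapsed.

All functions accept scalars or aligned numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters

__all__ = [
    "step_concentration",
    "lowering_effect",
    "net_reward_threshold",
    "decide_intake",
]


def step_concentration(concentration, intake, params: ModelParameters):
    """One-minute PK update: exponential decay plus an intake bolus."""
    decay = np.exp(-params.pk_elimination_per_min)
    bolus = params.dose_unit / params.pk_volume
    return concentration * decay + np.asarray(intake) * bolus


def lowering_effect(concentration, t0, params: ModelParameters):
    """Drug's lowering effect on reward threshold: T = T_0 * C / (C + T_50).

    Saturating in C with half-effect at the potency index ``t50``; zero with
    no drug on board and bounded above by the baseline threshold ``t0``.
    """
    concentration = np.asarray(concentration, dtype=float)
    return t0 * concentration / (concentration + params.t50)


def net_reward_threshold(effect, t0):
    """Current reward threshold: the baseline lowered by the drug effect."""
    return t0 - effect


def decide_intake(
    effect,
    ts,
    t0,
    g,
    available,
    minutes_since_intake,
    params: ModelParameters,
):
    """Binary intake decision Z for the current minute.

    Z = 1 iff drug is available, the tendency is maladaptive (G < 0), the
    net reward threshold exceeds the set point ((T_0 - T) - T_S > 0, the
    negative hedonic valence that drives self-administration), and at least
    ``refractory_min`` minutes have elapsed since the previous intake.
    ``minutes_since_intake`` may be inf/large for a drug-naive subject.
    """
    valence = net_reward_threshold(effect, t0) - ts
    z = (
        np.asarray(available, dtype=bool)
        & (np.asarray(g) < 0.0)
        & (valence > 0.0)
        & (np.asarray(minutes_since_intake) >= params.refractory_min)
    )
    return z
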
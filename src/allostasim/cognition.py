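"""Hour-scale neuropsychology, stochastic cognitive weights, and behavior.

Neuropsychological processes, each confined to [0, 1]:

* ``S`` stress/anxiety -- grows during withdrawal (dependent subject,
  abstinent beyond an onset lag and before the hump abates), relaxes
  otherwise;
* ``P`` health worry -- accumulates with consumption and is near-permanent;
* ``D`` craving -- grows with recent intakes, decays only during protracted
  abstinence;
* ``Q`` drug-cue magnitude -- a memory trace of paired intakes.

External triggers AS/AP/AD/AQ add their magnitude to the matching process in
their event hour and enter the rationality density directly that hour.

Rationality density aggregates the processes through their cognitive weights:
stress, craving, and cues (and the AS/AD/AQ triggers) *reduce* rationality;
health worry, an acute-distress trigger AP, and an active healing signal
*increase* it:

    rd = rd0 + omega_P*P + omega_H*H + omega_A*AP
             - omega_S*S - omega_D*D - omega_Q*Q - omega_A*(AS + AD + AQ)

The cognitive state squashes rd into [0, 1] with a logistic of scale
``cs_scale`` (cs = 0 pure compulsion, cs = 1 pure inhibition), and the
behavioral tendency balances the two constant drives:

    G = cs * inhibition - (1 - cs) * compulsion

so G is strictly increasing in cs and its sign (healthy >= 0, maladaptive
< 0) drives both the set-point branching and the intake gate.

The time-varying weights (omega_S, omega_P, omega_D) take fixed-size
stochastic steps: while associative learning is active and drug pairing is
recent, each weight independently steps toward its maladaptive end
(omega_S, omega_D up; omega_P down) with probability ``p_learn_per_hour``;
while a healing intervention is active each steps toward its healthy end with
probability ``p_heal_per_hour``.  Healing steps accumulate in a *pending*
displacement that either becomes permanent at a window offset (see
:mod:`allostasim.healing`) or relaxes back.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters

__all__ = [
    "update_neuropsych",
    "update_weights",
    "effective_weights",
    "rationality_density",
    "cognitive_state",
    "drug_seeking_tendency",
]

# maladaptive step directions for (omega_S, omega_P, omega_D)
_MALADAPTIVE_DIR = (+1.0, -1.0, +1.0)


def update_neuropsych(
    s,
    p,
    d,
    q,
    intakes_last_hour,
    abstinent_hours,
    dependent,
    trigger_as=0.0,
    trigger_ap=0.0,
    trigger_ad=0.0,
    trigger_aq=0.0,
    params: ModelParameters = None,
):
    """One hourly update of (S, P, D, Q); all outputs clipped to [0, 1]."""
    z = np.asarray(intakes_last_hour, dtype=float)
    abst = np.asarray(abstinent_hours, dtype=float)
    dep = np.asarray(dependent, dtype=bool)

    withdrawing = dep & (abst >= params.withdrawal_onset_h) & (abst <= params.withdrawal_end_h)
    s_new = np.where(
        withdrawing,
        s + params.s_rise_per_hour * (1.0 - s),
        s * (1.0 - params.s_relax_per_hour),
    )
    p_new = p + params.p_rise_per_intake * z * (1.0 - p) - params.p_relax_per_hour * p
    # craving decays toward a cue-conditioned floor (incentive-sensitization
    # residue): deep cue memory keeps a residual craving alive even after
    # protracted abstinence
    d_floor = params.d_floor_frac * np.asarray(q, dtype=float)
    d_decay = (z == 0) & (abst >= params.d_abstinence_onset_h)
    d_new = np.where(
        d_decay,
        d_floor + np.maximum(d - d_floor, 0.0) * (1.0 - params.d_relax_per_hour),
        d + params.d_rise_per_intake * z * (1.0 - d),
    )
    q_new = q + params.q_rise_per_intake * z * (1.0 - q) - params.q_relax_per_hour * q

    s_new = np.clip(s_new + trigger_as, 0.0, 1.0)
    p_new = np.clip(p_new + trigger_ap, 0.0, 1.0)
    d_new = np.clip(d_new + trigger_ad, 0.0, 1.0)
    q_new = np.clip(q_new + trigger_aq, 0.0, 1.0)
    return s_new, p_new, d_new, q_new


def _clip_pending(base, pending, params: ModelParameters):
    """Keep the effective weight (base + pending) inside the omega bounds."""
    eff = np.clip(base + pending, params.omega_min, params.omega_max)
    return eff - base


def update_weights(
    base,
    pending,
    learning_eligible,
    healing_active,
    uniforms,
    params: ModelParameters,
):
    """One hourly stochastic update of the three time-varying weights.

    ``base`` and ``pending`` are 3-tuples of arrays ordered
    (omega_S, omega_P, omega_D); ``uniforms`` supplies one U(0,1) draw per
    weight (sequence of 3 arrays).  Returns updated ``(base, pending)``.
    Learning steps move the permanent base toward the maladaptive end;
    healing steps accumulate in ``pending`` toward the healthy end; pending
    displacement relaxes at ``heal_relax_per_hour`` whenever H = 0.
    """
    healing = np.asarray(healing_active, dtype=bool)
    learn = np.asarray(learning_eligible, dtype=bool) & ~healing
    new_base, new_pending = [], []
    for j in range(3):
        b, pend, u = np.asarray(base[j], dtype=float), np.asarray(pending[j], dtype=float), uniforms[j]
        step_learn = learn & (u < params.p_learn_per_hour)
        step_heal = healing & (u < params.p_heal_per_hour)
        b = b + np.where(step_learn, _MALADAPTIVE_DIR[j] * params.weight_step, 0.0)
        b = np.clip(b, params.omega_min, params.omega_max)
        pend = pend + np.where(step_heal, -_MALADAPTIVE_DIR[j] * params.weight_step, 0.0)
        pend = np.where(healing, pend, pend * (1.0 - params.heal_relax_per_hour))
        pend = _clip_pending(b, pend, params)
        new_base.append(b)
        new_pending.append(pend)
    return tuple(new_base), tuple(new_pending)


def effective_weights(base, pending, params: ModelParameters):
    """Effective (omega_S, omega_P, omega_D): base plus pending, bounded."""
    return tuple(
        np.clip(np.asarray(base[j]) + np.asarray(pending[j]), params.omega_min, params.omega_max)
        for j in range(3)
    )


def rationality_density(
    s,
    p,
    d,
    q,
    omega_s,
    omega_p,
    omega_d,
    healing_active,
    trigger_as=0.0,
    trigger_ap=0.0,
    trigger_ad=0.0,
    trigger_aq=0.0,
    params: ModelParameters = None,
):
    """Weighted aggregate of the neuropsychological scale (see module docs)."""
    h = np.asarray(healing_active, dtype=float)
    return (
        params.rd_baseline
        + omega_p * np.asarray(p, dtype=float)
        + params.omega_h * h
        + params.omega_a * np.asarray(trigger_ap, dtype=float)
        - omega_s * np.asarray(s, dtype=float)
        - omega_d * np.asarray(d, dtype=float)
        - params.omega_q * np.asarray(q, dtype=float)
        - params.omega_a * (
            np.asarray(trigger_as, dtype=float)
            + np.asarray(trigger_ad, dtype=float)
            + np.asarray(trigger_aq, dtype=float)
        )
    )


def cognitive_state(rd, params: ModelParameters):
    """Logistic squash of rationality density into [0, 1]."""
    from scipy.special import expit

    return expit(np.asarray(rd, dtype=float) / params.cs_scale)


def drug_seeking_tendency(cs, params: ModelParameters):
    """Inhibition-vs-compulsion balance; strictly increasing in cs."""
    cs = np.asarray(cs, dtype=float)
    return cs * params.inhibition_const - (1.0 - cs) * params.compulsion_const
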
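# Methods

`allostasim` simulates the allostatic account of drug dependence as a
discrete-time stochastic hybrid system on two clocks: pharmacology on a
minute grid `t`, and neuropsychology/cognition/behavior on an hour grid
`t* = floor(t/60)`.  A "virtual subject" is one seeded trajectory; the
study-level objects are 100-run ensembles with pointwise 95% simulation
envelopes.  This note records the model, the choices made where the design
was genuinely open, and what the packaged defaults do and do not emulate.

## Model

### Pharmacological scale (minutes)

Brain drug concentration follows a single compartment with first-order
elimination and an instantaneous bolus per intake:

    C(t+1) = C(t) e^{-k_e} + Z(t) * dose / V

The default elimination rate corresponds to a ~2 h half-life (nicotine-like);
dose and apparent distribution volume are expressed in model units, so only
the bolus increment `dose/V` matters.  One compartment is the minimal
structure consistent with a brain-concentration state variable; the PK step
sits behind its own function so a richer model can be swapped in.

The drug's lowering effect on reward threshold is a saturating Emax curve
scaled by the baseline reward threshold, with half-effect at the potency
index `T_50`:

    T(t) = T_0(t*) * C(t) / (C(t) + T_50)

"Potency index" is read in the standard pharmacodynamic sense (half-effect
concentration).

**Intake decision.**  The current reward threshold is the baseline lowered by
the drug effect, `T_0 - T`.  A dose is taken at minute `t` iff

1. drug is available (schedule),
2. the behavioral tendency is maladaptive, `G(t*) < 0`,
3. the net threshold exceeds the reward set point, `(T_0 - T) - T_S > 0`
   (negative hedonic valence: the drug on board no longer brings the subject
   to the set point), and
4. at least 30 min have elapsed since the previous intake (refractory rule).

This negative-reinforcement gate makes escalation follow from a rising
baseline threshold or a falling set point, reproduces satiety at the
refractory-implied ceiling of 48 intakes/day without any explicit cap, and
lets a set point raised above the baseline act as a protective "shield"
(no concentration can produce craving).  Within a minute the order is
decay -> effect -> decision -> bolus, so a decision never sees its own
bolus.

### Within-system adaptation: reward set point (hours)

    T_S(t*+1) = lambda (1 - e^{-beta d}) + T_S(t_c)   if G >= 0 and sum(Z) >= 1
                T_S(t_c) e^{-gamma d}                 if G <  0 and sum(Z) >= 1
                T_S(t*)                               otherwise

`t_c` is the hour of the last sign change of G and `d` counts hours since
then; resetting `d` on each sign change keeps `T_S` continuous.  Healthy
stretches ratchet the set point up by at most `lambda` each; sustained
drug-seeking lets it decay geometrically.  Under the intake gate above,
a high set point means *less* consumption, so the healthy branch is an
improvement and the maladaptive branch a deterioration, consistent with the
hypothesis the equation encodes.

### Between-system adaptation: baseline reward threshold (hours)

    T_0(t*+1) = T_0 + delta_T0 (-2H + 1)(omega_S - omega_P + omega_D)   if sum(Z) >= alpha
                T_0                                                    otherwise

active only after `alpha` cumulative intakes (the craving-stage gate), with
the drift direction flipped while a healing intervention is active.  After
successful healing the weight balance itself turns negative, so `T_0`
*continues to fall* with H idle — that is what produces the post-treatment
mood recovery.  `T_0` is clamped at zero (thresholds are magnitudes).

### Neuropsychological scale (hours, all processes in [0, 1])

Bounded first-order dynamics, clipped to [0, 1]:

* stress `S`: rises during withdrawal (dependent subject abstinent between
  an onset lag and a hump end), relaxes otherwise — the acute withdrawal
  hump that punctures unprotected quit attempts;
* health worry `P`: accumulates with intakes, near-permanent — the slow
  rescue force;
* craving `D`: grows with each intake; once an abstinence gap exceeds a
  short onset (2 h default) it decays — not to zero but toward a
  cue-conditioned floor `d_floor_frac * Q` (incentive-sensitization
  residue), so a long-exposed subject keeps a residual craving that a
  brief experimenter does not;
* cue memory `Q`: a very slow, non-decaying memory of cumulative exposure —
  the relapse trap that distinguishes a subject who quit after a few hundred
  cigarettes from one treated after thousands.

External triggers AS/AP/AD/AQ add their magnitude to the matching process in
their event hour (severe stressor, acute distress, drug priming, cue
reactivation).  The three case studies schedule no trigger events; the
machinery is exercised by tests.

### Cognitive scale (hours)

Rationality density aggregates the processes through their weights:

    rd = rd_0 + omega_P P + omega_H H + omega_A AP
             - omega_S S - omega_D D - omega_Q Q - omega_A (AS + AD + AQ)

`cs = logistic(rd / cs_scale)` maps rd to [0, 1] (0 compulsion, 1
inhibition), and the behavioral tendency is the balance

    G = cs * inhibition - (1 - cs) * compulsion.

Only the sign of G feeds back (intake gate, set-point branching).  The
drug-naive baseline `rd_0` is slightly negative: an untreated subject with no
drug history is mildly disposed to experiment, which is what starts
consumption when the drug becomes available on day 5.

The time-varying weights `omega_S, omega_P, omega_D` take fixed-size steps
(`weight_step`) within [0, 1]:

* **associative learning** — while learning is active and at least one intake
  occurred in the trailing pairing window (3 h default), each weight
  independently steps toward its maladaptive end (`omega_S`, `omega_D` up,
  `omega_P` down) with probability `p_learn_per_hour`.  Tying eligibility to
  recent drug pairing makes learning speed scale with consumption intensity;
  learning stops permanently once the trailing 7-day consumption rate
  reaches the "needing" stage (stage 4 of the four-stage dependence
  classification, boundary 10.9 intakes/day);
* **healing** — while H = 1 each weight steps toward its healthy end with
  probability `p_heal_per_hour`; these displacements accumulate in a pending
  buffer;
* **persistence** — at each H 1->0 transition each weight's pending
  displacement becomes permanent with probability `p_persist`, otherwise it
  keeps relaxing back at `heal_relax_per_hour`.

Fixed-size Bernoulli steps (rather than diffusions) keep every stochastic
element binomially testable.

### Healing interventions

H(t*) is a pure schedule indicator.  Replacement therapy and meditation-like
practice share the code path and differ only through the window list (two
120 h windows vs eight 15 h windows).  While active, H adds `omega_H` inside
rd — large enough to force immediate abstinence — and flips the drift sign
of `T_0`.  The pharmacology of the replacement agent itself is not modeled
(the patch's nicotine does not enter C); healing is purely cognitive, and
its only durable traces are persisted weight displacements.

### Mood (minutes)

    M(t) = rc(t) + cd(t)
    cd(t) = -T(t) + gamma_M (dTSO(t*) - dTSO(t*-1))    once sum(Z) >= 1, else 0

with `dTSO = T_S - T_0` evaluated hourly and held within the hour (the
equation mixes the two clocks explicitly).  Each intake launches a
rush/comedown pulse: one full sinusoid period (rush half, comedown half)
continued as an exponentially damped sinusoid tail; rc is the superposition
of all pulses.  The tail is taken to continue the sinusoid under a decaying
envelope — the least-surprising reading of a "slightly exponentially
decaying tail" — and pulses are retired once the envelope falls below
1e-6 of the amplitude.  Mood never feeds back into the dynamics, so the
engine assembles it after the state loop (the rc superposition becomes a
convolution of the intake train with the pulse kernel).

## Emergent structure the calibration relies on

With the default ledger the ensemble dynamics are bimodal, which is what
makes ensemble-mean endpoints and abstinence indices move together:

* **lock-in**: learning erodes the weights, rd stays negative, the set point
  decays and the baseline threshold grows, so consumption escalates to the
  refractory ceiling;
* **spontaneous quit**: runs with lucky (slow) learning draws are rescued by
  accumulating health worry before cue memory and erosion close the window;
  a quit collapses craving, which makes it cognitively self-sustaining;
* **shielded abstinence**: a ratcheted set point above the baseline
  threshold blocks relapse intakes even while rd dips negative (dry
  craving) — this is what separates the evaluations: with `T_S` frozen
  (Evaluation 2) the shield does not exist and every marginal subject
  relapses; with `T_0` frozen (Evaluation 3) the shield is easiest to reach;
* **treatment**: healing forces abstinence, collapses craving, and either
  locks healed weights (persistence draws at window offsets) or leaves the
  subject to the race between pending-weight relaxation and the cue trap.
  Many short windows beat few long ones through more persistence draws and
  continuous coverage of the withdrawal hump.

## Parameters

The full ledger (54 constants) ships as `data/reference_params.yaml` with
units in the key names.  Values printed in the study set-up are locked:
30 min refractory, 160-day horizon, availability on day 5, 100 runs,
healing window times/durations, the stage rates (2.2/4.4/8.6/13.2 per day,
midpoint boundaries 3.3/6.5/10.9), and the stage linkage of learning (stops
at stage 4) and of the `alpha` gate (craving stage).  The remaining
constants are a reference calibration, tuned with the packaged
coordinate-descent harness (`allostasim.calibration`, reduced-replicate
ensembles with fixed seeds) so that the shipped presets reproduce the
documented case-study endpoints; they are provisional in the sense that any
later authoritative constant set should replace them verbatim, after which
the harness remains useful only for sensitivity analysis.

## Numerical choices

* Hours are the scheduling unit, minutes the integration unit (60 min/h);
  all windows are whole hours, half-open `[start, end)`.
* The engine is vectorized across ensemble runs; every run consumes its own
  pre-drawn stream (`seed = base_seed + run index`, one PCG64 generator per
  run), so a run is bit-identical alone or inside any ensemble and
  independent of evaluation order.
* Envelopes are pointwise empirical 2.5/97.5 percentiles across runs; traces
  are stored in float32, which bounds cross-platform trace differences well
  below the 1e-9 relative reproducibility contract of the state update
  (performed in float64).
* Endpoint summaries average the final 7 simulated days to denoise daily
  counts; the abstinence index is the percentage of runs with zero intakes
  on a given day.
* Mood-trend diagnostics use documented windows: the overall trend is the
  least-squares slope of the ensemble-mean daily mood over days 10-160;
  treatment recovery is assessed over days 75-125 (spanning the day-80 to
  day-100 healing period of the treated presets); oscillation growth is the
  intraday standard deviation of mood per run per day, compared early
  (days 10-40) versus late (days 130-160).
* Degenerate inputs: empty schedules are valid (drug-naive runs); `T_0` is
  clamped at 0; weight steps are clipped to the omega bounds; non-finite
  state aborts with the offending symbol and time index.

## What the defaults emulate — and what they do not

The defaults narrate tobacco smoking: a ~2 h elimination half-life, one
bolus per cigarette, a 30-min refractory interval, dependence staging in
cigarettes per day, nicotine-patch-like and meditation-like healing
schedules.  They do not emulate pharmacodynamic tolerance at receptor level,
the pharmacology of replacement agents, inter-subject parameter
heterogeneity (runs differ only by seed), or clinical mood scales (all
units except time are arbitrary).  Passing tests therefore demonstrate
internal consistency and reproduction of the documented simulation
endpoints — not calibration against human data.

## Known limitations

* The cognitive functional forms (rd aggregation, logistic cs, constant
  compulsion/inhibition) are the simplest bounded monotone forms satisfying
  the qualitative statements they encode; alternatives fit behind the same
  operation contracts.
* Ensemble endpoints of the stochastic weight race are sensitive to the
  learning/worry/cue rate constants; the reference calibration pins one
  workable regime rather than a measured one.
* The abstinence index is binary per day; low-rate smoking (1-3/day) and
  true abstinence are distinguished only through it, not through a
  consumption-distribution metric.
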
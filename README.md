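# allostasim

A dual-time-scale stochastic simulator of the **allostatic theory of drug
dependence**, narrated for tobacco smoking.  It is aimed at computational
psychiatry researchers who want a reproducible, testable implementation of
the hypothesis that addiction trajectories — escalation, conventional
replacement therapy, and meditation-like interventions — emerge from the
interplay of pharmacology, reward-system adaptation, and a stochastic
cognitive substrate.

## The model in brief

Minute clock `t` (pharmacology):

* brain concentration: `C(t+1) = C(t)·e^{-k_e} + Z(t)·dose/V`
* drug effect (Emax): `T = T_0·C/(C + T_50)`
* intake decision: `Z = 1` iff drug available, tendency maladaptive
  (`G < 0`), net threshold above set point (`(T_0 − T) − T_S > 0`), and
  ≥ 30 min since the last intake
* mood: `M = rc + cd`, with `rc` a superposition of per-intake
  rush/comedown pulses and `cd = −T + γ_M·ΔTSO(t*) − ΔTSO(t*−1))` once
  consumption has started (`ΔTSO = T_S − T_0`)

Hour clock `t*` (adaptation, cognition, behavior):

* reward set point (within-system):
  `T_S ← λ(1 − e^{−β·d}) + T_S(t_c)` while `G ≥ 0`,
  `T_S ← T_S(t_c)·e^{−γ·d}` while `G < 0` (after the first intake),
  with `d` hours since the last sign change of `G`
* baseline reward threshold (between-system), after `α` intakes:
  `T_0 ← T_0 + δ_T0·(−2H + 1)·(ω_S − ω_P + ω_D)`
* bounded neuropsychological processes S (stress), P (health worry),
  D (craving), Q (cue memory) plus external triggers AS/AP/AD/AQ
* stochastic cognitive weights ω_S, ω_P, ω_D (Bernoulli steps: associative
  learning toward maladaptive values, healing toward healthy values, with
  persistence draws at each healing-window offset)
* rationality density → cognitive state `cs ∈ [0,1]` → tendency
  `G = cs·inhibition − (1 − cs)·compulsion`

A healing intervention `H(t*)` is a scheduled binary signal: two 120 h
windows emulate nicotine-patch-like replacement therapy, eight 15 h windows
emulate meditation practice — same mathematics, different calibration.

See `docs/methods.md` for the full model description, parameter ledger, and
design rationale.

## Worked example

Case study 2 (replacement therapy), Evaluation 1, at reduced ensemble size:

```python
from allostasim import preset, run_ensemble

params, schedule, mode = preset(2, 1)        # two 120 h healing windows
ens = run_ensemble(params, schedule, mode, n_runs=20, base_seed=1)
print(ens.summary().to_string(index=False))
```

```
 n_runs  endpoint_intakes_per_day  endpoint_abstinence_pct  endpoint_stage  total_intakes_mean    config_digest
     20                 22.278571                46.428571               4             3642.35 76376fd3e148632b
```

`endpoint_intakes_per_day` is the ensemble-mean consumption over the final
week (cigarettes/day; 22.3 here — roughly one pack, down from the ~40/day
the untreated baseline reaches), `endpoint_abstinence_pct` the mean daily
abstinence index (46% of these 20 runs smoke-free per day at the end), and
`endpoint_stage` the dependence stage (1 none … 4 needing) implied by the
endpoint rate.  At the full 100-run study scale the same configuration
settles near 16 intakes/day with ~61% abstinence.
The same configuration from the shell:

```bash
allostasim run --preset 2.1 --runs 20 --seed 1 --out out/
```

writes per-quantity ensemble means and 95% simulation envelopes
(`hourly_mean.csv`, `minute_mean.csv`), per-run daily intake counts, the
daily abstinence index, an endpoint summary table, and an overview plot.

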
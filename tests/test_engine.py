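"""Orchestration: single runs, ensembles, metrics, and a step-by-step oracle."""

import math

import numpy as np
import pytest

from allostasim.engine import run_ensemble, run_simulation
from allostasim.metrics import abstinence_index, difranza_stage, mood_slope
from allostasim.params import EvaluationMode, ModelParameters, Schedule


def _toy(**overrides):
    defaults = dict(horizon_days=3, availability_start_day=1, n_runs=4)
    defaults.update(overrides)
    return ModelParameters().replace(**defaults)


class TestSingleRun:
    def test_drug_naive_run_is_inert(self, toy_params, empty_schedule):
        run = run_simulation(toy_params, empty_schedule, seed=3)
        assert run.total_intakes == 0
        assert not run.minute["Z"].any()
        assert np.all(run.minute["M"] == 0.0)
        assert np.all(run.hourly["TS"] == toy_params.ts_init)
        assert np.all(run.hourly["T0"] == toy_params.t0_init)

    def test_same_seed_reproduces_bitwise(self, toy_params, toy_schedule):
        a = run_simulation(toy_params, toy_schedule, seed=11)
        b = run_simulation(toy_params, toy_schedule, seed=11)
        for key in a.minute:
            np.testing.assert_array_equal(a.minute[key], b.minute[key])
        for key in a.hourly:
            np.testing.assert_array_equal(a.hourly[key], b.hourly[key])

    def test_run_identical_alone_or_inside_ensemble(self, toy_params, toy_schedule):
        alone = run_simulation(toy_params, toy_schedule, seed=7)
        ensemble = run_ensemble(toy_params, toy_schedule, n_runs=3, base_seed=5)
        # seed 7 is run index 2 of the ensemble
        np.testing.assert_array_equal(
            ensemble.daily_intakes[2], alone.daily_intakes
        )

    def test_refractory_spacing_enforced(self, toy_params, toy_schedule):
        run = run_simulation(toy_params, toy_schedule, seed=1)
        intake_minutes = np.flatnonzero(run.minute["Z"])
        assert len(intake_minutes) > 5, "toy run should consume"
        assert np.diff(intake_minutes).min() >= toy_params.refractory_min

    def test_daily_counts_sum_to_total(self, toy_params, toy_schedule):
        run = run_simulation(toy_params, toy_schedule, seed=1)
        assert run.daily_intakes.sum() == run.minute["Z"].sum()
        assert run.daily_intakes.shape == (toy_params.horizon_days,)

    def test_mood_is_zero_until_first_intake(self, toy_params, toy_schedule):
        run = run_simulation(toy_params, toy_schedule, seed=1)
        first = np.flatnonzero(run.minute["Z"])[0]
        assert np.all(run.minute["M"][:first] == 0.0)
        assert np.all(run.minute["cd"][:first] == 0.0)

    @pytest.mark.parametrize(
        "mode, column",
        [(EvaluationMode.TS_CONSTANT, "TS"), (EvaluationMode.T0_CONSTANT, "T0")],
    )
    def test_frozen_evaluation_modes(self, toy_params, toy_schedule, mode, column):
        run = run_simulation(toy_params, toy_schedule, mode=mode, seed=1)
        assert np.ptp(run.hourly[column]) == 0.0


class TestEnsemble:
    def test_single_run_envelopes_collapse_onto_mean(self, toy_params, toy_schedule):
        ens = run_ensemble(toy_params, toy_schedule, n_runs=1, base_seed=9)
        np.testing.assert_allclose(ens.hourly_low.values, ens.hourly_mean.values, rtol=1e-6)
        np.testing.assert_allclose(ens.hourly_high.values, ens.hourly_mean.values, rtol=1e-6)

    def test_envelopes_bracket_mean(self, toy_params, toy_schedule):
        ens = run_ensemble(toy_params, toy_schedule, n_runs=8, base_seed=0)
        assert (ens.hourly_low.values <= ens.hourly_mean.values + 1e-6).all()
        assert (ens.hourly_high.values >= ens.hourly_mean.values - 1e-6).all()

    def test_summary_table_columns(self, toy_params, toy_schedule):
        ens = run_ensemble(toy_params, toy_schedule, n_runs=2, base_seed=0)
        row = ens.summary().iloc[0]
        assert row["n_runs"] == 2
        assert 0.0 <= row["endpoint_abstinence_pct"] <= 100.0
        assert row["endpoint_stage"] in (1, 2, 3, 4)


class TestMetrics:
    def test_abstinence_index_definition(self):
        # 89 of 100 runs consume on the final day -> 11%
        daily = np.ones((100, 1), dtype=int)
        daily[:11, 0] = 0
        assert abstinence_index(daily)[0] == pytest.approx(11.0)
        assert abstinence_index(np.zeros((5, 2), dtype=int))[1] == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "rate, stage",
        [
            (0.0, 1), (2.2, 1), (3.2, 1),
            (3.3, 2), (4.4, 2), (6.4, 2),
            (6.5, 3), (8.6, 3), (10.8, 3),
            (10.9, 4), (13.2, 4), (50.0, 4),
        ],
    )
    def test_difranza_stage_boundaries(self, rate, stage):
        assert difranza_stage(rate) == stage

    def test_difranza_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            difranza_stage(-1.0)

    def test_mood_slope_recovers_linear_trend(self):
        days = np.arange(100)
        series = 2.0 - 0.03 * days
        assert mood_slope(series, (10, 90)) == pytest.approx(-0.03)


# --------------------------------------------------------------------------
# Straight-line oracle: an independent scalar re-implementation of the
# documented update order, compared step by step against the engine.
# --------------------------------------------------------------------------

_BOUNDS = (3.3, 6.5, 10.9)
_MAL_DIR = (1.0, -1.0, 1.0)


def _oracle_run(p, schedule, seed, frozen_ts=False, frozen_t0=False):
    n_h, n_min = p.horizon_hours, p.horizon_minutes
    avail = np.zeros(n_min, dtype=bool)
    for a, b in schedule.availability_windows:
        avail[a * 60: b * 60] = True
    h_hour = np.zeros(n_h, dtype=bool)
    for a, b in schedule.healing_windows:
        h_hour[a:b] = True
    offsets = [h for h in range(1, n_h) if h_hour[h - 1] and not h_hour[h]]
    trig = {k: np.zeros(n_h) for k in ("AS", "AP", "AD", "AQ")}
    for hour, kind, mag in schedule.trigger_events:
        if hour < n_h:
            trig[kind][hour] += mag

    gen = np.random.default_rng(int(seed))
    u_w = gen.random((n_h, 3))
    u_p = gen.random((max(len(offsets), 1), 3))

    C, last, cum = 0.0, -(10 ** 9), 0
    ts, t0 = p.ts_init, p.t0_init
    tc, d, dtso_prev = p.ts_init, 0, p.ts_init - p.t0_init
    S = P = D = Q = 0.0
    base = [p.omega_s_init, p.omega_p_init, p.omega_d_init]
    pending = [0.0, 0.0, 0.0]
    learning = True

    def eff(j):
        return min(max(base[j] + pending[j], p.omega_min), p.omega_max)

    def rd_value(h_active, t_star):
        return (
            p.rd_baseline + eff(1) * P + p.omega_h * h_active
            + p.omega_a * trig["AP"][t_star]
            - eff(0) * S - eff(2) * D - p.omega_q * Q
            - p.omega_a * (trig["AS"][t_star] + trig["AD"][t_star] + trig["AQ"][t_star])
        )

    rd = rd_value(0.0, 0) if n_h else p.rd_baseline
    # initial tendency from the naive state (no triggers at "hour -1")
    rd_init = p.rd_baseline
    cs = 1.0 / (1.0 + math.exp(-rd_init / p.cs_scale))
    sign_prev = (cs * p.inhibition_const - (1 - cs) * p.compulsion_const) >= 0

    cumh = [0] * (n_h + 1)
    decay = math.exp(-p.pk_elimination_per_min)
    out = {
        "Z": np.zeros(n_min, dtype=int), "C": np.zeros(n_min),
        "TS": np.zeros(n_h), "T0": np.zeros(n_h), "rd": np.zeros(n_h),
        "G": np.zeros(n_h),
    }

    for t_star in range(n_h):
        cumh[t_star] = cum
        z_hour = cum - cumh[t_star - 1] if t_star >= 1 else 0
        abst = min((t_star * 60 - last) / 60.0, 1e9)
        dep = cum >= p.alpha_intakes

        withdrawing = dep and p.withdrawal_onset_h <= abst <= p.withdrawal_end_h
        S = S + p.s_rise_per_hour * (1 - S) if withdrawing else S * (1 - p.s_relax_per_hour)
        P = P + p.p_rise_per_intake * z_hour * (1 - P) - p.p_relax_per_hour * P
        if z_hour == 0 and abst >= p.d_abstinence_onset_h:
            floor = p.d_floor_frac * Q
            D = floor + max(D - floor, 0.0) * (1 - p.d_relax_per_hour)
        else:
            D = D + p.d_rise_per_intake * z_hour * (1 - D)
        Q = Q + p.q_rise_per_intake * z_hour * (1 - Q) - p.q_relax_per_hour * Q
        S = min(max(S + trig["AS"][t_star], 0), 1)
        P = min(max(P + trig["AP"][t_star], 0), 1)
        D = min(max(D + trig["AD"][t_star], 0), 1)
        Q = min(max(Q + trig["AQ"][t_star], 0), 1)

        trailing = (cum - cumh[max(t_star - 168, 0)]) / 7.0
        stage = 1 + sum(trailing >= b for b in _BOUNDS)
        learning = learning and stage < p.learning_stage_cap

        h_now = bool(h_hour[t_star])
        if t_star in offsets:
            idx = offsets.index(t_star)
            for j in range(3):
                if u_p[idx, j] < p.p_persist:
                    base[j] += pending[j]
                    pending[j] = 0.0

        recent = cum - cumh[max(t_star - p.learning_pair_window_h, 0)]
        eligible = learning and recent > 0
        for j in range(3):
            u = u_w[t_star, j]
            if eligible and not h_now and u < p.p_learn_per_hour:
                base[j] += _MAL_DIR[j] * p.weight_step
            base[j] = min(max(base[j], p.omega_min), p.omega_max)
            if h_now and u < p.p_heal_per_hour:
                pending[j] -= _MAL_DIR[j] * p.weight_step
            if not h_now:
                pending[j] *= 1 - p.heal_relax_per_hour
            pending[j] = min(max(base[j] + pending[j], p.omega_min), p.omega_max) - base[j]

        rd = rd_value(float(h_now), t_star)
        cs = 1.0 / (1.0 + math.exp(-rd / p.cs_scale))
        g = cs * p.inhibition_const - (1 - cs) * p.compulsion_const

        sign_now = g >= 0
        if sign_now != sign_prev:
            d, tc = 0, ts
        else:
            d += 1
        if not frozen_ts and cum >= 1:
            if g >= 0:
                ts = p.lambda_ts * (1 - math.exp(-p.beta_ts_per_hour * d)) + tc
            else:
                ts = tc * math.exp(-p.gamma_ts_per_hour * d)
        sign_prev = sign_now

        if not frozen_t0 and cum >= p.alpha_intakes:
            drift = p.delta_t0 * (-2 * h_now + 1) * (eff(0) - eff(1) + eff(2))
            t0 = max(t0 + drift, 0.0)

        dtso_prev = ts - t0
        out["TS"][t_star], out["T0"][t_star] = ts, t0
        out["rd"][t_star], out["G"][t_star] = rd, g

        for m in range(60):
            t = t_star * 60 + m
            C *= decay
            if avail[t]:
                effect = t0 * C / (C + p.t50)
                if g < 0 and (t0 - ts) - effect > 0 and t - last >= p.refractory_min:
                    out["Z"][t] = 1
                    C += p.dose_unit / p.pk_volume
                    last = t
                    cum += 1
            out["C"][t] = C
    return out


class TestStraightLineOracle:
    @pytest.mark.parametrize("seed", [3, 11])
    def test_engine_matches_independent_scalar_walk(self, seed):
        p = _toy(
            horizon_days=2,
            alpha_intakes=3,
            p_learn_per_hour=0.3,
            learning_pair_window_h=3,
            p_heal_per_hour=0.5,
            p_persist=0.5,
            heal_relax_per_hour=0.05,
            withdrawal_onset_h=2,
            d_abstinence_onset_h=4,
            s_rise_per_hour=0.05,
        )
        schedule = Schedule(
            availability_windows=[(0, p.horizon_hours)],
            healing_windows=[(10, 14), (30, 33)],
            trigger_events=[(20, "AD", 0.3), (26, "AP", 0.2)],
        )
        run = run_simulation(p, schedule, seed=seed)
        oracle = _oracle_run(p, schedule, seed)

        np.testing.assert_array_equal(run.minute["Z"], oracle["Z"])
        np.testing.assert_allclose(run.minute["C"], oracle["C"], rtol=1e-5, atol=1e-6)
        for key in ("TS", "T0", "rd", "G"):
            np.testing.assert_allclose(run.hourly[key], oracle[key], rtol=1e-5, atol=1e-6)
        assert run.total_intakes == oracle["Z"].sum()
        assert run.total_intakes > 0, "oracle scenario should include intakes"
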
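"""Virtual trials: schedules, accrual, trial execution, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from commtrial import (
    AccrualModel,
    Boundaries,
    InterimSchedule,
    PosteriorSettings,
    Scenario,
    build_interim_schedule,
    design_preset,
    run_many,
    run_trial,
    scenario_preset,
    simulate_accrual,
)
from commtrial.simulator import apply_design, simulate_traces

FAST = PosteriorSettings(grid_size=64)


class TestInterimSchedule:
    @pytest.mark.parametrize(
        "k, expected",
        [
            (0, ()),
            (1, (128,)),
            (2, (85, 170)),
            (6, (37, 74, 110, 146, 183, 220)),
            (9, (25, 50, 75, 100, 125, 150, 175, 200, 225)),
            (18, tuple(range(13, 235, 13))),
        ],
    )
    def test_printed_rows_for_max_n_256(self, k, expected):
        assert build_interim_schedule(k).looks == expected

    def test_generic_even_spacing_rule(self):
        assert build_interim_schedule(3, 100).looks == (25, 50, 75)
        assert build_interim_schedule(1, 10).looks == (5,)

    def test_rejects_too_many_interims(self):
        with pytest.raises(ValueError):
            build_interim_schedule(256, 256)
        with pytest.raises(ValueError):
            build_interim_schedule(-1)

    def test_schedule_invariants_enforced(self):
        with pytest.raises(ValueError):
            InterimSchedule(100, (50, 50))
        with pytest.raises(ValueError):
            InterimSchedule(100, (100,))

    @given(k=st.integers(0, 40), max_n=st.integers(8, 500))
    @settings(max_examples=80, deadline=None)
    def test_generic_rule_properties(self, k, max_n):
        if k >= max_n:
            return
        sched = build_interim_schedule(k, max_n)
        looks = sched.looks
        assert len(looks) <= k
        assert all(0 < a < max_n for a in looks)
        assert all(b > a for a, b in zip(looks, looks[1:]))


class TestAccrual:
    def test_empty_for_zero_subjects(self, rng):
        assert simulate_accrual(AccrualModel(), 0, rng).size == 0

    def test_times_nondecreasing(self, rng):
        t = simulate_accrual(AccrualModel(), 100, rng)
        assert t.size == 100 and np.all(np.diff(t) >= 0)

    def test_mean_completion_time_of_full_accrual(self, rng):
        # 256 subjects at 2/week: the 256th enrollment averages 128 weeks
        last = [simulate_accrual(AccrualModel(), 256, rng)[-1] for _ in range(300)]
        se = 128 / np.sqrt(256 * 300)
        assert np.mean(last) == pytest.approx(128.0, abs=4 * se)

    def test_gaps_are_exponential(self, rng):
        t = simulate_accrual(AccrualModel(), 10_001, rng)
        gaps = np.diff(t)
        _, p = stats.kstest(gaps, "expon", args=(0, 0.5))
        assert p > 0.01

    def test_deterministic_option(self, rng):
        t = simulate_accrual(AccrualModel(kind="deterministic"), 4, rng)
        assert t == pytest.approx([0.5, 1.0, 1.5, 2.0])

    def test_dropout_not_modeled(self):
        with pytest.raises(NotImplementedError):
            AccrualModel(dropout_rate=0.1)


class TestRunTrial:
    spec = design_preset("design3")
    target = scenario_preset("target")

    def test_same_seed_reproduces_outcomes(self):
        kw = dict(schedule=build_interim_schedule(2), settings=FAST, n_sims=40, seed=5)
        a = run_many(self.spec, self.target, **kw)
        b = run_many(self.spec, self.target, **kw)
        assert [o.decision for o in a] == [o.decision for o in b]
        assert [o.n_enrolled for o in a] == [o.n_enrolled for o in b]
        assert [o.duration_weeks for o in a] == [o.duration_weeks for o in b]

    def test_run_trial_is_first_replicate_of_stream(self):
        kw = dict(schedule=build_interim_schedule(2), settings=FAST, seed=9)
        single = run_trial(self.spec, self.target, **kw)
        batch = run_many(self.spec, self.target, n_sims=3, **kw)
        assert single.decision == batch[0].decision
        assert single.n_enrolled == batch[0].n_enrolled

    def test_degenerate_low_success_boundary_forces_stop_at_first_look(self):
        eager = self.spec.with_boundaries(
            Boundaries(early_success=1e-6, early_futility=1e-7,
                       late_success=0.975, late_futility=0.85)
        )
        outcomes = run_many(
            eager, self.target, schedule=build_interim_schedule(6),
            settings=FAST, n_sims=25, seed=2,
        )
        assert all(o.decision.kind == "early_success" for o in outcomes)
        assert all(o.decision.look_index == 1 for o in outcomes)
        assert all(o.n_enrolled >= 37 for o in outcomes)

    def test_fixed_design_runs_to_full_accrual(self):
        outcomes = run_many(
            design_preset("fixed"), self.target,
            schedule=build_interim_schedule(0), settings=FAST, n_sims=30, seed=4,
        )
        assert all(o.n_enrolled == 256 for o in outcomes)
        assert all(o.decision.kind in ("late_success", "late_futility", "inconclusive")
                   for o in outcomes)

    def test_no_looks_reduces_any_design_to_fixed(self):
        kw = dict(schedule=build_interim_schedule(0), settings=FAST, n_sims=50, seed=6)
        d3 = run_many(self.spec, self.target, **kw)
        fx = run_many(design_preset("fixed"), self.target, **kw)
        assert [o.decision.kind for o in d3] == [o.decision.kind for o in fx]

    def test_sample_size_accounting(self):
        outcomes = run_many(
            self.spec, scenario_preset("null"),
            schedule=build_interim_schedule(6), settings=FAST, n_sims=200, seed=8,
        )
        looks = build_interim_schedule(6).looks
        for o in outcomes:
            assert o.n_enrolled <= 256
            if o.decision.kind in ("early_success", "early_futility"):
                assert o.n_enrolled >= looks[o.decision.look_index - 1]

    def test_harmful_scenario_stops_early_and_small(self):
        outcomes = run_many(
            self.spec, scenario_preset("harmful"),
            schedule=build_interim_schedule(6), settings=FAST, n_sims=200, seed=10,
        )
        futility_looks = [
            o.decision.look_index for o in outcomes if o.decision.kind == "early_futility"
        ]
        assert len(futility_looks) / len(outcomes) > 0.95
        assert np.mean(futility_looks) < 2.5  # overwhelmingly the first looks
        assert np.mean([o.n_enrolled for o in outcomes]) < 128

    def test_pipeline_subjects_excluded_under_concurrent_semantics(self):
        traces = simulate_traces(
            self.spec, self.target, schedule=build_interim_schedule(6),
            settings=FAST, n_sims=10, seed=3, interim_data="concurrent",
        )
        observed = traces.n_c[:, :-1] + traces.n_t[:, :-1]
        assert np.all(observed <= traces.n_enrolled[:, :-1])
        # with a 12-week lag and 2/week accrual roughly 24 subjects are pending
        assert np.all(traces.n_enrolled[:, 0] - observed[:, 0] >= 5)

    def test_completed_semantics_analyzes_scheduled_count(self):
        traces = simulate_traces(
            self.spec, self.target, schedule=build_interim_schedule(6),
            settings=FAST, n_sims=10, seed=3, interim_data="completed",
        )
        observed = traces.n_c[:, :-1] + traces.n_t[:, :-1]
        assert np.all(observed == np.array(traces.look_counts))
        assert np.all(traces.n_enrolled[:, :-1] >= observed)

    def test_early_looks_with_thin_arms_are_skipped_not_fatal(self):
        # an 8-subject trial with a look at 3 can produce a <2 arm; the look
        # is skipped and the trial continues to the final analysis
        tiny = Scenario("tiny", 0.0, 0.0, 0.07)
        outcomes = run_many(
            self.spec, tiny, schedule=InterimSchedule(8, (3,)),
            settings=FAST, n_sims=60, seed=1,
        )
        assert all(o.decision.is_terminal for o in outcomes)
        skipped = [o for o in outcomes if o.skipped_looks]
        assert skipped, "expected at least one skipped thin-arm look"


def test_design4_matches_frequentist_gsd_on_shared_streams():
    """Flat-prior posterior monitoring and the t-test comparator almost always
    agree trial by trial (decision disagreement well under 1%)."""
    schedule = build_interim_schedule(3)
    traces = simulate_traces(
        design_preset("design4"), scenario_preset("target"),
        schedule=schedule, settings=FAST, n_sims=400, seed=17,
    )
    from commtrial.inference import p_value_arrays

    traces.p_values = p_value_arrays(
        traces.n_c, traces.mean_c, traces.sse_c,
        traces.n_t, traces.mean_t, traces.sse_t,
    )
    d4 = apply_design(design_preset("design4"), traces)
    gsd = apply_design(design_preset("frequentist_gsd"), traces)
    disagree = np.mean(
        [a.decision.kind != b.decision.kind for a, b in zip(d4, gsd)]
    )
    assert disagree < 0.01


def test_fixed_design_power_matches_analytic_oracle(rng):
    """No-interim success rate agrees with the closed-form known-variance
    prediction within Monte-Carlo error (small-difference scenario)."""
    from commtrial import prob_superiority_known_variance
    from commtrial.inference import ArmSummary

    scen = scenario_preset("small")
    sigma, n_arm = scen.subject_sd, 128
    # success at the final analysis iff the skeptical posterior exceeds 0.975;
    # invert the closed form to a threshold on the observed difference
    from scipy.optimize import brentq

    def crossing(dhat):
        ac = ArmSummary(n_arm, 0.0, sigma**2 * (n_arm - 1))
        at = ArmSummary(n_arm, dhat, sigma**2 * (n_arm - 1))
        from commtrial import make_community

        return prob_superiority_known_variance(ac, at, make_community("skeptical"), sigma) - 0.975

    thresh = brentq(crossing, 0.0, 0.1)
    se = sigma * np.sqrt(2.0 / n_arm)
    analytic = stats.norm.sf((thresh - scen.delta) / se)

    outcomes = run_many(
        design_preset("fixed"), scen, schedule=build_interim_schedule(0),
        settings=FAST, n_sims=600, seed=23,
    )
    rate = np.mean([o.decision.is_success for o in outcomes])
    mc_se = np.sqrt(analytic * (1 - analytic) / 600)
    assert rate == pytest.approx(analytic, abs=3.5 * mc_se)
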
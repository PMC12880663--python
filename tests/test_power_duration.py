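"""Unit and property tests for the 3-parameter critical-power core."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from powerstrain import (
    AthleteProfile,
    InfeasiblePowerError,
    MpaVariant,
    PowerSeries,
    RecoveryModel,
    UnboundedDurationError,
    fresh_state,
    gen_intervals,
    gen_steady,
    mpa,
    split_power,
    step_w_prime,
    sustainable_power,
    time_to_exhaustion,
    trace_session,
    validate_profile,
)

profiles = st.builds(
    AthleteProfile,
    cp=st.floats(100, 500),
    w_prime=st.floats(5_000, 40_000),
    pmax=st.floats(600, 2500),
)


class TestProfileValidation:
    def test_valid_profile_passes_unchanged(self, profile):
        assert validate_profile(profile) is profile
        assert profile.ftp == profile.cp  # FTP defaults to CP

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cp=300, w_prime=20000, pmax=300),  # no headroom above CP
            dict(cp=300, w_prime=20000, pmax=250),
            dict(cp=0, w_prime=20000, pmax=1200),
            dict(cp=-10, w_prime=20000, pmax=1200),
            dict(cp=300, w_prime=0, pmax=1200),
            dict(cp=300, w_prime=20000, pmax=1200, ftp=-1),
        ],
    )
    def test_invalid_profiles_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AthleteProfile(**kwargs)


class TestPowerDurationCurve:
    def test_exhaustion_time_at_400w(self, profile):
        # W'/(P-CP) - W'/(Pmax-CP) = 200 - 22.22
        assert time_to_exhaustion(profile, 400) == pytest.approx(20000 / 100 - 20000 / 900)

    def test_exhaustion_time_is_zero_at_pmax(self, profile):
        assert time_to_exhaustion(profile, 1200) == pytest.approx(0.0)

    def test_power_at_or_below_cp_is_unbounded(self, profile):
        with pytest.raises(UnboundedDurationError):
            time_to_exhaustion(profile, 300)
        with pytest.raises(UnboundedDurationError):
            time_to_exhaustion(profile, 150)

    def test_power_above_pmax_infeasible(self, profile):
        with pytest.raises(InfeasiblePowerError):
            time_to_exhaustion(profile, 1300)

    def test_sustainable_power_limits(self, profile):
        assert sustainable_power(profile, 0) == profile.pmax
        assert sustainable_power(profile, 1e9) == pytest.approx(profile.cp, rel=1e-4)
        assert sustainable_power(profile, 3600) > profile.cp

    def test_sustainable_power_rejects_negative_duration(self, profile):
        with pytest.raises(ValueError):
            sustainable_power(profile, -1)

    @settings(deadline=None, derandomize=True)
    @given(profiles, st.floats(0.01, 0.99))
    def test_round_trip_identity(self, prof, frac):
        """sustainable_power inverts time_to_exhaustion on (cp, pmax)."""
        p = prof.cp + frac * (prof.pmax - prof.cp)
        t = time_to_exhaustion(prof, p)
        assert sustainable_power(prof, t) == pytest.approx(p, rel=1e-9)


class TestMpa:
    def test_fresh_equals_pmax_depleted_equals_cp(self, profile):
        for variant in MpaVariant:
            assert mpa(profile, 0.0, variant) == profile.pmax
            assert mpa(profile, profile.w_prime, variant) == profile.cp

    def test_half_depletion_values(self, profile):
        assert mpa(profile, 10000, "linear") == pytest.approx(750.0)
        assert mpa(profile, 10000, "squared") == pytest.approx(975.0)

    def test_w_exp_out_of_range_rejected(self, profile):
        with pytest.raises(ValueError):
            mpa(profile, -1.0)
        with pytest.raises(ValueError):
            mpa(profile, profile.w_prime + 1)

    @settings(deadline=None, derandomize=True)
    @given(profiles, st.data())
    def test_strictly_decreasing_and_bounded(self, prof, data):
        variant = data.draw(st.sampled_from(list(MpaVariant)))
        fracs = np.sort(data.draw(
            st.lists(st.floats(0.001, 0.999), min_size=2, max_size=6, unique=True)
        ))
        assume(np.all(np.diff(fracs) > 1e-6))
        vals = [mpa(prof, f * prof.w_prime, variant) for f in fracs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(prof.cp <= v <= prof.pmax for v in vals)


class TestWPrimeStepping:
    def test_no_depletion_at_cp(self, profile):
        state = fresh_state(profile)
        new = step_w_prime(profile, state, profile.cp, dt=10.0)
        assert new.w_exp == 0.0 and new.mpa == profile.pmax

    def test_one_second_above_cp(self, profile):
        new = step_w_prime(profile, fresh_state(profile), 400.0, dt=1.0)
        assert new.w_exp == pytest.approx(100.0)
        assert new.w_bal == pytest.approx(19900.0)
        assert new.mpa == pytest.approx(1195.5)

    def test_full_recovery_limit_under_skiba(self, profile):
        state = fresh_state(profile)
        for _ in range(4000):
            state = step_w_prime(profile, state, 350.0, dt=1.0, recovery="skiba_differential")
            if state.w_bal <= 0:
                break
        assert state.w_bal == 0.0
        for _ in range(20000):
            state = step_w_prime(profile, state, 0.0, dt=1.0, recovery="skiba_differential")
        assert state.w_bal == pytest.approx(profile.w_prime, rel=1e-3)

    def test_no_recovery_below_cp_when_disabled(self, profile):
        state = step_w_prime(profile, fresh_state(profile), 500.0, dt=10.0)
        after = step_w_prime(profile, state, 0.0, dt=100.0, recovery="none")
        assert after.w_exp == state.w_exp

    def test_rejects_bad_inputs(self, profile):
        with pytest.raises(ValueError):
            step_w_prime(profile, fresh_state(profile), 400.0, dt=0.0)
        with pytest.raises(ValueError):
            step_w_prime(profile, fresh_state(profile), -5.0)


class TestSessionTracing:
    def test_constant_350w_depletes_in_400s(self, profile):
        trace = trace_session(profile, gen_steady(350, 1200))
        assert trace.w_exp[399] == pytest.approx(20000.0)
        # task failure (power meets MPA) precedes full depletion
        assert trace.overdraw[399:].all()
        assert not trace.overdraw[:370].any()

    def test_all_zero_series_stays_fresh(self, profile):
        trace = trace_session(profile, gen_steady(0, 100))
        assert np.all(trace.w_exp == 0.0)
        assert np.all(trace.mpa == profile.pmax)
        assert trace.overdraw_samples == 0

    def test_intervals_with_recovery_complete(self, profile):
        series = gen_intervals(350, 60, 0, 60, 20)
        trace = trace_session(profile, series, recovery="skiba_differential")
        assert trace.w_exp[-1] < 20000.0
        assert trace.peak_w_exp < profile.w_prime  # session is completable

    def test_trace_matches_stepping(self, profile):
        series = gen_intervals(500, 30, 100, 30, 5)
        trace = trace_session(profile, series, recovery="skiba_differential")
        state = fresh_state(profile)
        for i, p in enumerate(series.power):
            state = step_w_prime(profile, state, p, series.dt, "skiba_differential")
            assert state.w_exp == pytest.approx(trace.w_exp[i], abs=1e-9)
            assert state.mpa == pytest.approx(trace.mpa[i], abs=1e-9)

    def test_sequence_interface(self, profile):
        trace = trace_session(profile, gen_steady(400, 10))
        assert len(trace) == 10
        assert trace[0].w_exp == pytest.approx(100.0)
        assert [s.w_exp for s in trace][-1] == pytest.approx(1000.0)


class TestContributionSplit:
    def test_worked_example_1000w(self, profile):
        s = split_power(profile, 1000)
        assert round(s.p_pmax) == 544
        assert round(s.p_w) == 156
        assert round(s.p_cp) == 300

    def test_worked_example_400w(self, profile):
        s = split_power(profile, 400)
        assert round(s.p_pmax) == 11
        assert round(s.p_w) == 89
        assert round(s.p_cp) == 300

    def test_sub_cp_fully_aerobic(self, profile):
        s = split_power(profile, 250)
        assert (s.p_cp, s.p_w, s.p_pmax) == (250.0, 0.0, 0.0)

    def test_boundary_continuity(self, profile):
        """Alactic share is 0 at CP and the whole supra-CP excess at Pmax."""
        assert split_power(profile, profile.cp).p_pmax == 0.0
        at_pmax = split_power(profile, profile.pmax)
        assert at_pmax.p_pmax == pytest.approx(profile.pmax - profile.cp)
        assert at_pmax.p_w == pytest.approx(0.0, abs=1e-9)

    def test_above_pmax_rejected(self, profile):
        with pytest.raises(InfeasiblePowerError):
            split_power(profile, 1201)

    @settings(deadline=None, derandomize=True)
    @given(profiles, st.floats(0, 1))
    def test_conservation(self, prof, frac):
        """Components always sum to the input power."""
        p = frac * prof.pmax
        s = split_power(prof, p)
        assert s.total == pytest.approx(p, rel=1e-9, abs=1e-9)
        assert s.p_cp >= 0 and s.p_w >= -1e-12 and s.p_pmax >= 0
        assert s.p_cp <= prof.cp


class TestExhaustionOracle:
    def test_fine_simulation_matches_closed_form(self, profile):
        """Stepping at dt=0.01 until MPA falls to P reproduces t_lim."""
        for p in (400.0, 600.0, 900.0):
            t_pred = time_to_exhaustion(profile, p)
            state = fresh_state(profile)
            t, dt = 0.0, 0.01
            while state.mpa > p:
                state = step_w_prime(profile, state, p, dt)
                t += dt
            assert t == pytest.approx(t_pred, rel=0.005)


class TestPowerSeries:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            PowerSeries(power=np.array([100.0, -1.0]))
        with pytest.raises(ValueError):
            PowerSeries(power=np.array([100.0, np.nan]))
        with pytest.raises(ValueError):
            PowerSeries(power=np.array([100.0]), dt=0.0)

    def test_duration_and_work(self):
        s = PowerSeries(power=np.full(100, 250.0))
        assert s.duration_s == 100.0
        assert s.work_kj == pytest.approx(25.0)
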
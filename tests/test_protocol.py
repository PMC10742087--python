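"""Session protocol engine: baseline, phase plan, cues, countdown."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tremorkit import (
    AnalysisError,
    ConfigError,
    ProtocolConfig,
    SessionPhase,
    build_phase_plan,
    compute_baseline,
    estimate_dominant_frequency,
    generate_cue_times,
    load_config,
    phase_at,
    run_session,
    scheduled_duration,
    simulate_tremor,
    treatment_frequency,
)
from tremorkit.simulate import SimulationScenario, simulate_entrained_subject


class TestSchedule:
    def test_day1_is_sixty_minutes(self, cfg):
        assert scheduled_duration(1, cfg) == 3600.0

    def test_later_days_are_thirty_minutes(self, cfg):
        assert all(scheduled_duration(d, cfg) == 1800.0 for d in range(2, 8))

    @pytest.mark.parametrize("day", [0, 8, -1])
    def test_day_outside_protocol_rejected(self, cfg, day):
        with pytest.raises(ConfigError):
            scheduled_duration(day, cfg)

    def test_week_totals(self, cfg):
        total = sum(scheduled_duration(d, cfg) for d in range(1, cfg.n_days + 1))
        assert total == cfg.day1_duration + 6 * cfg.daily_duration


class TestTreatmentFrequency:
    def test_phase_ratios_of_six_hertz(self, wide_cfg):
        assert treatment_frequency(6.0, SessionPhase.PHASE1, wide_cfg) == pytest.approx(4.0)
        assert treatment_frequency(6.0, SessionPhase.PHASE2, wide_cfg) == pytest.approx(2.0)

    def test_clamp_floor_applies(self, cfg):
        # raw 2.4 * 1/3 = 0.8 is clamped up to f_min = 1.0
        assert treatment_frequency(2.4, "phase2", cfg) == cfg.f_min

    def test_clamp_ceiling_applies(self, cfg):
        assert treatment_frequency(9.0, "phase1", cfg) == cfg.f_max

    def test_non_positive_baseline_rejected(self, cfg):
        with pytest.raises(ConfigError):
            treatment_frequency(0.0, "phase1", cfg)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        f0=st.floats(min_value=0.01, max_value=50.0),
        f_min=st.floats(min_value=0.1, max_value=3.0),
        spread=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_clamps_always_hold(self, f0, f_min, spread):
        cfg = ProtocolConfig(f_min=f_min, f_max=f_min + spread)
        for phase in ("phase1", "phase2"):
            f = treatment_frequency(f0, phase, cfg)
            assert cfg.f_min <= f <= cfg.f_max

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        f0=st.floats(min_value=0.1, max_value=20.0),
        delta=st.floats(min_value=0.0, max_value=5.0),
    )
    def test_monotone_in_baseline_frequency(self, f0, delta):
        cfg = ProtocolConfig()
        for phase in ("phase1", "phase2"):
            assert treatment_frequency(f0 + delta, phase, cfg) >= treatment_frequency(
                f0, phase, cfg
            )


class TestPhasePlan:
    def test_day1_boundaries(self, wide_cfg):
        plan = build_phase_plan(1, 6.0, True, wide_cfg)
        assert plan.baseline_end == 10.0
        assert plan.phase1_end == 1805.0
        assert plan.scheduled_duration == 3600.0

    def test_day2_boundaries(self, wide_cfg):
        assert build_phase_plan(2, 6.0, True, wide_cfg).phase1_end == 905.0

    def test_halves_are_equal(self, cfg):
        plan = build_phase_plan(3, 5.0, True, cfg)
        assert plan.phase1_end - plan.baseline_end == pytest.approx(
            plan.scheduled_duration - plan.phase1_end
        )

    def test_phase1_frequency_exceeds_phase2_when_unclamped(self, wide_cfg):
        plan = build_phase_plan(1, 7.0, True, wide_cfg)
        assert plan.phase1_frequency > plan.phase2_frequency

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        day=st.integers(min_value=1, max_value=7),
        f0=st.floats(min_value=0.5, max_value=15.0),
        elapsed=st.floats(min_value=0.0, max_value=4000.0),
    )
    def test_phases_partition_the_session(self, day, f0, elapsed):
        cfg = ProtocolConfig()
        plan = build_phase_plan(day, f0, True, cfg)
        phase, remaining = phase_at(elapsed, plan)
        if elapsed < plan.scheduled_duration:
            assert phase in (SessionPhase.BASELINE, SessionPhase.PHASE1, SessionPhase.PHASE2)
            assert remaining == pytest.approx(plan.scheduled_duration - elapsed)
        else:
            assert phase is SessionPhase.COMPLETE and remaining == 0.0
        # boundaries are half-open: each instant maps to exactly one phase
        assert phase_at(plan.baseline_end, plan)[0] is SessionPhase.PHASE1
        assert phase_at(plan.phase1_end, plan)[0] is SessionPhase.PHASE2
        assert phase_at(plan.scheduled_duration, plan)[0] is SessionPhase.COMPLETE


class TestCueTimes:
    def test_twenty_ticks_for_ten_seconds_at_two_hertz(self, wide_cfg):
        # phase durations engineered: day-2 halves are 895 s; use direct plan
        from tremorkit.protocol import PhasePlan

        plan = PhasePlan(
            day=2, scheduled_duration=30.0, baseline_end=10.0, phase1_end=20.0,
            phase1_frequency=2.0, phase2_frequency=1.0, baseline_frequency=3.0,
            baseline_significant=True,
        )
        cues = generate_cue_times(plan)
        phase1 = cues.tick_times[cues.tick_times < 20.0]
        assert phase1.size == 20
        np.testing.assert_allclose(np.diff(phase1), 0.5, atol=1e-9)
        assert phase1[0] == 10.0

    def test_day1_phase1_tick_count(self, wide_cfg):
        plan = build_phase_plan(1, 6.0, True, wide_cfg)
        cues = generate_cue_times(plan)
        n1 = int(np.sum(cues.tick_times < plan.phase1_end))
        assert abs(n1 - 7180) <= 1  # 1795 s x 4 Hz

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        day=st.integers(min_value=1, max_value=7),
        f0=st.floats(min_value=0.5, max_value=12.0),
    )
    def test_cue_count_equals_duration_times_frequency(self, day, f0):
        cfg = ProtocolConfig()
        plan = build_phase_plan(day, f0, True, cfg)
        cues = generate_cue_times(plan)
        t = cues.tick_times
        for start, end, freq in (
            (plan.baseline_end, plan.phase1_end, plan.phase1_frequency),
            (plan.phase1_end, plan.scheduled_duration, plan.phase2_frequency),
        ):
            n = int(np.sum((t >= start) & (t < end)))
            assert abs(n - int((end - start) * freq)) <= 1

    def test_no_cues_before_baseline_ends(self, cfg):
        plan = build_phase_plan(2, 6.0, True, cfg)
        assert generate_cue_times(plan).tick_times[0] >= plan.baseline_end


class TestBaseline:
    def test_simulated_five_hertz_tremor_recovered(self, cfg):
        rec = simulate_tremor(
            SimulationScenario(f_tremor=5.0, noise_sd=0.2, duration=12.0, seed=21)
        )
        f0, significant = compute_baseline(rec, cfg)
        assert significant
        # oracle: single full-prefix periodogram over the same 10 s
        from tremorkit import combine_axes

        prefix = rec.truncated(10.0)
        est = estimate_dominant_frequency(
            combine_axes(prefix), rec.sample_rate, cfg.band_low, cfg.band_high
        )
        assert abs(f0 - est.dominant_frequency) <= est.resolution + 1e-9
        assert abs(f0 - 5.0) <= 0.1 + 1e-9

    def test_noise_only_falls_back_to_default(self, cfg):
        rec = simulate_tremor(
            SimulationScenario(amplitude=0.0, noise_sd=0.3, duration=12.0, seed=22)
        )
        assert compute_baseline(rec, cfg) == (cfg.f_default, False)

    def test_recording_shorter_than_baseline_rejected(self, cfg):
        rec = simulate_tremor(SimulationScenario(duration=6.0, seed=0))
        with pytest.raises(AnalysisError, match="shorter"):
            compute_baseline(rec, cfg)


class TestConfigFile:
    def test_round_trip_of_overridden_values(self, tmp_path):
        p = tmp_path / "protocol.cfg"
        p.write_text("f_min = 0.5\nf_max = 8\nn_days = 5\n# comment\n")
        cfg = load_config(p)
        assert (cfg.f_min, cfg.f_max, cfg.n_days) == (0.5, 8.0, 5)
        assert cfg.ratio_phase1 == pytest.approx(2 / 3)  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "protocol.cfg"
        p.write_text("frequency_min = 0.5\n")
        with pytest.raises(ConfigError, match="unknown key"):
            load_config(p)

    def test_invalid_ratio_ordering_rejected(self):
        with pytest.raises(ConfigError):
            ProtocolConfig(ratio_phase1=0.3, ratio_phase2=0.6)


class TestRunSession:
    def test_truncated_recording_gives_half_completion(self, cfg):
        sc = SimulationScenario(f_tremor=6.0, noise_sd=0.1, duration=900.0, seed=31)
        rec = simulate_tremor(sc)
        result = run_session(rec, 2, cfg)
        entry = result.log_entry
        assert entry.completed_duration == pytest.approx(900.0)
        assert entry.completed_duration / entry.scheduled_duration == pytest.approx(0.5)
        assert entry.ended_early

    def test_full_recording_completes_fully(self, cfg):
        plan = build_phase_plan(2, 6.0, True, cfg)
        sc = SimulationScenario(
            f_tremor=6.0, responsiveness=1.0, noise_sd=0.1, duration=1800.0, seed=32
        )
        rec = simulate_entrained_subject(sc, plan)
        entry = run_session(rec, 2, cfg).log_entry
        assert not entry.ended_early
        assert entry.completed_duration == entry.scheduled_duration
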
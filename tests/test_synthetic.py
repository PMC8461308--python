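"""Virtual-patient generator and session simulator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from tremorkit.features import rms_windows
from tremorkit.synthetic import (
    CohortSettings,
    ConfigurationError,
    GloveCsvError,
    GyroStream,
    PatientProfile,
    SessionConfig,
    auto_ramp_schedule,
    expected_reset_summary,
    generate_cohort,
    generate_patient,
    read_glove_csv,
    simulate_session,
    write_glove_csv,
)


class TestGeneratePatient:
    def test_deterministic_for_seed(self):
        a, b = generate_patient(1), generate_patient(1)
        assert np.array_equal(a.tremor_freq, b.tremor_freq)
        assert np.array_equal(a.baseline_rms, b.baseline_rms)
        assert a.response_threshold == b.response_threshold
        assert a.reset_hold == b.reset_hold

    def test_invariants_over_many_draws(self):
        profiles = [generate_patient(s) for s in range(1000)]
        freqs = np.concatenate([p.tremor_freq for p in profiles])
        assert np.all((freqs > 2.0) & (freqs < 12.0))
        assert all(0.0 < p.suppression_floor < 0.5 for p in profiles)
        assert all(3.0 <= p.response_threshold <= 17.0 for p in profiles)
        assert all(p.reset_hold >= 0 for p in profiles)
        assert all(np.all(p.baseline_rms > 0) for p in profiles)

    def test_tremor_freq_matches_configured_moments(self):
        """Monte-Carlo check of the frequency generator against the exact
        truncated-normal moments it is configured with."""
        s = CohortSettings()
        a = (s.freq_bounds[0] - s.freq_mean) / s.freq_sd
        b = (s.freq_bounds[1] - s.freq_mean) / s.freq_sd
        dist = sp_stats.truncnorm(a, b, loc=s.freq_mean, scale=s.freq_sd)
        freqs = np.concatenate([generate_patient(s_).tremor_freq for s_ in range(1000)])
        se = dist.std() / np.sqrt(freqs.size)
        assert abs(freqs.mean() - dist.mean()) < 3 * se

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSettings(floor_bounds=(0.1, 0.7))
        with pytest.raises(ConfigurationError):
            CohortSettings(freq_bounds=(1.0, 11.0))

    def test_cohort_ids_and_determinism(self):
        c1 = generate_cohort(5, seed=9)
        c2 = generate_cohort(5, seed=9)
        assert [p.patient_id for p in c1] == ["P000", "P001", "P002", "P003", "P004"]
        assert all(a.response_threshold == b.response_threshold for a, b in zip(c1, c2))


class TestProfileInvariants:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("tremor_freq", np.array([1.0, 5.0, 5.0])),
            ("suppression_floor", 0.6),
            ("suppression_floor", 0.0),
            ("response_threshold", -1.0),
            ("reset_hold", -5.0),
        ],
    )
    def test_bad_profiles_rejected(self, clean_profile, field, value):
        with pytest.raises(ConfigurationError):
            replace(clean_profile, **{field: value})


class TestSimulateSession:
    def test_auto_ramp_reaches_and_holds_threshold(self, clean_profile, short_session):
        stream = simulate_session(clean_profile, short_session)
        assert stream.i_t.max() == clean_profile.response_threshold == 5.0
        sched = auto_ramp_schedule(clean_profile, short_session)
        # held for ~30 s at the top amplitude
        assert np.sum(sched == 5.0) == short_session.hold_duration
        assert np.all(stream.i_t[stream.section != "during"] == 0)

    def test_noise_free_rms_is_amplitude_over_sqrt2(self, clean_profile, short_session):
        """With integer cycles per window, windowed RMS of the pure tremor
        sinusoid equals baseline amplitude / sqrt(2) = baseline_rms."""
        stream = simulate_session(clean_profile, short_session)
        w = rms_windows(stream)
        before = w[w.section == "before"]
        for ax, expected in zip(("x", "y", "z"), clean_profile.baseline_rms):
            assert np.allclose(before[f"rms_{ax}"], expected, rtol=1e-9)

    def test_suppression_ratio_equals_floor(self, clean_profile, short_session):
        stream = simulate_session(clean_profile, short_session)
        w = rms_windows(stream)
        during = w[w.section == "during"]
        # windows well inside the suppressed hold (past slew transient)
        held = during[during.i_t >= clean_profile.response_threshold].iloc[5:]
        for ax, base in zip(("x", "y", "z"), clean_profile.baseline_rms):
            ratios = held[f"rms_{ax}"] / base
            assert np.allclose(ratios, clean_profile.suppression_floor, atol=1e-9)

    def test_envelope_piecewise_by_cycle_maxima(self, clean_profile, short_session):
        """Brute-force envelope extraction (max |x| per tremor cycle)
        recovers suppression onset and recovery completion within one
        tremor period of the closed-form change-points."""
        stream = simulate_session(clean_profile, short_session)
        period = 1.0 / clean_profile.tremor_freq[0]
        n_cycle = int(round(period * stream.sample_rate))
        n_cycles = len(stream) // n_cycle
        env = np.abs(stream.g_x[: n_cycles * n_cycle]).reshape(n_cycles, n_cycle).max(axis=1)
        amp = clean_profile.baseline_rms[0] * np.sqrt(2)
        exp = expected_reset_summary(clean_profile, short_session)
        # suppression onset: first cycle below 60 % of baseline amplitude
        onset_cycle = np.argmax(env < 0.6 * amp)
        t_onset = onset_cycle * period
        assert abs(t_onset - exp["suppression_onset_s"]) < 2 * period
        # re-emergence: the linear ramp crosses 95 % of baseline at a
        # closed-form time (hold, then (0.95 - floor)/(1 - floor) of the ramp)
        t_stim_off = short_session.before_duration + exp["stim_duration_A"]
        floor = clean_profile.suppression_floor
        t_cross95 = (
            t_stim_off
            + clean_profile.reset_hold
            + (0.95 - floor) / (1.0 - floor) * clean_profile.reemergence_ramp
        )
        last_low = np.nonzero(env < 0.95 * amp)[0][-1]
        assert abs(last_low * period - t_cross95) < 2 * period

    def test_schedule_validation(self, clean_profile, short_session):
        with pytest.raises(ConfigurationError):
            simulate_session(clean_profile, short_session, protocol=np.full(10_000, 1.0))
        with pytest.raises(ConfigurationError):
            simulate_session(clean_profile, short_session, protocol=np.array([-1.0, 2.0]))

    def test_deterministic_for_seed(self, noisy_profile, short_session):
        s1 = simulate_session(noisy_profile, short_session)
        s2 = simulate_session(noisy_profile, short_session)
        assert np.array_equal(s1.g_x, s2.g_x)
        assert np.array_equal(s1.i_t, s2.i_t)

    def test_stream_invariants_enforced(self):
        t = np.array([0.0, 0.1, 0.05])
        z = np.zeros(3)
        with pytest.raises(ValueError, match="increasing"):
            GyroStream(t, z, z, z, z, np.array(["before"] * 3), 10.0)
        t = np.array([0.0, 0.1, 0.2])
        with pytest.raises(ValueError, match="outside"):
            GyroStream(t, z, z, z, np.array([0.0, 1.0, 0.0]), np.array(["before"] * 3), 10.0)


class TestGloveCsv:
    def test_round_trip_identity(self, clean_stream, tmp_path):
        path = tmp_path / "s.csv"
        write_glove_csv(clean_stream, path)
        back = read_glove_csv(path, sample_rate=clean_stream.sample_rate)
        assert len(back) == len(clean_stream)
        assert np.allclose(back.g_x, clean_stream.g_x, atol=1e-5)
        assert np.allclose(back.i_t, clean_stream.i_t, atol=1e-6)
        assert np.array_equal(back.section, clean_stream.section)

    def test_session_row_count_matches_rate_times_duration(self, clean_profile):
        config = SessionConfig(
            before_duration=120, max_during_duration=300, after_duration=180, seed=0
        )
        stream = simulate_session(clean_profile, config, protocol=np.full(300, 6.0))
        assert len(stream) == 600 * 50  # 10 min at 50 Hz -> 30,000 rows

    def test_shuffled_timestamps_rejected_with_line_number(self, clean_stream, tmp_path):
        path = tmp_path / "bad.csv"
        write_glove_csv(clean_stream, path)
        df = pd.read_csv(path)
        df.loc[4, "timestamp"], df.loc[5, "timestamp"] = (
            df.loc[5, "timestamp"],
            df.loc[4, "timestamp"],
        )
        df.to_csv(path, index=False)
        with pytest.raises(GloveCsvError, match="line"):
            read_glove_csv(path)

    def test_malformed_value_rejected(self, clean_stream, tmp_path):
        path = tmp_path / "bad.csv"
        write_glove_csv(clean_stream, path)
        df = pd.read_csv(path)
        df["gx"] = df["gx"].astype(object)
        df.loc[2, "gx"] = "oops"
        df.to_csv(path, index=False)
        with pytest.raises(GloveCsvError, match="line 4"):
            read_glove_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("timestamp,gx\n0,1\n")
        with pytest.raises(GloveCsvError, match="missing"):
            read_glove_csv(path)
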
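"""Synthetic generator: dose-response model, ECG traces, protocol timing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vns_chrono import (
    Protocol,
    chronotropic_response,
    default_cohort,
    default_subject,
    lhs_sample,
    simulate_experiment,
    simulate_response_table,
    summarize_subject,
    synthesize_ecg,
)
from vns_chrono.design import ParameterSet
from vns_chrono.io import ranges_for
from vns_chrono.synthetic import STATES, SubjectModel


def burst(intensity=1.0, pw=100.0, n=2, f=30.0, delay=50.0):
    return ParameterSet(
        intensity=intensity, pulse_width=pw, num_pulses=n, frequency=f, delay=delay
    )


class TestDoseResponse:
    def test_zero_dose_limit(self):
        m = default_subject("vagotomy")
        tiny = burst(intensity=1e-9, pw=1e-3, n=1)
        assert chronotropic_response(tiny, m) < 1e-6

    def test_saturation_limit_capped_at_max(self):
        m = default_subject("isolated")
        huge = burst(intensity=1e4, pw=1e4, n=14, f=30.0)
        assert chronotropic_response(huge, m) == pytest.approx(m.dhr_max_true)

    def test_half_effect_point(self):
        # charge at u = K gives exactly half of the maximal reduction when
        # the pulse-number modulation is switched off
        import dataclasses

        m = dataclasses.replace(default_subject("isolated"), pulse_gain=0.0)
        q_half = m.half_effect_qnorm * m.q_thr_true  # μC
        pw = q_half / (1.0 * 10) * 1e3  # I = 1 mA, NP = 10
        ps = burst(intensity=1.0, pw=pw, n=10)
        assert chronotropic_response(ps, m) == pytest.approx(m.dhr_max_true / 2, rel=1e-9)

    def test_five_bpm_calibration_at_threshold_charge(self):
        # a burst delivering exactly q_thr_true at the reference pulse count
        # lowers heart rate by 5 bpm
        for state in STATES:
            m = default_subject(state)
            n_ref = int(round(m.pulse_ref))
            pw = m.q_thr_true / (1.0 * n_ref) * 1e3
            ps = burst(intensity=1.0, pw=pw, n=n_ref)
            drop = chronotropic_response(ps, m) * m.hr_baseline
            # pulse modulation shifts the anchor by < g*(n_ref-pulse_ref)
            assert drop == pytest.approx(5.0, rel=0.05), state

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        i1=st.floats(0.2, 2.0),
        i2=st.floats(0.2, 2.0),
        pw=st.floats(50, 200),
        n=st.integers(1, 6),
    )
    def test_monotone_in_intensity(self, i1, i2, pw, n):
        m = default_subject("vagotomy")
        lo, hi = sorted((i1, i2))
        r_lo = chronotropic_response(burst(intensity=lo, pw=pw, n=n), m)
        r_hi = chronotropic_response(burst(intensity=hi, pw=pw, n=n), m)
        assert r_hi >= r_lo - 1e-12

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(pw1=st.floats(50, 200), pw2=st.floats(50, 200), n=st.integers(1, 6))
    def test_monotone_in_pulse_width_and_count(self, pw1, pw2, n):
        m = default_subject("vagotomy")
        lo, hi = sorted((pw1, pw2))
        assert chronotropic_response(burst(pw=hi, n=n), m) >= chronotropic_response(
            burst(pw=lo, n=n), m
        ) - 1e-12
        if n < 6:
            assert chronotropic_response(burst(pw=lo, n=n + 1), m) >= chronotropic_response(
                burst(pw=lo, n=n), m
            ) - 1e-12

    def test_frequency_and_delay_neutrality(self):
        m = default_subject("intact")
        d = lhs_sample(ranges_for("intact"), 30, seed=2)
        base = [chronotropic_response(ps, m) for ps in d.sets]
        rng = np.random.default_rng(0)
        freqs = rng.permutation([ps.frequency for ps in d.sets])
        delays = rng.permutation([ps.delay for ps in d.sets])
        permuted = [
            chronotropic_response(
                ParameterSet(ps.intensity, ps.pulse_width, ps.num_pulses, f, dl), m
            )
            for ps, f, dl in zip(d.sets, freqs, delays)
        ]
        np.testing.assert_allclose(base, permuted, rtol=1e-12)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            SubjectModel(
                state="intact",
                hr_baseline=-1,
                q_thr_true=0.1,
                dhr_max_true=0.4,
                hill_coeff=4,
                half_effect_qnorm=2,
            )
        with pytest.raises(ValueError):
            SubjectModel.calibrated("intact", hr_baseline=100, q_thr_true=0.1, dhr_max_true=0.04)


class TestEcgSynthesis:
    def test_constant_60_bpm(self):
        rec = synthesize_ecg(60, 30.0, fs=1000.0, noise_sd=0.0)
        beats = rec.truth.r_times
        assert 29 <= len(beats) <= 31
        np.testing.assert_allclose(np.diff(beats), 1.0, atol=1e-9)
        assert rec.samples.max() == pytest.approx(1.0, abs=0.1)

    def test_isolated_baseline_rate_spacing(self):
        rec = synthesize_ecg(155, 30.0)
        assert np.mean(np.diff(rec.truth.r_times)) == pytest.approx(60 / 155, abs=1e-3)

    def test_step_profile_changes_beat_spacing(self):
        prof = lambda t: 180.0 if t < 30 else 160.0  # noqa: E731
        rec = synthesize_ecg(prof, 60.0)
        beats = rec.truth.r_times
        rr_early = np.diff(beats[(beats > 5) & (beats < 28)])
        rr_late = np.diff(beats[(beats > 32) & (beats < 58)])
        np.testing.assert_allclose(rr_early, 60 / 180, atol=1e-6)
        np.testing.assert_allclose(rr_late, 60 / 160, atol=1e-6)

    def test_truth_consistency_on_constant_segment(self):
        rec = synthesize_ecg(140, 20.0, noise_sd=0.05, seed=4)
        beats = rec.truth.r_times
        hr = 60.0 / np.mean(np.diff(beats))
        assert hr == pytest.approx(140.0, abs=1.0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="20 bpm"):
            synthesize_ecg(10, 30.0)


class TestSimulateExperiment:
    def test_event_log_and_spacing(self):
        d = lhs_sample(ranges_for("vagotomy"), 5, seed=1)
        m = default_subject("vagotomy")
        sim = simulate_experiment(m, d, seed=1)
        onsets = [t for t, _ in sim.recording.stim_events]
        assert len(onsets) == 5
        assert all(b - a >= 60.0 for a, b in zip(onsets, onsets[1:]))
        assert sim.recording.duration_s >= 5 * 60

    def test_saturating_set_reaches_max_reduction(self):
        m = default_subject("intact")
        big = burst(intensity=1e3, pw=1e3, n=4)
        d_one = lhs_sample(ranges_for("intact"), 1, seed=0)
        d_one = type(d_one)(sets=(big,), seed=0, ranges=d_one.ranges)
        sim = simulate_experiment(m, d_one, seed=2)
        assert sim.truth["dhr_model"].iloc[0] == pytest.approx(m.dhr_max_true)

    def test_truth_matches_profile_heart_rates(self, vagotomy_subject_run):
        sim = vagotomy_subject_run["sim"]
        truth = sim.truth
        m = vagotomy_subject_run["model"]
        assert truth["hr_bl_true"].iloc[0] == m.hr_baseline
        # after the grace interval, residual recovery in the baseline window
        # is negligible
        assert (m.hr_baseline - truth["hr_bl_true"]).abs().max() < 0.1
        np.testing.assert_allclose(
            truth["hr_stim_true"], m.hr_baseline * (1 - truth["dhr_model"]), rtol=1e-9
        )

    def test_invalid_protocol(self):
        with pytest.raises(ValueError):
            Protocol(stim_s=0.0)
        d = lhs_sample(ranges_for("vagotomy"), 1, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            simulate_experiment(
                default_subject("vagotomy"),
                type(d)(sets=(), seed=0, ranges=d.ranges),
            )


class TestCohortCalibration:
    def test_group_means_match_reported_physiology(self):
        # marker-level recovery of the shipped cohorts: group means must
        # land inside the reported band (mean ± IQR) for baseline rate,
        # maximal relative reduction and threshold charge
        bands = {
            "intact": dict(hr=(141, 153), dhr=(0.322, 0.482), qthr=(0.03, 0.15)),
            "vagotomy": dict(hr=(164, 196), dhr=(0.066, 0.192), qthr=(0.16, 0.24)),
            "isolated": dict(hr=(144, 166), dhr=(0.296, 0.474), qthr=(8.25, 9.75)),
        }
        for state, n in [("intact", 75), ("vagotomy", 75), ("isolated", 100)]:
            d = lhs_sample(ranges_for(state), n, seed=21)
            rows = []
            for i, m in enumerate(default_cohort(state, seed=30)):
                resp = simulate_response_table(m, d, subject_id=f"s{i}")
                s = summarize_subject(f"s{i}", state, resp)
                rows.append((resp["hr_bl_bpm"].mean(), s.dhr_max, s.q_thr))
            hr, dhr, qthr = np.array(rows).mean(axis=0)
            b = bands[state]
            assert b["hr"][0] <= hr <= b["hr"][1], (state, hr)
            assert b["dhr"][0] <= dhr <= b["dhr"][1], (state, dhr)
            assert b["qthr"][0] <= qthr <= b["qthr"][1], (state, qthr)

    def test_cohort_sizes(self):
        assert len(default_cohort("intact")) == 6
        assert len(default_cohort("vagotomy")) == 5
        assert len(default_cohort("isolated")) == 4
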
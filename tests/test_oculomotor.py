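"""Saccade detection, choice registration, drift, ISI, main sequence, gain."""

import numpy as np
import pytest

from oculoforage.model import ModelParams
from oculoforage.oculomotor import (
    EyeTrace,
    detect_saccades,
    exclude_trial,
    fit_main_sequence,
    intersaccadic_intervals,
    main_sequence_velocity,
    postsaccadic_drift,
    postsaccadic_drifts,
    register_choices,
    saccade_gain,
)
from oculoforage.synth import generate_session
from oculoforage.traces import generate_eye_trace


@pytest.fixture(scope="module")
def session():
    return generate_session(
        ModelParams(10, 2, 0.9), 25, rng=np.random.default_rng(40)
    )


def _trace(trial, seed=0, **kw):
    return generate_eye_trace(
        trial, (500.0, -0.1), rng=np.random.default_rng(seed), **kw
    )


class TestDetectSaccades:
    def test_constant_trace_has_no_events(self):
        trace = EyeTrace(samples=np.zeros((1000, 2)))
        assert detect_saccades(trace) == []

    def test_recovers_implanted_events(self, session):
        for trial in session.trials[:12]:
            trace, truth = _trace(trial, seed=trial.trial_id, return_truth=True)
            events = detect_saccades(trace)
            assert len(events) == len(truth.onsets_ms)
            err = np.array([e.onset_ms for e in events]) - truth.onsets_ms
            assert np.all(np.abs(err) <= 5.0)
            amp_err = np.array([e.amplitude_deg for e in events]) - truth.amplitudes_deg
            assert np.all(np.abs(amp_err) < 0.3)

    def test_microsaccade_rejected_by_amplitude(self, session):
        trial = session.trials[0]
        trace, truth = _trace(trial, return_truth=True)
        # implant a 1.5-degree movement in the tail fixation
        i0 = trace.n_samples - 120
        t = np.arange(30) / 30.0
        prof = 1.5 * (t - np.sin(2 * np.pi * t) / (2 * np.pi))
        trace.samples[i0 : i0 + 30, 0] += prof
        trace.samples[i0 + 30 :, 0] += 1.5
        events = detect_saccades(trace)
        assert len(events) == len(truth.onsets_ms)  # the microsaccade is not counted

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            detect_saccades(EyeTrace(samples=np.zeros((3, 2))))


class TestRegisterChoices:
    def test_exact_sequence_recovery(self, session):
        for trial in session.trials:
            trace = _trace(trial, seed=100 + trial.trial_id)
            assert tuple(register_choices(trace, trial.array)) == trial.choices

    def test_recovery_with_drift_and_mild_noise(self, session):
        ok = 0
        for trial in session.trials[:10]:
            trace = _trace(
                trial, seed=trial.trial_id, drift_magnitude=0.4, noise_sd=0.02
            )
            ok += tuple(register_choices(trace, trial.array)) == trial.choices
        assert ok >= 9

    def test_brief_dwell_not_registered(self, session):
        trial = session.trials[1]
        trace = _trace(
            trial, mean_isi_ms=80.0, isi_sd_ms=1e-9, min_isi_ms=80.0, tail_ms=80.0
        )
        # 80-ms dwells everywhere: below the 100-ms criterion, nothing registers
        assert register_choices(trace, trial.array) == []


class TestDriftAndISI:
    def test_noiseless_stable_fixation_zero_drift(self, session):
        trial = session.trials[2]
        trace = _trace(trial)
        saccades = detect_saccades(trace)
        drifts = postsaccadic_drifts(trace, saccades)
        valid = drifts[~np.isnan(drifts)]
        assert valid.size > 0 and np.all(valid < 0.05)

    def test_implanted_drift_recovered(self, session):
        est = []
        for trial in session.trials[:10]:
            trace = _trace(trial, seed=trial.trial_id, drift_magnitude=0.6)
            d = postsaccadic_drifts(trace, detect_saccades(trace))
            est.extend(d[~np.isnan(d)])
        assert abs(np.mean(est) - 0.6) < 0.05

    def test_truncated_window_flagged(self):
        trace = EyeTrace(samples=np.zeros((1000, 2)))
        from oculoforage.oculomotor import SaccadeEvent

        s = SaccadeEvent(
            onset_ms=900, offset_ms=950, amplitude_deg=5, peak_velocity=300,
            vector_deg=np.array([5.0, 0.0]),
        )
        assert np.isnan(postsaccadic_drift(trace, s))  # trace ends inside window
        s2 = SaccadeEvent(
            onset_ms=100, offset_ms=150, amplitude_deg=5, peak_velocity=300,
            vector_deg=np.array([5.0, 0.0]),
        )
        assert np.isnan(postsaccadic_drift(trace, s2, next_onset_ms=200.0))

    def test_isi_pairwise_and_empty(self):
        from oculoforage.oculomotor import SaccadeEvent

        mk = lambda on, off: SaccadeEvent(
            onset_ms=on, offset_ms=off, amplitude_deg=5, peak_velocity=300,
            vector_deg=np.array([5.0, 0.0]),
        )
        assert intersaccadic_intervals([mk(900, 1000), mk(1250, 1300)]).tolist() == [250.0]
        assert intersaccadic_intervals([mk(0, 10)]).size == 0

    def test_session_isi_recovered(self, session):
        isis = []
        for trial in session.trials[:15]:
            trace = _trace(trial, seed=trial.trial_id)
            isis.extend(intersaccadic_intervals(detect_saccades(trace)))
        assert abs(np.mean(isis) - 220.0) / 220.0 < 0.05


class TestMainSequence:
    def test_exact_recovery_from_points(self):
        amps = np.linspace(2.5, 30, 40)
        vels = main_sequence_velocity(amps, 500.0, -0.10)
        ms = fit_main_sequence((amps, vels))
        assert ms.emax == pytest.approx(500.0, rel=1e-4)
        assert ms.tau == pytest.approx(-0.10, rel=1e-4)
        assert ms.v20 == pytest.approx(500.0 * (1 - np.exp(-2.0)), rel=1e-4)

    def test_plateau_at_large_amplitudes(self):
        amps = np.linspace(50, 120, 30)
        vels = main_sequence_velocity(amps, 480.0, -0.12)
        ms = fit_main_sequence((amps, vels))
        assert main_sequence_velocity(np.array(100.0), ms.emax, ms.tau) == pytest.approx(
            480.0, rel=0.01
        )

    def test_noisy_recovery_within_5_percent(self):
        failures = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            amps = rng.uniform(2.5, 30, 300)
            vels = main_sequence_velocity(amps, 500.0, -0.10)
            vels = vels * (1 + 0.10 * rng.standard_normal(300))
            ms = fit_main_sequence((amps, vels))
            if abs(ms.v20 - 432.33) / 432.33 > 0.05:
                failures += 1
        assert failures == 0

    def test_scale_consistency(self):
        rng = np.random.default_rng(41)
        amps = rng.uniform(2.5, 25, 100)
        vels = main_sequence_velocity(amps, 450.0, -0.11)
        a = fit_main_sequence((amps, vels))
        b = fit_main_sequence((amps, 2.0 * vels))
        assert b.emax == pytest.approx(2.0 * a.emax, rel=1e-3)
        assert b.v20 == pytest.approx(2.0 * a.v20, rel=1e-3)
        assert b.tau == pytest.approx(a.tau, rel=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_main_sequence((np.array([5.0, 5.5, 6.0, 6.5, 7.0]), np.full(5, 300.0)))
        with pytest.raises(ValueError):
            fit_main_sequence((np.array([5.0, 15.0]), np.array([300.0, 400.0])))


class TestGain:
    def test_identities(self):
        t = np.array([10.0, 0.0])
        assert saccade_gain(t, t) == pytest.approx(1.0)
        assert saccade_gain(np.array([0.0, 10.0]), t) == pytest.approx(0.0)
        rot45 = np.array([10.0 / np.sqrt(2), 10.0 / np.sqrt(2)])
        assert saccade_gain(rot45, t) == pytest.approx(np.sqrt(2) / 2)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(42)
        s = rng.normal(size=2) * 8
        t = rng.normal(size=2) * 8
        g0 = saccade_gain(s, t)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert saccade_gain(R @ s, R @ t) == pytest.approx(g0)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            saccade_gain(np.array([1.0, 0.0]), np.array([0.0, 0.0]))


class TestVirtualWindowExclusion:
    def test_in_field_gaze_retained(self, session):
        trial = session.trials[3]
        assert exclude_trial(_trace(trial)) is False

    def test_excursion_excluded(self, session):
        trial = session.trials[3]
        trace = _trace(trial, excursion=True)
        assert exclude_trial(trace) is True

    def test_population_exclusion_fraction(self, session):
        rng = np.random.default_rng(43)
        n, frac = 60, 0.05
        flags = []
        for k in range(n):
            trial = session.trials[k % len(session.trials)]
            exc = rng.random() < frac
            flags.append(exclude_trial(_trace(trial, seed=k, excursion=exc)) == exc)
        assert np.mean(flags) == 1.0
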
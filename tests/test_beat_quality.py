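import numpy as np
import pytest

from tcdenv.beat_quality import (Beat, QualityConfig, assess_quality,
                                 beats_from_onsets, build_template,
                                 detect_onsets, normalized_mse, screen_beats,
                                 select_best_candidate)
from tcdenv.synth import SceneConfig, generate_true_envelope

FS = 217.0
CFG = QualityConfig()


def make_beat(samples, onset=0):
    samples = np.asarray(samples, dtype=float)
    return Beat(onset, onset + samples.size, samples)


def pulse_beat(n=130, base=40.0, peak=90.0):
    t = np.linspace(0, 1, n, endpoint=False)
    return base + (peak - base) * np.clip(np.sin(np.pi * t) ** 2, 0, 1)


class TestDetectOnsets:
    def test_recovers_generator_onsets(self):
        env, true_onsets = generate_true_envelope(SceneConfig(duration=60.0, seed=2))
        onsets = detect_onsets(env, CFG)
        assert abs(onsets.size - 60) <= 1
        tol = int(round(0.040 * FS))
        matched = [np.min(np.abs(true_onsets - o)) <= tol for o in onsets]
        assert all(matched)

    def test_constant_signal_has_no_onsets(self):
        assert detect_onsets(np.full(1000, 50.0), CFG).size == 0

    def test_scale_invariance(self):
        env, _ = generate_true_envelope(SceneConfig(duration=20.0, seed=4))
        assert np.array_equal(detect_onsets(env, CFG), detect_onsets(2.0 * env, CFG))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            detect_onsets(np.ones(100), CFG)


class TestScreens:
    def test_low_systolic_max(self):
        beats = [make_beat(pulse_beat(base=0.0, peak=25.0)),
                 make_beat(pulse_beat()), make_beat(pulse_beat())]
        assert 1 in screen_beats(beats, CFG)[0]
        assert screen_beats(beats, CFG)[1] == ()

    def test_low_pulse_amplitude(self):
        beats = [make_beat(pulse_beat(base=65.0, peak=80.0)),
                 make_beat(pulse_beat()), make_beat(pulse_beat())]
        assert 2 in screen_beats(beats, CFG)[0]

    def test_absolute_duration_bounds(self):
        short = make_beat(pulse_beat(n=int(0.2 * FS)))
        ok = make_beat(pulse_beat(n=int(0.6 * FS)))
        reasons = screen_beats([short, ok, ok, ok, ok], CFG)
        assert 3 in reasons[0]
        assert reasons[1] == ()

    def test_relative_duration_band(self):
        # 1.5 s beat among 0.6 s beats: 1.5 > 2 * 0.6 fails the relative screen
        long = make_beat(pulse_beat(n=int(1.5 * FS)))
        ok = make_beat(pulse_beat(n=int(0.6 * FS)))
        reasons = screen_beats([ok, ok, ok, ok, long], CFG)
        assert 4 in reasons[-1]
        assert 3 not in reasons[-1]


class TestTemplate:
    def test_identical_beats(self):
        b = pulse_beat(130)
        tpl = build_template([make_beat(b) for _ in range(5)])
        assert np.allclose(tpl, b)

    def test_median_length_truncation(self):
        beats = [make_beat(pulse_beat(130)), make_beat(pulse_beat(130)),
                 make_beat(pulse_beat(131))]
        tpl = build_template(beats)
        assert tpl.size == 130

    def test_no_valid_beats(self):
        with pytest.raises(ValueError, match="valid"):
            build_template([])


class TestNormalizedMse:
    def test_identical_is_zero(self):
        t = pulse_beat()
        assert normalized_mse(t, t) == 0.0

    def test_double_amplitude_is_one(self):
        t = pulse_beat()
        assert normalized_mse(2.0 * t, t) == pytest.approx(1.0)

    def test_tail_differences_ignored(self):
        t = pulse_beat(100)
        b = t.copy()
        b[76:] += 50.0  # beyond the 75% evaluation window
        assert normalized_mse(b, t, fraction=0.75) == 0.0

    def test_zero_template_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalized_mse(np.ones(10), np.zeros(10))


class TestAssessQuality:
    def _env_with_onsets(self, beats):
        env = np.concatenate(beats)
        onsets = np.cumsum([0] + [b.size for b in beats])
        return env, onsets

    def test_clean_identical_beats(self):
        env, onsets = self._env_with_onsets([pulse_beat() for _ in range(10)])
        rep = assess_quality(env, onsets, CFG)
        assert rep.artifact_index == 0.0
        assert all(b.sqi == pytest.approx(100.0) for b in rep.beats)

    def test_half_dropout_flags_half(self):
        good = [pulse_beat() for _ in range(5)]
        flat = [np.full(130, 10.0) for _ in range(5)]
        env, onsets = self._env_with_onsets(good + flat)
        rep = assess_quality(env, onsets, CFG)
        assert rep.artifact_index == pytest.approx(50.0)

    def test_moderate_mismatch_keeps_beat(self):
        t = pulse_beat()
        off = t + np.sqrt(0.2 * np.mean(t[:97] ** 2))  # NMSE = 0.2 on the window
        env, onsets = self._env_with_onsets([t] * 6 + [off])
        rep = assess_quality(env, onsets, CFG)
        last = rep.beats[-1]
        assert last.nmse == pytest.approx(0.2, abs=0.02)
        assert not last.flagged
        assert last.sqi == pytest.approx(80.0, abs=2.0)

    def test_unusable_segment(self):
        env = np.full(1000, 10.0)
        rep = assess_quality(env, np.array([0, 200, 400, 600]), CFG)
        assert rep.artifact_index == 100.0


class TestSelection:
    def _rep(self, gamma, ai):
        from tcdenv.beat_quality import CandidateReport
        return CandidateReport(gamma=gamma, beats=[], artifact_index=ai)

    def test_min_artifact_index_wins(self):
        reps = [self._rep(0.3, 10.0), self._rep(0.4, 0.0), self._rep(0.5, 40.0)]
        assert select_best_candidate(reps, gamma_otsu=0.4).gamma == 0.4

    def test_tie_prefers_gamma_otsu(self):
        reps = [self._rep(g, 5.0) for g in (0.36, 0.38, 0.40, 0.42, 0.44)]
        assert select_best_candidate(reps, gamma_otsu=0.40).gamma == 0.40

    def test_single_candidate(self):
        reps = [self._rep(0.7, 33.0)]
        assert select_best_candidate(reps, gamma_otsu=0.4).gamma == 0.7


def test_beats_from_onsets_spans():
    env = np.arange(100.0)
    beats = beats_from_onsets(env, np.array([10, 40, 90]))
    assert [(b.onset, b.end) for b in beats] == [(10, 40), (40, 90)]
    assert np.array_equal(beats[0].samples, env[10:40])
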
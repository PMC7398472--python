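import numpy as np
import pytest

from tcdenv.spectrogram import compute_spectrogram
from tcdenv.synth import (PRESETS, SceneConfig, generate_true_envelope,
                          preset_scene, render_spectrogram, synthesize_iq)

FS = 217.0


class TestTrueEnvelope:
    def test_per_beat_extrema(self):
        cfg = SceneConfig(duration=30.0, seed=0)
        env, onsets = generate_true_envelope(cfg)
        for a, b in zip(onsets[:-1], onsets[1:]):
            beat = env[a:b]
            assert beat.max() == pytest.approx(cfg.psv, abs=0.1)
            assert beat.min() == pytest.approx(cfg.edv, abs=0.1)

    def test_beat_count(self):
        env, onsets = generate_true_envelope(SceneConfig(duration=30.0, seed=1))
        assert abs(onsets.size - 30) <= 1

    def test_reproducible(self):
        cfg = SceneConfig(duration=10.0, seed=5)
        e1, o1 = generate_true_envelope(cfg)
        e2, o2 = generate_true_envelope(cfg)
        assert np.array_equal(e1, e2) and np.array_equal(o1, o2)

    def test_invalid_psv_edv(self):
        with pytest.raises(ValueError):
            SceneConfig(psv=40.0, edv=40.0)


class TestRenderedSpectrogram:
    def test_top_edge_tracks_truth(self):
        # speckle-free render: the naive per-column scan is an edge oracle,
        # not a speckle-robust tracer
        cfg = SceneConfig(duration=6.0, seed=2, speckle_prob=0.0)
        env, _ = generate_true_envelope(cfg)
        sp = render_spectrogram(env, cfg)
        pos = sp.velocities >= 0
        vels = sp.velocities[pos]
        # scan in linear power: on the 40 dB display scale the compressed
        # noise floor sits near intensity 0.5 and would defeat a naive scan
        power = 10.0 ** ((sp.intensity[pos] - 1.0) * 40.0 / 10.0)
        half = power.max() / 2.0
        for k in range(0, env.size, 25):
            rows = np.flatnonzero(power[:, k] >= half)
            top = vels[rows.max()]
            assert abs(top - env[k]) <= cfg.broadening

    def test_snr_recovered_from_image(self):
        cfg = SceneConfig(duration=10.0, seed=3, speckle_prob=0.0)
        env, _ = generate_true_envelope(cfg)
        sp = render_spectrogram(env, cfg)
        # invert the 40 dB display compression back to linear power
        power = 10.0 ** ((sp.intensity - 1.0) * 40.0 / 10.0)
        v = sp.velocities
        sig_band = (v >= 10.0) & (v <= env.min() - cfg.broadening)
        noise_band = v <= -20.0
        snr_db = 10 * np.log10(power[sig_band].mean() / power[noise_band].mean())
        assert snr_db == pytest.approx(cfg.edge_snr, rel=0.10)

    def test_dropout_attenuates_signal(self):
        cfg = SceneConfig(duration=10.0, seed=4, dropouts=((2.0, 2.0, 0.03),),
                          speckle_prob=0.0)
        env, _ = generate_true_envelope(cfg)
        sp = render_spectrogram(env, cfg)
        power = 10.0 ** ((sp.intensity - 1.0) * 40.0 / 10.0)
        v = sp.velocities
        plateau = (v >= 10.0) & (v <= env.min() - cfg.broadening)
        a, b = int(2.0 * FS), int(4.0 * FS)
        during = power[plateau][:, a:b].mean()
        outside = power[plateau][:, b + 50:].mean()
        atten = cfg.dropouts[0][2]
        n0 = 10 ** (-cfg.edge_snr / 10)
        assert atten * 0.5 < during / outside < atten + 3 * n0

    def test_negative_flow_mirrors_axis(self):
        cfg = SceneConfig(duration=6.0, seed=2, flow_sign=-1)
        env, _ = generate_true_envelope(cfg)
        sp = render_spectrogram(env, cfg)
        neg = sp.intensity[sp.velocities <= -10.0].mean()
        pos = sp.intensity[sp.velocities >= 10.0].mean()
        assert neg > pos

    def test_envelope_above_vmax_rejected(self):
        cfg = SceneConfig(duration=6.0, seed=2)
        with pytest.raises(ValueError, match="maximal"):
            render_spectrogram(np.full(100, 200.0), cfg)

    def test_reproducible(self):
        cfg = SceneConfig(duration=5.0, seed=9)
        env, _ = generate_true_envelope(cfg)
        s1 = render_spectrogram(env, cfg)
        s2 = render_spectrogram(env, cfg)
        assert np.array_equal(s1.intensity, s2.intensity)


class TestSyntheticIQ:
    def test_length_and_reproducibility(self):
        cfg = SceneConfig(duration=4.0, seed=8)
        env, _ = generate_true_envelope(cfg)
        iq1 = synthesize_iq(env, cfg)
        iq2 = synthesize_iq(env, cfg)
        assert iq1.samples.size == env.size * 32
        assert np.array_equal(iq1.samples, iq2.samples)

    def test_spectrogram_edge_consistency(self):
        cfg = SceneConfig(duration=4.0, seed=8)
        env, _ = generate_true_envelope(cfg)
        sp = compute_spectrogram(synthesize_iq(env, cfg))
        pos = sp.velocities >= 0
        vels = sp.velocities[pos]
        sub = sp.intensity[pos]
        n = min(sp.n_cols, env.size)
        errs = []
        for k in range(5, n - 5, 10):
            rows = np.flatnonzero(sub[:, k] >= 0.55)
            if rows.size:
                errs.append(abs(vels[rows.max()] - env[k]))
        assert np.median(errs) <= 2.0 * cfg.broadening


class TestPresets:
    def test_preset_set(self):
        assert set(PRESETS) == {"mca", "ica", "low-snr", "dropout"}

    def test_preset_overrides(self):
        scene = preset_scene("mca", seed=7, duration=5.0)
        assert scene.config.seed == 7
        assert scene.config.duration == 5.0

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="preset"):
            preset_scene("nope")

    def test_truth_alignment(self):
        scene = preset_scene("mca", duration=5.0)
        assert scene.spectrogram.n_cols == scene.true_envelope.size
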
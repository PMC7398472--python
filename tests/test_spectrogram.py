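import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcdenv.spectrogram import (AcquisitionParams, IQSignal, Spectrogram,
                                compute_spectrogram,
                                default_velocity_axis, freq_to_velocity,
                                select_flow_region, velocity_to_freq,
                                wall_filter)

ACQ = AcquisitionParams()
FS = ACQ.echo_sampling_rate


def tone(freq, duration=2.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.exp(2j * np.pi * freq * t)


class TestDopplerConversion:
    def test_maximal_detectable_velocity(self):
        # half the echo sampling rate maps to ~152 cm/s at the default probe
        v = freq_to_velocity(3472.0, ACQ)
        assert v == pytest.approx(152.768, abs=1e-3)

    def test_zero_shift(self):
        assert freq_to_velocity(0.0, ACQ) == 0.0

    def test_angle_60_doubles_velocity(self):
        acq60 = AcquisitionParams(insonation_angle=60.0)
        assert freq_to_velocity(1000.0, acq60) == pytest.approx(
            2.0 * freq_to_velocity(1000.0, ACQ))

    def test_angle_90_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionParams(insonation_angle=90.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-5e3, 5e3), st.floats(-10, 10))
    def test_linearity(self, df, a):
        assert freq_to_velocity(a * df, ACQ) == pytest.approx(
            a * freq_to_velocity(df, ACQ), rel=1e-9, abs=1e-9)

    def test_inverse_roundtrip(self):
        assert velocity_to_freq(freq_to_velocity(1234.5, ACQ), ACQ) == pytest.approx(1234.5)


class TestWallFilter:
    def test_dc_removed(self):
        iq = IQSignal(np.full(2000, 1.0 + 1.0j), FS, ACQ)
        out = wall_filter(iq, 100.0)
        assert np.abs(out.samples[200:-200]).max() < 1e-6

    def test_passband_tone_preserved(self):
        iq = IQSignal(tone(500.0), FS, ACQ)
        out = wall_filter(iq, 100.0)
        mid = slice(2000, -2000)
        gain = np.abs(out.samples[mid]).mean()
        assert gain == pytest.approx(1.0, rel=0.01)

    def test_cutoff_gain_is_half(self):
        # -3 dB per pass, two passes (zero-phase) -> amplitude gain 0.5
        iq = IQSignal(tone(100.0), FS, ACQ)
        out = wall_filter(iq, 100.0)
        mid = slice(2000, -2000)
        assert np.abs(out.samples[mid]).mean() == pytest.approx(0.5, rel=0.02)

    @pytest.mark.parametrize("freq", [60.0, 100.0, 150.0, 300.0, 600.0])
    def test_matches_closed_form_butterworth(self, freq):
        # forward-backward second-order high-pass: |H|^2 = r^4/(1+r^4), r=f/fc
        iq = IQSignal(tone(freq, duration=4.0), FS, ACQ)
        out = wall_filter(iq, 100.0)
        mid = slice(4000, -4000)
        measured = float(np.mean(np.abs(out.samples[mid])))
        r4 = (freq / 100.0) ** 4
        assert abs(measured - r4 / (1.0 + r4)) < 1e-3

    def test_too_short_signal(self):
        iq = IQSignal(np.ones(5, dtype=complex), FS, ACQ)
        with pytest.raises(ValueError, match="short"):
            wall_filter(iq, 100.0)


class TestComputeSpectrogram:
    def test_pure_tone_ridge(self):
        sp = compute_spectrogram(IQSignal(tone(1736.0, 1.0), FS, ACQ))
        ridge_rows = np.argmax(sp.intensity, axis=0)
        ridge_v = np.median(sp.velocities[ridge_rows])
        assert ridge_v == pytest.approx(freq_to_velocity(1736.0, ACQ), abs=sp.dv)
        assert ridge_v == pytest.approx(76.4, abs=0.5)

    def test_normalisation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000) + 1j * rng.normal(size=4000)
        sp = compute_spectrogram(IQSignal(x, FS, ACQ))
        assert sp.intensity.max() == pytest.approx(1.0)
        assert sp.intensity.min() >= 0.0

    def test_column_rate_217(self):
        sp = compute_spectrogram(IQSignal(tone(1000.0, 1.0), FS, ACQ))
        assert abs(sp.n_cols - 217) <= 1
        assert sp.dt == pytest.approx(1.0 / 217.0)

    def test_velocity_resolution(self):
        v = default_velocity_axis(ACQ, 1024)
        dv = v[1] - v[0]
        assert dv == pytest.approx(0.2984, abs=1e-3)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError, match="zero-power"):
            compute_spectrogram(IQSignal(np.zeros(2000, dtype=complex), FS, ACQ))


def band_spectrogram(lo=40.0, hi=90.0, value=1.0):
    v = default_velocity_axis(ACQ, 1024)
    intensity = np.zeros((v.size, 50))
    intensity[(v >= lo) & (v <= hi)] = value
    return Spectrogram(intensity, np.arange(50) / 217.0, v, ACQ)


class TestFlowRegion:
    def test_positive_band_wins(self):
        assert select_flow_region(band_spectrogram()).sign == 1

    def test_mirrored_band_flips_sign(self):
        sp = band_spectrogram()
        mirrored = Spectrogram(sp.intensity[::-1], sp.times, sp.velocities, ACQ)
        assert select_flow_region(mirrored).sign == -1

    def test_tie_breaks_positive(self):
        v = default_velocity_axis(ACQ, 1024)
        sp = Spectrogram(np.zeros((v.size, 10)), np.arange(10) / 217.0, v, ACQ)
        assert select_flow_region(sp).sign == 1

    def test_band_floor_enforced(self):
        from tcdenv.spectrogram import FlowRegion
        with pytest.raises(ValueError, match="wall-filter"):
            FlowRegion(sign=1, v_low=2.0)
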
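"""Doppler spectrogram computation for transcranial ultrasound.

A pulsed-Doppler device emits short bursts at a carrier frequency ``f_c`` and
receives echoes from moving red blood cells.  After demodulation the echo is a
complex ("IQ") time series whose instantaneous frequency content encodes the
velocity distribution of the scatterers in the sample volume.  This module

* removes low-frequency vessel-wall clutter with a high-pass "wall" filter,
* computes a log-compressed short-time power spectrogram normalised to [0, 1],
* converts Doppler frequency shifts to velocities via
  ``v = Δf · c / (2 f_c cos α)``, and
* decides whether the signal-carrying flow is positive (toward the probe,
  e.g. middle cerebral artery) or negative (away, e.g. internal carotid).

The default acquisition geometry (1.75 MHz carrier, 6.944 kHz echo sampling,
1/217 s hop with 4-hop windows) yields the 217 Hz envelope rate and the
~0.298 cm/s velocity bin used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "AcquisitionParams",
    "IQSignal",
    "StftConfig",
    "Spectrogram",
    "FlowRegion",
    "wall_filter",
    "compute_spectrogram",
    "freq_to_velocity",
    "velocity_to_freq",
    "select_flow_region",
    "oriented_magnitude",
    "default_velocity_axis",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulsed-Doppler acquisition settings.

    carrier_freq : Hz, ultrasound carrier f_c.
    sound_speed : m/s, assumed average speed of sound in tissue.
    insonation_angle : degrees between beam and flow; 0 is the common
        assumption for MCA/ICA insonation.
    echo_sampling_rate : Hz, sampling rate of the demodulated echo.
    """

    carrier_freq: float = 1.75e6
    sound_speed: float = 1540.0
    insonation_angle: float = 0.0
    echo_sampling_rate: float = 6944.0

    def __post_init__(self) -> None:
        if self.carrier_freq <= 0 or self.sound_speed <= 0 or self.echo_sampling_rate <= 0:
            raise ValueError("carrier_freq, sound_speed and echo_sampling_rate must be positive")
        if not (0.0 <= self.insonation_angle < 90.0):
            raise ValueError("insonation_angle must lie in [0, 90) degrees")


@dataclass
class IQSignal:
    """Complex demodulated echo signal with its acquisition metadata."""

    samples: np.ndarray
    sampling_rate: float
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("IQ signal must be a non-empty 1-D array")
        if not math.isclose(self.sampling_rate, self.acquisition.echo_sampling_rate,
                            rel_tol=1e-9):
            raise ValueError("sampling_rate must equal acquisition.echo_sampling_rate")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class StftConfig:
    """Short-time Fourier transform geometry.

    hop : s, shift between adjacent windows (1/217 s gives the 217 Hz
        envelope rate).
    window_hops : window length expressed in hops; 4 hops means 75% overlap.
    fft_bins : zero-padded FFT length.
    window_shape : scipy.signal.get_window taper name.
    dynamic_range : dB span mapped onto the [0, 1] intensity scale.
    """

    hop: float = 1.0 / 217.0
    window_hops: int = 4
    fft_bins: int = 1024
    window_shape: str = "hann"
    dynamic_range: float = 40.0

    def __post_init__(self) -> None:
        if self.window_hops < 2:
            raise ValueError("window_hops must be >= 2")
        if self.hop <= 0 or self.dynamic_range <= 0:
            raise ValueError("hop and dynamic_range must be positive")

    def hop_samples(self, sampling_rate: float) -> int:
        n = int(round(self.hop * sampling_rate))
        if n < 1:
            raise ValueError("hop shorter than one sample at this rate")
        return n

    def window_samples(self, sampling_rate: float) -> int:
        n = self.window_hops * self.hop_samples(sampling_rate)
        if self.fft_bins < n:
            raise ValueError("fft_bins must be >= window length in samples")
        return n


@dataclass
class Spectrogram:
    """Normalised time-velocity intensity image.

    ``intensity`` has shape (n_velocities, n_times); row order follows the
    strictly increasing ``velocities`` axis (row 0 is the most negative
    velocity).  All intensities lie in [0, 1] with 1 at the global maximum.
    """

    intensity: np.ndarray
    times: np.ndarray
    velocities: np.ndarray
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2-D (velocity x time)")
        if self.intensity.shape != (self.velocities.size, self.times.size):
            raise ValueError("intensity shape must be (len(velocities), len(times))")
        if np.nanmin(self.intensity) < -1e-12 or np.nanmax(self.intensity) > 1 + 1e-12:
            raise ValueError("intensities must lie in [0, 1]")
        for name, ax in (("times", self.times), ("velocities", self.velocities)):
            d = np.diff(ax)
            if ax.size > 1 and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-12)):
                raise ValueError(f"{name} axis must be strictly increasing with constant spacing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else float("nan")

    @property
    def dv(self) -> float:
        return float(self.velocities[1] - self.velocities[0]) if self.velocities.size > 1 else float("nan")

    @property
    def n_cols(self) -> int:
        return self.times.size

    def time_slice(self, start: int, stop: int) -> "Spectrogram":
        """Column-range view as a new Spectrogram (times re-referenced as-is)."""
        return Spectrogram(self.intensity[:, start:stop], self.times[start:stop],
                           self.velocities, self.acquisition)


@dataclass(frozen=True)
class FlowRegion:
    """Signed velocity band containing the flow signal.

    The band magnitude defaults to 5-125 cm/s; the lower bound excludes the
    wall-filter stop band around 0 cm/s.
    """

    sign: int
    v_low: float = 5.0
    v_high: float = 125.0

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if not (0 < self.v_low < self.v_high):
            raise ValueError("band must satisfy 0 < v_low < v_high")
        if self.v_low < 5.0 - 1e-9:
            raise ValueError("band must exclude |v| < 5 cm/s (wall-filter stop band)")


def freq_to_velocity(freq_shift, acq: AcquisitionParams = AcquisitionParams()):
    """Doppler frequency shift (Hz) to velocity in cm/s.

    v = Δf · c / (2 f_c cos α); odd and linear in the shift.
    """
    cos_a = math.cos(math.radians(acq.insonation_angle))
    if cos_a <= 0:
        raise ValueError("insonation angle must be < 90 degrees")
    v_m_s = np.asarray(freq_shift, dtype=float) * acq.sound_speed / (2.0 * acq.carrier_freq * cos_a)
    out = v_m_s * 100.0
    return float(out) if np.isscalar(freq_shift) else out


def velocity_to_freq(velocity_cm_s, acq: AcquisitionParams = AcquisitionParams()):
    """Inverse Doppler conversion: velocity in cm/s to frequency shift in Hz."""
    cos_a = math.cos(math.radians(acq.insonation_angle))
    if cos_a <= 0:
        raise ValueError("insonation angle must be < 90 degrees")
    v = np.asarray(velocity_cm_s, dtype=float) / 100.0
    f = v * 2.0 * acq.carrier_freq * cos_a / acq.sound_speed
    return float(f) if np.isscalar(velocity_cm_s) else f


def wall_filter(iq: IQSignal, cutoff: float = 100.0) -> IQSignal:
    """High-pass the IQ signal to suppress vessel-wall clutter.

    Second-order Butterworth, applied zero-phase (forward-backward) to the
    real and imaginary parts independently, so the attenuation at the cutoff
    is -6 dB (amplitude gain 0.5) and no group delay is introduced.
    """
    fs = iq.sampling_rate
    if not (0 < cutoff < fs / 2):
        raise ValueError("cutoff must lie in (0, sampling_rate/2)")
    b, a = sps.butter(2, cutoff / (fs / 2.0), btype="highpass")
    padlen = 3 * max(len(a), len(b))
    if iq.samples.size <= padlen:
        raise ValueError(
            f"IQ signal too short for wall filter warm-up ({iq.samples.size} <= {padlen} samples)")
    re = sps.filtfilt(b, a, iq.samples.real)
    im = sps.filtfilt(b, a, iq.samples.imag)
    return IQSignal(re + 1j * im, iq.sampling_rate, iq.acquisition)


def default_velocity_axis(acq: AcquisitionParams = AcquisitionParams(),
                          fft_bins: int = 1024) -> np.ndarray:
    """Velocity axis (cm/s) for the two-sided spectrum, ascending.

    Spans [-v_max, +v_max) in fft_bins steps where v_max corresponds to half
    the echo sampling rate (~152.8 cm/s at the defaults).
    """
    freqs = np.fft.fftshift(np.fft.fftfreq(fft_bins, d=1.0 / acq.echo_sampling_rate))
    return freq_to_velocity(freqs, acq)


def compute_spectrogram(iq: IQSignal, cfg: StftConfig = StftConfig()) -> Spectrogram:
    """Log-compressed, normalised time-velocity spectrogram of an IQ signal.

    Frames are centred at k·hop (reflect-padded at the edges) so that the
    column rate is exactly 1/hop — 217 Hz at the defaults — and column k
    corresponds to time k·hop.  Per column the two-sided power spectrum of
    the tapered frame is mapped to intensity through

        intensity = clip(1 + 10·log10(P / P_max) / dynamic_range, 0, 1),

    the standard ultrasound display compression: the global maximum maps to
    1 and anything more than ``dynamic_range`` dB below it to 0.
    """
    fs = iq.sampling_rate
    hop = cfg.hop_samples(fs)
    win = cfg.window_samples(fs)
    x = iq.samples
    if x.size < win:
        raise ValueError("IQ signal shorter than one analysis window")
    n_cols = int(math.ceil(x.size / hop))
    half = win // 2
    starts = np.arange(n_cols) * hop
    pad_right = max(0, int(starts[-1]) + win - (x.size + half))
    xp = np.pad(x, (half, pad_right), mode="reflect")
    taper = sps.get_window(cfg.window_shape, win, fftbins=True)
    frames = xp[starts[:, None] + np.arange(win)[None, :]] * taper[None, :]
    spec = np.fft.fftshift(np.fft.fft(frames, n=cfg.fft_bins, axis=1), axes=1)
    power = (spec.real ** 2 + spec.imag ** 2).T  # (velocity, time)
    p_max = power.max()
    if p_max <= 0:
        raise ValueError("zero-power input: spectrogram normalisation undefined")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power / p_max)
    intensity = np.clip(1.0 + db / cfg.dynamic_range, 0.0, 1.0)
    times = starts / fs
    velocities = default_velocity_axis(iq.acquisition, cfg.fft_bins)
    return Spectrogram(intensity, times, velocities, iq.acquisition)


def select_flow_region(sp: Spectrogram, v_low: float = 5.0, v_high: float = 125.0) -> FlowRegion:
    """Pick the signed velocity band carrying the flow signal.

    Compares summed pixel intensity in [+v_low, +v_high] against
    [-v_high, -v_low]; the band with more energy wins, ties going to +1.
    Flow that crosses zero (reverse flow) cannot be represented this way.
    """
    v = sp.velocities
    if v[0] > -v_high or v[-1] < v_high:
        raise ValueError(f"velocity axis must cover +/-{v_high} cm/s")
    pos = (v >= v_low) & (v <= v_high)
    neg = (v <= -v_low) & (v >= -v_high)
    e_pos = float(sp.intensity[pos].sum())
    e_neg = float(sp.intensity[neg].sum())
    return FlowRegion(sign=1 if e_pos >= e_neg else -1, v_low=v_low, v_high=v_high)


def oriented_magnitude(sp: Spectrogram, sign: int) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-oriented half of the spectrogram for the given flow sign.

    Returns (intensity, velocities) where velocities ascend from 0 to v_max
    regardless of the physical flow direction; negative-flow spectrograms are
    flipped so all downstream processing works on magnitudes and the sign is
    restored on output.
    """
    if sign >= 0:
        intensity, vel = sp.intensity, sp.velocities
    else:
        intensity, vel = sp.intensity[::-1], -sp.velocities[::-1]
    keep = vel >= 0
    return intensity[keep], vel[keep]
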
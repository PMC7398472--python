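"""Synthetic transcranial Doppler scenes with known ground truth.

Generates pulsatile maximal-velocity waveforms (raised-cosine systolic
upstroke, exponential diastolic decay, Gaussian dicrotic bump), renders them
into spectrogram images with the intensity structure real TCD data shows —
a bright plateau of scatterer velocities below the envelope, a sigmoid edge
rolloff modelling spectral broadening, an exponential (speckle-like) noise
floor at a configurable SNR, salt speckle and optional signal-loss intervals
— and can additionally synthesise a matching complex IQ signal as a sum of
random-phase scatterer tones.  Ground truth (envelope and beat onsets) is
kept alongside every rendered artifact so parameter-recovery tests can close
the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .spectrogram import (AcquisitionParams, IQSignal, Spectrogram, StftConfig,
                          default_velocity_axis, velocity_to_freq)

__all__ = ["SceneConfig", "SyntheticScene", "generate_true_envelope",
           "render_spectrogram", "synthesize_iq", "make_scene", "PRESETS"]

ENVELOPE_RATE = 217.0


@dataclass(frozen=True)
class SceneConfig:
    """Physiological and acoustic parameters of a synthetic scene.

    duration : s.  heart_rate : bpm; beat durations are normal with SD
    ``beat_sd`` seconds, floored at 0.3 s.  psv/edv : peak-systolic and
    end-diastolic velocity, cm/s.  dicrotic_amp : bump amplitude as a
    fraction of the pulse amplitude; dicrotic_frac its centre as a fraction
    of the beat.  edge_snr : dB ratio of signal plateau to noise floor.
    broadening : cm/s, 10-90% width of the spectral edge rolloff.
    speckle_prob : per-pixel probability of a signal-level salt speckle.
    dropouts : (start_s, length_s, attenuation) intervals where the signal
    term is multiplicatively attenuated (probe slip / signal loss).
    """

    duration: float = 60.0
    heart_rate: float = 60.0
    beat_sd: float = 0.03
    psv: float = 90.0
    edv: float = 40.0
    dicrotic_amp: float = 0.15
    dicrotic_frac: float = 0.45
    dicrotic_width_frac: float = 0.05
    flow_sign: int = 1
    edge_snr: float = 20.0
    broadening: float = 4.0
    speckle_prob: float = 0.005
    dropouts: tuple = ()
    seed: int = 0
    band_floor: float = 5.0

    def __post_init__(self) -> None:
        if not (self.psv > self.edv > 0):
            raise ValueError("must have psv > edv > 0")
        if self.duration <= 2 * 60.0 / self.heart_rate:
            raise ValueError("duration must exceed two beat periods")
        if self.flow_sign not in (-1, 1):
            raise ValueError("flow_sign must be +1 or -1")


@dataclass
class SyntheticScene:
    config: SceneConfig
    true_envelope: np.ndarray   # cm/s magnitude, at 217 Hz
    true_onsets: np.ndarray     # sample indices of beat starts
    spectrogram: Spectrogram
    iq: IQSignal | None = None


PRESETS: dict = {
    "mca": SceneConfig(),
    "ica": SceneConfig(psv=60.0, edv=25.0, flow_sign=-1),
    "low-snr": SceneConfig(edge_snr=10.0),
    "dropout": SceneConfig(dropouts=((2.0, 2.0, 0.03),)),
}


def _beat_curve(n: int, dur: float, cfg: SceneConfig) -> np.ndarray:
    """One beat sampled at the envelope rate; min = EDV at t=0, max = PSV."""
    t = np.arange(n) / ENVELOPE_RATE
    pulse = cfg.psv - cfg.edv
    t_rise = min(0.15, 0.3 * dur)
    tau = 0.18 * dur
    v = np.empty(n)
    up = t <= t_rise
    v[up] = cfg.edv + pulse * 0.5 * (1.0 - np.cos(np.pi * t[up] / t_rise))
    v[~up] = cfg.edv + pulse * np.exp(-(t[~up] - t_rise) / tau)
    t_d = cfg.dicrotic_frac * dur
    w = cfg.dicrotic_width_frac * dur
    v += cfg.dicrotic_amp * pulse * np.exp(-((t - t_d) / w) ** 2) * (t > t_rise)
    return np.minimum(v, cfg.psv)


def generate_true_envelope(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth envelope (cm/s, 217 Hz) and beat-onset sample indices.

    Beat durations are drawn once from the seeded generator, so the output
    is bit-reproducible for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = int(round(cfg.duration * ENVELOPE_RATE))
    mean_dur = 60.0 / cfg.heart_rate
    chunks = []
    onsets = []
    pos = 0
    while pos < n_total:
        dur = max(0.3, float(rng.normal(mean_dur, cfg.beat_sd)))
        n = max(1, int(round(dur * ENVELOPE_RATE)))
        onsets.append(pos)
        chunks.append(_beat_curve(n, dur, cfg))
        pos += n
    env = np.concatenate(chunks)[:n_total]
    onsets_arr = np.array([o for o in onsets if o < n_total], dtype=int)
    return env, onsets_arr


def render_spectrogram(true_envelope: np.ndarray, cfg: SceneConfig,
                       acq: AcquisitionParams = AcquisitionParams(),
                       stft: StftConfig = StftConfig()) -> Spectrogram:
    """Render a ground-truth envelope into a normalised spectrogram image.

    Linear power per column: unit plateau over [band_floor, env(t)] with a
    logistic edge rolloff of 10-90% width ``cfg.broadening``, an exponential
    noise floor at ``cfg.edge_snr`` dB below the plateau, salt speckle, and
    dropout attenuation of the signal term; then the same log-compression as
    the measured spectrogram path.  ``flow_sign`` mirrors the velocity axis.
    """
    env = np.asarray(true_envelope, dtype=float)
    velocities = default_velocity_axis(acq, stft.fft_bins)
    if env.max() > velocities[-1]:
        raise ValueError("true envelope exceeds the maximal detectable velocity")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_cols = env.size
    v_eff = cfg.flow_sign * velocities  # magnitude coordinate along the axis
    s = cfg.broadening / 4.394  # logistic scale for a 10-90% width
    # The rolloff is placed so the rendered signal support tops out at the
    # true envelope (half power at env - broadening/2): the ground truth is
    # the maximal velocity carrying signal power, which is the quantity an
    # edge tracer (or a human) estimates.  Centering the rolloff at env
    # would smear power above the true maximum and build a +broadening/2
    # bias into every comparison against the stored truth.
    edge = expit((env[None, :] - cfg.broadening / 2.0 - v_eff[:, None]) / s)
    floor = expit((v_eff[:, None] - cfg.band_floor) / 0.5)
    signal = edge * floor
    for start_s, len_s, atten in cfg.dropouts:
        a = int(round(start_s * ENVELOPE_RATE))
        b = int(round((start_s + len_s) * ENVELOPE_RATE))
        signal[:, a:b] *= atten
    n0 = 10.0 ** (-cfg.edge_snr / 10.0)
    power = signal + n0 * rng.exponential(size=signal.shape)
    if cfg.speckle_prob > 0:
        salt = rng.random(size=power.shape) < cfg.speckle_prob
        power[salt] += 1.0
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power / power.max())
    intensity = np.clip(1.0 + db / stft.dynamic_range, 0.0, 1.0)
    times = np.arange(n_cols) / ENVELOPE_RATE
    return Spectrogram(intensity, times, velocities, acq)


def synthesize_iq(true_envelope: np.ndarray, cfg: SceneConfig,
                  acq: AcquisitionParams = AcquisitionParams(),
                  n_scatterers: int = 64) -> IQSignal:
    """Complex echo signal matching the ground-truth envelope.

    Per envelope sample (one 1/217 s block) the signal is a sum of
    random-phase complex exponentials whose Doppler frequencies come from
    scatterer velocities drawn uniformly below the envelope and smeared by a
    logistic edge of scale ``broadening``; complex white noise is added at
    the configured SNR.  Seeded and bit-reproducible.
    """
    env = np.asarray(true_envelope, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    fs = acq.echo_sampling_rate
    hop = int(round(fs / ENVELOPE_RATE))
    s = cfg.broadening / 4.394
    n0 = 10.0 ** (-cfg.edge_snr / 10.0)
    t_block = np.arange(hop) / fs
    out = np.empty(env.size * hop, dtype=complex)
    amp = 1.0 / np.sqrt(n_scatterers)
    for k, e in enumerate(env):
        top = max(e - cfg.broadening / 2.0, cfg.band_floor + 1e-6)
        v = rng.uniform(cfg.band_floor, top, size=n_scatterers)
        v = v + s * rng.logistic(size=n_scatterers)
        freqs = velocity_to_freq(cfg.flow_sign * v, acq)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_scatterers)
        block = amp * np.exp(
            1j * (2.0 * np.pi * freqs[:, None] * (k * hop / fs + t_block)[None, :]
                  + phases[:, None])).sum(axis=0)
        out[k * hop:(k + 1) * hop] = block
    noise = rng.normal(scale=np.sqrt(n0 / 2.0), size=(2, out.size))
    out += noise[0] + 1j * noise[1]
    return IQSignal(out, fs, acq)


def make_scene(cfg: SceneConfig, with_iq: bool = False) -> SyntheticScene:
    """Generate a complete scene: truth, spectrogram, optional IQ signal."""
    env, onsets = generate_true_envelope(cfg)
    sp = render_spectrogram(env, cfg)
    iq = synthesize_iq(env, cfg) if with_iq else None
    return SyntheticScene(config=cfg, true_envelope=env, true_onsets=onsets,
                          spectrogram=sp, iq=iq)


def preset_scene(name: str, seed: int | None = None,
                 duration: float | None = None, with_iq: bool = False) -> SyntheticScene:
    """Named preset scene (mca, ica, low-snr, dropout) with optional overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    kwargs = {}
    if seed is not None:
        kwargs["seed"] = seed
    if duration is not None:
        kwargs["duration"] = duration
    if kwargs:
        cfg = replace(cfg, **kwargs)
    return make_scene(cfg, with_iq=with_iq)
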
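"""Beat-by-beat signal quality assessment of flow velocity waveforms.

A candidate envelope is split into beats at detected onsets, each beat is
screened against four physiological conditions (systolic amplitude, pulse
amplitude, absolute and relative duration), and surviving beats are compared
with the segment's median beat template via a normalised mean squared error
(NMSE) evaluated on the first 75% of the template span, where heart-rate
variability matters least.  Beats failing a screen or with NMSE > 30% are
artifacts; the artifact index (percentage of flagged beats) ranks the
candidate segmentation thresholds and its arg-min is the selected envelope.
The per-beat signal quality index is SQI = 100 * max(0, 1 - NMSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "QualityConfig",
    "Beat",
    "BeatRecord",
    "CandidateReport",
    "detect_onsets",
    "screen_beats",
    "build_template",
    "normalized_mse",
    "assess_quality",
    "select_best_candidate",
]

ENVELOPE_RATE = 217.0


@dataclass(frozen=True)
class QualityConfig:
    """Thresholds of the physiological beat screens and template matching.

    min_systolic : cm/s, screen 1 — systolic maximum must exceed this.
    min_pulse : cm/s, screen 2 — max-min amplitude must exceed this.
    min_duration / max_duration : s, screen 3 absolute duration bounds
        (heart rate between 30 and 240 bpm).
    rel_duration_band : multiples of the segment median duration, screen 4.
    template_fraction : leading fraction of the template used for the NMSE.
    nmse_flag : NMSE above which a beat is flagged as artifact.
    abp_peak_target : onset detection rescales the waveform so the mean
        per-beat peak sits at this value (an arterial-pressure-like scale,
        mmHg); the rescaling never touches reported velocities.
    """

    min_systolic: float = 30.0
    min_pulse: float = 20.0
    min_duration: float = 0.25
    max_duration: float = 2.0
    rel_duration_band: tuple = (0.5, 2.0)
    template_fraction: float = 0.75
    nmse_flag: float = 0.30
    abp_peak_target: float = 140.0

    def __post_init__(self) -> None:
        if not (0.0 < self.template_fraction <= 1.0):
            raise ValueError("template_fraction must lie in (0, 1]")
        if min(self.min_systolic, self.min_pulse, self.min_duration,
               self.max_duration, self.nmse_flag, self.abp_peak_target) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class Beat:
    """One beat: [onset, end) sample indices at the envelope rate."""

    onset: int
    end: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.end <= self.onset:
            raise ValueError("beat end must exceed onset")

    def duration(self, fs: float = ENVELOPE_RATE) -> float:
        return (self.end - self.onset) / fs


@dataclass
class BeatRecord:
    onset: int
    duration_s: float
    reasons: tuple
    nmse: float | None
    sqi: float
    flagged: bool


@dataclass
class CandidateReport:
    """Quality assessment of one candidate envelope (one threshold gamma)."""

    gamma: float
    beats: list
    artifact_index: float
    template: np.ndarray | None = None
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_beats(self) -> int:
        return len(self.beats)


def _slope_sum(x: np.ndarray, fs: float, window_s: float = 0.128) -> np.ndarray:
    """Causal slope sum function: windowed sum of positive first differences."""
    du = np.maximum(np.diff(x), 0.0)
    w = max(1, int(round(window_s * fs)))
    ssf = np.convolve(du, np.ones(w))[: du.size]
    return np.concatenate(([0.0], ssf))


def detect_onsets(env: np.ndarray, cfg: QualityConfig = QualityConfig(),
                  fs: float = ENVELOPE_RATE) -> np.ndarray:
    """Beat onsets of a flow velocity waveform, strictly increasing.

    The waveform is first rescaled so its mean per-beat peak is near
    ``cfg.abp_peak_target`` (making the detector scale-invariant), then a
    slope-sum function over a 128 ms window is thresholded adaptively (the
    threshold decays to 40% of the median of the last five accepted SSF
    peaks) with a 250 ms refractory period.  Each threshold crossing is
    mapped back to the beat foot: the latest minimum of the envelope in the
    preceding 200 ms.
    """
    env = np.asarray(env, dtype=float)
    if env.size < int(2 * fs):
        raise ValueError("envelope shorter than 2 s: onset detection undefined")
    peaks, _ = find_peaks(env, distance=max(1, int(round(0.4 * fs))))
    if peaks.size == 0 or np.mean(env[peaks]) <= 0:
        return np.empty(0, dtype=int)
    scaled = env * (cfg.abp_peak_target / np.mean(env[peaks]))
    ssf = _slope_sum(scaled, fs)
    ref = float(np.percentile(ssf, 98))
    if ref < 1.0:  # essentially flat on the rescaled (mmHg-like) scale
        return np.empty(0, dtype=int)
    thr = 0.4 * ref
    refractory = int(round(0.25 * fs))
    search = max(1, int(round(0.15 * fs)))
    back = int(round(0.2 * fs))
    onsets: list[int] = []
    recent: list[float] = []
    last_cross = -10 ** 9
    k = 1
    while k < ssf.size:
        if ssf[k] >= thr and ssf[k - 1] < thr and k - last_cross >= refractory:
            peak_val = float(np.max(ssf[k: k + search]))
            lo = max(0, k - back)
            win = env[lo: k + 1]
            onset = lo + int(np.flatnonzero(win == win.min())[-1])
            if not onsets or onset > onsets[-1]:
                onsets.append(onset)
                last_cross = k
                recent = (recent + [peak_val])[-5:]
                thr = 0.4 * float(np.median(recent))
        k += 1
    return np.asarray(onsets, dtype=int)


def beats_from_onsets(env: np.ndarray, onsets: np.ndarray) -> list:
    """Cut the envelope into beats between consecutive onsets."""
    env = np.asarray(env, dtype=float)
    return [Beat(int(a), int(b), env[int(a): int(b)])
            for a, b in zip(onsets[:-1], onsets[1:])]


def screen_beats(beats: list, cfg: QualityConfig = QualityConfig(),
                 fs: float = ENVELOPE_RATE) -> list:
    """Per-beat failure reason codes (empty tuple = beat passes all screens).

    Codes: 1 systolic maximum too low, 2 pulse amplitude too low, 3 absolute
    duration out of [0.25, 2] s, 4 duration outside (0.5, 2) x the segment's
    median beat duration.
    """
    if not beats:
        raise ValueError("no beats to screen")
    durations = np.array([b.duration(fs) for b in beats])
    med = float(np.median(durations))
    out = []
    for b, d in zip(beats, durations):
        reasons = []
        if np.max(b.samples) <= cfg.min_systolic:
            reasons.append(1)
        if np.ptp(b.samples) <= cfg.min_pulse:
            reasons.append(2)
        if not (cfg.min_duration < d < cfg.max_duration):
            reasons.append(3)
        if not (cfg.rel_duration_band[0] * med < d < cfg.rel_duration_band[1] * med):
            reasons.append(4)
        out.append(tuple(reasons))
    return out


def build_template(valid_beats: list) -> np.ndarray:
    """Median beat template from screened beats.

    Beats are zero-padded to the longest valid beat, the pointwise median is
    taken, and the template is truncated to the median valid-beat duration.
    """
    if not valid_beats:
        raise ValueError("no valid beats: segment unusable for template matching")
    lengths = [b.samples.size for b in valid_beats]
    lmax = max(lengths)
    stack = np.zeros((len(valid_beats), lmax))
    for i, b in enumerate(valid_beats):
        stack[i, : b.samples.size] = b.samples
    template = np.median(stack, axis=0)
    lmed = int(round(float(np.median(lengths))))
    return template[:lmed]


def normalized_mse(beat_samples: np.ndarray, template: np.ndarray,
                   fraction: float = 0.75) -> float:
    """NMSE between a beat and the template over the leading template window.

    The window is the first floor(fraction * len(template)) samples; the
    beat is zero-padded or truncated to it.  NMSE = mean((b-t)^2)/mean(t^2).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    template = np.asarray(template, dtype=float)
    b = np.asarray(beat_samples, dtype=float)
    n = int(np.floor(fraction * template.size))
    if n < 1:
        raise ValueError("template too short for the requested fraction")
    t = template[:n]
    denom = float(np.mean(t ** 2))
    if denom == 0.0:
        raise ValueError("all-zero template window: NMSE undefined")
    bw = np.zeros(n)
    m = min(n, b.size)
    bw[:m] = b[:m]
    return float(np.mean((bw - t) ** 2) / denom)


def assess_quality(env: np.ndarray, onsets: np.ndarray,
                   cfg: QualityConfig = QualityConfig(),
                   gamma: float = float("nan"),
                   fs: float = ENVELOPE_RATE) -> CandidateReport:
    """Full quality assessment of one candidate envelope.

    Screen-failed beats get SQI 0 and are excluded from the template and the
    NMSE comparison but still count in the artifact-index denominator.  A
    segment with no usable beats at all gets artifact index 100%.
    """
    onsets = np.asarray(onsets, dtype=int)
    beats = beats_from_onsets(env, onsets) if onsets.size >= 2 else []
    if not beats:
        return CandidateReport(gamma=gamma, beats=[], artifact_index=100.0,
                               onsets=onsets)
    reasons = screen_beats(beats, cfg, fs)
    valid = [b for b, r in zip(beats, reasons) if not r]
    try:
        template = build_template(valid)
    except ValueError:
        records = [BeatRecord(b.onset, b.duration(fs), r, None, 0.0, True)
                   for b, r in zip(beats, reasons)]
        return CandidateReport(gamma=gamma, beats=records, artifact_index=100.0,
                               onsets=onsets)
    records = []
    n_flagged = 0
    for b, r in zip(beats, reasons):
        if r:
            records.append(BeatRecord(b.onset, b.duration(fs), r, None, 0.0, True))
            n_flagged += 1
            continue
        nmse = normalized_mse(b.samples, template, cfg.template_fraction)
        flagged = nmse > cfg.nmse_flag
        sqi = 100.0 * max(0.0, 1.0 - nmse)
        n_flagged += int(flagged)
        records.append(BeatRecord(b.onset, b.duration(fs), r, nmse, sqi, flagged))
    artifact_index = 100.0 * n_flagged / len(beats)
    return CandidateReport(gamma=gamma, beats=records, artifact_index=artifact_index,
                           template=template, onsets=onsets)


def select_best_candidate(reports: list, gamma_otsu: float) -> CandidateReport:
    """Candidate with the minimal artifact index.

    Ties are broken by the threshold closest to gamma_otsu, then by the
    smaller threshold.
    """
    if not reports:
        raise ValueError("no candidates to select from")
    return min(reports, key=lambda r: (r.artifact_index,
                                       abs(r.gamma - gamma_otsu), r.gamma))
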
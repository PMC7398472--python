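"""End-to-end maximal flow velocity estimation with quality feedback.

Per 60 s spectrogram segment the pipeline

1. picks the signal-carrying flow direction (positive or negative band),
2. computes an Otsu threshold on the flow band and a multiplicative grid of
   candidate thresholds around it,
3. for each threshold: binarises, despeckles, traces the envelope and scores
   it with the beat-quality module,
4. keeps the candidate with the smallest artifact index, and
5. post-processes the winner (zero-phase 4th-order Butterworth low-pass at
   16 Hz followed by a 3-sample median) and restores the flow sign.

Segments are non-overlapping; a trailing partial segment shorter than 10 s
is merged into the previous one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .beat_quality import (QualityConfig, assess_quality, detect_onsets,
                           select_best_candidate)
from .segmentation import (DEFAULT_MULTIPLIERS, binarize, despeckle,
                           make_threshold_grid, otsu_threshold)
from .spectrogram import (IQSignal, Spectrogram, StftConfig, compute_spectrogram,
                          oriented_magnitude, select_flow_region, wall_filter)
from .tracer import TracerConfig, trace_envelope

__all__ = ["PipelineConfig", "EnvelopeTrace", "SegmentResult",
           "postprocess_envelope", "estimate_envelope", "estimate_envelope_from_iq"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the segment loop in one place."""

    segment_length: float = 60.0
    min_tail: float = 10.0
    stft: StftConfig = field(default_factory=StftConfig)
    tracer: TracerConfig = field(default_factory=TracerConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    grid_multipliers: tuple = DEFAULT_MULTIPLIERS
    wall_cutoff: float = 100.0
    post_cutoff: float = 16.0
    post_order: int = 4
    post_median: int = 3

    def __post_init__(self) -> None:
        if self.segment_length < 2.0:
            raise ValueError("segment_length must be >= 2 s")
        if self.post_median % 2 != 1:
            raise ValueError("post_median must be odd")


@dataclass
class SegmentResult:
    segment_id: int
    start_col: int
    stop_col: int
    flow_sign: int
    gamma_otsu: float
    gamma_grid: tuple
    candidates: list            # CandidateReport per gamma
    selected: object            # winning CandidateReport
    raw_velocities: np.ndarray  # magnitude scale, before post-processing
    velocities: np.ndarray      # signed, post-processed
    usable: bool


@dataclass
class EnvelopeTrace:
    """Final signed envelope with per-sample quality annotations."""

    times: np.ndarray
    velocities: np.ndarray
    sqi: np.ndarray
    artifact: np.ndarray
    segment_id: np.ndarray
    gamma_selected: np.ndarray
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.times.size
        for name in ("velocities", "sqi", "artifact", "segment_id", "gamma_selected"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must match times length")
        if self.sqi.size and (self.sqi.min() < -1e-9 or self.sqi.max() > 100 + 1e-9):
            raise ValueError("sqi must lie in [0, 100]")


def postprocess_envelope(raw: np.ndarray, fs: float = 217.0, cutoff: float = 16.0,
                         order: int = 4, median: int = 3) -> np.ndarray:
    """Low-pass and median filter the raw envelope.

    The short median filter rejects isolated single-sample outliers first
    (a low-pass would smear them into multi-sample bumps the median can no
    longer remove); the zero-phase Butterworth (order ``order``, cutoff
    ``cutoff`` Hz) then removes rapid oscillations attributable to noise.
    Length is preserved.
    """
    raw = np.asarray(raw, dtype=float)
    b, a = sps.butter(order, cutoff / (fs / 2.0), btype="lowpass")
    padlen = 3 * max(len(a), len(b))
    if raw.size <= padlen:
        raise ValueError(f"envelope too short for post-filter ({raw.size} <= {padlen})")
    despiked = sps.medfilt(raw, kernel_size=median)
    return sps.filtfilt(b, a, despiked)


def _segment_bounds(n_cols: int, cols_per_seg: int, min_tail_cols: int) -> list:
    bounds = []
    start = 0
    while start < n_cols:
        stop = min(start + cols_per_seg, n_cols)
        bounds.append((start, stop))
        start = stop
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < min_tail_cols:
        last = bounds.pop()
        prev = bounds.pop()
        bounds.append((prev[0], last[1]))
    return bounds


def _per_sample_quality(n: int, start: int, report) -> tuple[np.ndarray, np.ndarray]:
    """Broadcast beat SQI/flags over the segment's samples.

    Samples before the first onset and after the last take the nearest
    beat's values; an unusable segment is all-artifact with SQI 0.
    """
    sqi = np.zeros(n)
    art = np.ones(n, dtype=bool)
    if not report.beats:
        return sqi, art
    edges = [b.onset - start for b in report.beats]
    ends = [edges[i + 1] if i + 1 < len(edges) else None for i in range(len(edges))]
    for i, b in enumerate(report.beats):
        lo = 0 if i == 0 else edges[i]
        hi = n if ends[i] is None else ends[i]
        hi = n if i == len(report.beats) - 1 else hi
        lo, hi = max(0, lo), min(n, hi)
        sqi[lo:hi] = b.sqi
        art[lo:hi] = b.flagged
    return sqi, art


def estimate_envelope(sp: Spectrogram,
                      cfg: PipelineConfig = PipelineConfig()) -> EnvelopeTrace:
    """Run the full quality-feedback loop on a spectrogram.

    Deterministic: identical input yields identical output.  Segments in
    which every candidate scores 100% artifacts are still emitted (best
    available candidate, all samples flagged).
    """
    dt = sp.dt
    fs_env = 1.0 / dt
    cols_per_seg = int(round(cfg.segment_length / dt))
    min_tail_cols = int(round(cfg.min_tail / dt))
    bounds = _segment_bounds(sp.n_cols, cols_per_seg, min_tail_cols)

    segments = []
    for seg_id, (c0, c1) in enumerate(bounds):
        sub = sp.time_slice(c0, c1)
        region = select_flow_region(sub)
        intensity, vmag = oriented_magnitude(sub, region.sign)
        band = (vmag >= region.v_low) & (vmag <= region.v_high)
        gamma_otsu = otsu_threshold(intensity[band])
        grid = make_threshold_grid(gamma_otsu, cfg.grid_multipliers)
        reports = []
        raw_by_gamma = {}
        for gamma in grid.thresholds:
            mask = despeckle(binarize(intensity, gamma), dt, sp.dv)
            raw = trace_envelope(mask, vmag, cfg.tracer)
            try:
                onsets = detect_onsets(raw.velocities, cfg.quality, fs_env)
            except ValueError:
                onsets = np.empty(0, dtype=int)
            onsets_abs = onsets + c0
            rep = assess_quality(raw.velocities, onsets, cfg.quality, gamma, fs_env)
            for b in rep.beats:
                b.onset += c0
            rep.onsets = onsets_abs
            reports.append(rep)
            raw_by_gamma[gamma] = raw
        selected = select_best_candidate(reports, gamma_otsu)
        raw_sel = raw_by_gamma[selected.gamma]
        post = postprocess_envelope(raw_sel.velocities, fs_env, cfg.post_cutoff,
                                    cfg.post_order, cfg.post_median)
        segments.append(SegmentResult(
            segment_id=seg_id, start_col=c0, stop_col=c1, flow_sign=region.sign,
            gamma_otsu=gamma_otsu, gamma_grid=grid.thresholds, candidates=reports,
            selected=selected, raw_velocities=raw_sel.velocities,
            velocities=region.sign * post,
            usable=selected.artifact_index < 100.0))

    n = sp.n_cols
    velocities = np.zeros(n)
    sqi = np.zeros(n)
    artifact = np.ones(n, dtype=bool)
    seg_ids = np.zeros(n, dtype=int)
    gammas = np.zeros(n)
    for seg in segments:
        sl = slice(seg.start_col, seg.stop_col)
        velocities[sl] = seg.velocities
        s, a = _per_sample_quality(seg.stop_col - seg.start_col, seg.start_col,
                                   seg.selected)
        sqi[sl] = s
        artifact[sl] = a
        seg_ids[sl] = seg.segment_id
        gammas[sl] = seg.selected.gamma
    return EnvelopeTrace(times=sp.times.copy(), velocities=velocities, sqi=sqi,
                         artifact=artifact, segment_id=seg_ids,
                         gamma_selected=gammas, segments=segments)


def estimate_envelope_from_iq(iq: IQSignal,
                              cfg: PipelineConfig = PipelineConfig()) -> EnvelopeTrace:
    """Wall-filter the IQ signal, compute its spectrogram and trace it."""
    filtered = wall_filter(iq, cfg.wall_cutoff)
    sp = compute_spectrogram(filtered, cfg.stft)
    return estimate_envelope(sp, cfg)
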
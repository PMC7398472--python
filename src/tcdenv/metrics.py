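"""Agreement metrics between an estimated and a reference envelope.

Sample-wise: for error e[n] = v_algo[n] - v_ref[n] the bias is the mean of
e, the error spread is the population standard deviation of e, and the
relative error is sum(e)/sum(v_ref).  Beat-wise the same three statistics
are computed on peak-systolic velocity differences, together with the
(mean, difference) pairs used for Bland-Altman plots.  Negative-flow traces
(e.g. internal carotid) are sign-flipped before comparison so positive and
negative flows share one scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WaveformErrors", "PeakErrors", "align_signs", "waveform_errors",
           "peak_errors", "pair_onsets", "beat_peaks"]


@dataclass(frozen=True)
class WaveformErrors:
    n_samples: int
    bias: float        # m_e, cm/s
    error_sd: float    # sigma_e, cm/s (population)
    relative_error: float  # r_e, dimensionless


@dataclass(frozen=True)
class PeakErrors:
    n_beats: int
    bias: float        # m_peak, cm/s
    error_sd: float    # sigma_peak, cm/s (population)
    relative_error: float
    bland_altman: np.ndarray  # (n_beats, 2): (pair mean, pair difference)


def align_signs(v_algo: np.ndarray, v_ref: np.ndarray,
                rel_tol: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Flip both series positive if the reference flow is negative.

    A reference whose mean is near zero relative to its magnitude indicates
    sign-crossing (reverse) flow, which this comparison cannot represent.
    """
    v_algo = np.asarray(v_algo, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    if v_algo.shape != v_ref.shape:
        raise ValueError("series must have equal length")
    scale = float(np.mean(np.abs(v_ref)))
    mean = float(np.mean(v_ref))
    if scale > 0 and abs(mean) < rel_tol * scale:
        raise ValueError("mixed-sign reference: reverse flow is unsupported")
    if mean < 0:
        return -v_algo, -v_ref
    return v_algo, v_ref


def waveform_errors(v_algo: np.ndarray, v_ref: np.ndarray) -> WaveformErrors:
    """Sample-wise bias, population error SD and relative error."""
    v_algo = np.asarray(v_algo, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    if v_algo.shape != v_ref.shape or v_algo.size < 1:
        raise ValueError("series must be non-empty and of equal length")
    e = v_algo - v_ref
    m = float(np.mean(e))
    sd = float(np.sqrt(np.mean((e - m) ** 2)))
    denom = float(np.sum(v_ref))
    if denom == 0.0:
        raise ValueError("reference sums to zero: relative error undefined")
    return WaveformErrors(n_samples=e.size, bias=m, error_sd=sd,
                          relative_error=float(np.sum(e)) / denom)


def peak_errors(peaks_algo: np.ndarray, peaks_ref: np.ndarray) -> PeakErrors:
    """Beat-wise peak-systolic difference statistics plus Bland-Altman pairs."""
    pa = np.asarray(peaks_algo, dtype=float)
    pm = np.asarray(peaks_ref, dtype=float)
    if pa.shape != pm.shape or pa.size < 1:
        raise ValueError("peak arrays must be non-empty and of equal length")
    d = pa - pm
    m = float(np.mean(d))
    sd = float(np.sqrt(np.mean((d - m) ** 2)))
    denom = float(np.sum(pm))
    if denom == 0.0:
        raise ValueError("reference peaks sum to zero: relative error undefined")
    ba = np.column_stack([(pa + pm) / 2.0, d])
    return PeakErrors(n_beats=d.size, bias=m, error_sd=sd,
                      relative_error=float(np.sum(d)) / denom, bland_altman=ba)


def pair_onsets(onsets_a: np.ndarray, onsets_b: np.ndarray,
                tol_s: float = 0.3, fs: float = 217.0) -> tuple[list, int]:
    """Greedy nearest-onset matching within a time tolerance.

    Returns (pairs, n_unmatched) where pairs are (index_a, index_b) tuples;
    beats with no partner within ``tol_s`` are excluded and counted.
    """
    a = np.asarray(onsets_a, dtype=float)
    b = np.asarray(onsets_b, dtype=float)
    tol = tol_s * fs
    pairs = []
    used_b: set[int] = set()
    for i, oa in enumerate(a):
        if b.size == 0:
            break
        j = int(np.argmin(np.abs(b - oa)))
        if j not in used_b and abs(b[j] - oa) <= tol:
            pairs.append((i, j))
            used_b.add(j)
    n_unmatched = (a.size - len(pairs)) + (b.size - len(pairs))
    return pairs, n_unmatched


def beat_peaks(env: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    """Peak-systolic velocity per beat (maximum between consecutive onsets)."""
    env = np.asarray(env, dtype=float)
    onsets = np.asarray(onsets, dtype=int)
    return np.array([float(np.max(env[a:b]))
                     for a, b in zip(onsets[:-1], onsets[1:])])
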
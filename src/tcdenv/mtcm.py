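"""Modified threshold crossing method (MTCM) baseline envelope estimator.

A classical fixed-threshold approach: per spectrogram column a group of
spectral samples slides from the high-velocity (noise) end toward zero, and
the first group in which enough samples exceed a preset intensity threshold
defines the maximal velocity as the group's highest-velocity bin.  Simple and
waveform-agnostic, but its performance depends entirely on the manually
chosen threshold, which is held constant over the whole segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrogram import FlowRegion, Spectrogram, oriented_magnitude
from .tracer import RawEnvelope

__all__ = ["MTCMConfig", "mtcm_envelope"]


@dataclass(frozen=True)
class MTCMConfig:
    """Group geometry and the fixed intensity threshold.

    group_size : spectral samples per sliding group.
    min_exceed : samples in the group that must exceed the threshold.
    threshold : fixed intensity threshold T, constant over the segment.
    noise_rows : top-velocity rows regarded as the noise floor (informational;
        the classical recipe derives T from their statistics by hand).
    """

    group_size: int = 10
    min_exceed: int = 5
    threshold: float = 0.5
    noise_rows: int = 20

    def __post_init__(self) -> None:
        if not (1 <= self.min_exceed <= self.group_size):
            raise ValueError("min_exceed must lie in [1, group_size]")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


def mtcm_envelope(sp: Spectrogram, region: FlowRegion,
                  cfg: MTCMConfig = MTCMConfig()) -> RawEnvelope:
    """Trace the envelope with the MTCM rule on the magnitude-oriented band.

    Per column, groups of ``group_size`` adjacent velocity bins are examined
    from the high-velocity end downward; the first group with at least
    ``min_exceed`` intensities above ``cfg.threshold`` sets the envelope to
    the velocity of the group's top bin.  Columns with no qualifying group
    get 0.  Output is on the magnitude scale (the caller restores the flow
    sign), deterministic, and monotone in the threshold.
    """
    intensity, vmag = oriented_magnitude(sp, region.sign)
    band = (vmag >= region.v_low) & (vmag <= region.v_high)
    sub = intensity[band]
    vels = vmag[band]
    n_rows, n_cols = sub.shape
    g = cfg.group_size
    if n_rows < g:
        raise ValueError("flow band has fewer rows than the MTCM group size")
    exceed = (sub > cfg.threshold).astype(np.int32)
    csum = np.zeros((n_rows + 1, n_cols), dtype=np.int32)
    np.cumsum(exceed, axis=0, out=csum[1:])
    # counts[t, c] = exceed count in rows [t-g+1, t] for top row t >= g-1
    tops = np.arange(g - 1, n_rows)
    counts = csum[tops + 1] - csum[tops - g + 1]
    ok = counts >= cfg.min_exceed
    # highest qualifying top row per column
    rev = ok[::-1]
    first = np.argmax(rev, axis=0)
    any_ok = rev[first, np.arange(n_cols)]
    top_rows = tops[ok.shape[0] - 1 - first]
    env = np.where(any_ok, vels[top_rows], 0.0)
    zeros = np.zeros(n_cols, dtype=bool)
    return RawEnvelope(env, zeros, zeros)
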
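"""Column-by-column envelope tracing on a binarised spectrogram.

The maximal flow velocity at each time step is the highest white pixel that
survives two physiological sanity checks:

1. *support*: the majority of the 40 velocity bins (~12 cm/s) directly below
   the candidate must be white, so isolated speckle is not mistaken for the
   envelope;
2. *continuity*: the candidate may not deviate by more than 30 cm/s from the
   mean of the previous three estimates (~14 ms at 217 Hz).

If no candidate passes, the previous value is held; if that happens for more
than 20 consecutive columns the maximal candidate is taken regardless, which
lets the trace re-lock after genuine step changes or signal loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TracerConfig", "RawEnvelope", "column_candidates", "trace_envelope"]


@dataclass(frozen=True)
class TracerConfig:
    """Constants of the envelope-following sanity checks.

    n_candidates : white pixels examined per column, top-down.
    support_bins / support_majority : size and pass fraction of the support
        window below a candidate (strictly more than the fraction must be
        white).
    max_step_dev : cm/s, continuity limit against the lookback mean.
    lookback : samples averaged for the continuity reference.
    override_after : consecutive failed columns before the forced take.
    v_start : cm/s, velocity from which the downward candidate scan starts.
    band_floor : cm/s, wall-filter stop band edge; support bins below it
        count as white so low-velocity edges are not unfairly rejected.
    """

    n_candidates: int = 5
    support_bins: int = 40
    support_majority: float = 0.5
    max_step_dev: float = 30.0
    lookback: int = 3
    override_after: int = 20
    v_start: float = 152.0
    band_floor: float = 5.0

    def __post_init__(self) -> None:
        if min(self.n_candidates, self.support_bins, self.lookback,
               self.override_after) <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 < self.support_majority <= 1.0):
            raise ValueError("support_majority must lie in (0, 1]")
        if self.max_step_dev <= 0 or self.v_start <= 0:
            raise ValueError("max_step_dev and v_start must be positive")


@dataclass
class RawEnvelope:
    """Per-column maximal velocity (magnitude scale) with tracing flags."""

    velocities: np.ndarray
    held: np.ndarray
    override: np.ndarray

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.held = np.asarray(self.held, dtype=bool)
        self.override = np.asarray(self.override, dtype=bool)
        if not (self.velocities.shape == self.held.shape == self.override.shape):
            raise ValueError("velocities and flags must have equal length")

    def __len__(self) -> int:
        return self.velocities.size


def _candidate_rows(col: np.ndarray, start_row: int, n: int) -> np.ndarray:
    """Row indices of the top-n white pixels at/below start_row, descending."""
    rows = np.flatnonzero(col[: start_row + 1])
    return rows[::-1][:n]


def column_candidates(mask_column: np.ndarray, velocities: np.ndarray,
                      cfg: TracerConfig = TracerConfig()) -> np.ndarray:
    """Candidate velocities of one column, strictly descending.

    Scans downward from ``cfg.v_start`` and returns the velocities of up to
    ``cfg.n_candidates`` white pixels; an all-black column yields an empty
    array.
    """
    col = np.asarray(mask_column, dtype=bool)
    velocities = np.asarray(velocities, dtype=float)
    start_row = int(np.searchsorted(velocities, cfg.v_start, side="right")) - 1
    if start_row < 0:
        return np.empty(0)
    return velocities[_candidate_rows(col, start_row, cfg.n_candidates)]


def trace_envelope(mask: np.ndarray, velocities: np.ndarray,
                   cfg: TracerConfig = TracerConfig()) -> RawEnvelope:
    """Trace the maximal-velocity envelope of a despeckled magnitude mask.

    ``mask`` is (n_velocity_bins, n_columns) with velocities ascending from
    ~0 to v_max.  Per column the highest candidate passing both sanity checks
    is taken; the continuity check is skipped for the first ``lookback``
    columns (no history).  Columns where every candidate fails are held at
    the previous value (``held`` flag); after more than ``override_after``
    consecutive failures the maximal candidate is taken regardless
    (``override`` flag) and the failure counter resets.  An all-black column
    during an override keeps holding and leaves the counter saturated.
    """
    mask = np.asarray(mask, dtype=bool)
    velocities = np.asarray(velocities, dtype=float)
    if mask.ndim != 2 or mask.shape[0] != velocities.size:
        raise ValueError("mask must be (len(velocities), n_columns)")
    n_rows, n_cols = mask.shape
    if n_cols == 0:
        raise ValueError("mask has no columns to trace")

    start_row = int(np.searchsorted(velocities, cfg.v_start, side="right")) - 1
    floor_row = int(np.searchsorted(velocities, cfg.band_floor, side="left"))
    need = int(np.floor(cfg.support_bins * cfg.support_majority)) + 1  # strict majority

    # prefix sums per column: csum[r, c] = # white pixels in rows [0, r) of column c
    csum = np.zeros((n_rows + 1, n_cols), dtype=np.int32)
    np.cumsum(mask, axis=0, out=csum[1:])

    env = np.zeros(n_cols)
    held = np.zeros(n_cols, dtype=bool)
    override = np.zeros(n_cols, dtype=bool)
    fail = 0

    def support_ok(r: int, c: int) -> bool:
        lo = r - cfg.support_bins
        virtual = max(0, min(r, floor_row) - lo)  # below array or below band floor
        lo_real = max(lo, floor_row, 0)
        white = int(csum[r, c] - csum[min(lo_real, r), c]) if r > lo_real else 0
        return virtual + white >= need

    for k in range(n_cols):
        cand = _candidate_rows(mask[:, k], start_row, cfg.n_candidates)
        chosen = -1
        for r in cand:
            if not support_ok(int(r), k):
                continue
            if k >= cfg.lookback:
                ref = env[k - cfg.lookback:k].mean()
                if abs(velocities[r] - ref) > cfg.max_step_dev:
                    continue
            chosen = int(r)
            break
        if chosen >= 0:
            env[k] = velocities[chosen]
            fail = 0
        else:
            fail += 1
            if fail > cfg.override_after and cand.size > 0:
                env[k] = velocities[int(cand[0])]
                override[k] = True
                fail = 0
            else:
                env[k] = env[k - 1] if k > 0 else 0.0
                held[k] = True
                if fail > cfg.override_after:
                    fail = cfg.override_after + 1  # stay saturated until pixels return
    return RawEnvelope(env, held, override)
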
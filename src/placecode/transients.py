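"""Significant calcium-transient detection and distance-normalised activity.

The detector follows the iterative baseline-exclusion scheme standard for
sparse calcium data: a transient starts when the (zero-phase low-pass
filtered) ΔF/F trace rises ``start_k`` baseline standard deviations above a
rolling-mean baseline and ends when it drops back below ``end_k`` sigma.
Detected transients are excluded and the baseline and sigma re-estimated,
iterating three times so large events do not inflate the noise estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import InvalidInputError, UndefinedActivityError
from .session import Session

__all__ = ["TransientSet", "lowpass_filter", "detect_transients",
           "compute_activity"]


@dataclass
class TransientSet:
    """Detected significant transients for a population of traces."""

    intervals: list[list[tuple[int, int]]]  # per neuron, (start, end) end-exclusive
    peaks: list[np.ndarray]                 # per neuron, peak ΔF/F per transient
    integrals: list[np.ndarray]             # per neuron, ΔF/F·s per transient
    masked: np.ndarray                      # trace inside transients, 0 elsewhere
    baseline: np.ndarray                    # final rolling-mean baseline
    sigma: np.ndarray                       # (n_iter, n_neurons) noise sd estimates
    frame_rate: float
    degenerate: np.ndarray = field(default=None)  # constant-trace flags

    @property
    def n_neurons(self) -> int:
        return self.masked.shape[0]

    def final_sigma(self) -> np.ndarray:
        return self.sigma[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per transient."""
        rows = []
        dt = 1.0 / self.frame_rate
        for n, ivs in enumerate(self.intervals):
            for j, (s, e) in enumerate(ivs):
                rows.append({"neuron": n, "start_s": s * dt, "end_s": e * dt,
                             "peak": self.peaks[n][j],
                             "integral": self.integrals[n][j]})
        return pd.DataFrame(rows,
                            columns=["neuron", "start_s", "end_s", "peak",
                                     "integral"])


def lowpass_filter(dff: np.ndarray, frame_rate: float,
                   cutoff: float = 2.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forwards and backwards)."""
    if cutoff >= frame_rate / 2.0:
        raise InvalidInputError("cutoff must be below the Nyquist frequency")
    if cutoff <= 0:
        raise InvalidInputError("cutoff must be positive")
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    b, a = butter(order, cutoff, fs=frame_rate)
    return filtfilt(b, a, dff, axis=-1)


def _find_runs(resid: np.ndarray, hi: float, lo: float,
               min_frames: int) -> list[tuple[int, int]]:
    """Hysteresis run detection.

    A run is a maximal stretch with ``resid >= lo`` that contains at least
    one sample ``> hi``; its start is the first sample above ``hi`` (onset
    defined by the high threshold), its end the first sample below ``lo``.
    """
    above_lo = resid >= lo
    if not above_lo.any():
        return []
    padded = np.concatenate(([False], above_lo, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    out = []
    for rs, re in zip(run_starts, run_ends):
        seg = resid[rs:re]
        over = np.flatnonzero(seg > hi)
        if over.size == 0:
            continue
        start = rs + int(over[0])
        if re - start >= min_frames:
            out.append((start, int(re)))
    return out


def detect_transients(
    filtered_dff: np.ndarray,
    frame_rate: float,
    start_k: float = 2.0,
    end_k: float = 0.5,
    n_iter: int = 3,
    baseline_window_s: float = 30.0,
    min_duration_s: float = 0.2,
) -> TransientSet:
    """Detect significant transients by iterative baseline re-estimation.

    Per iteration the rolling-mean baseline and the residual sd ``sigma``
    are computed from the transient-excluded trace (iteration 1 uses the
    full trace), then transients are re-marked as runs that rise above
    ``baseline + start_k*sigma`` and end below ``baseline + end_k*sigma``.
    Runs shorter than ``min_duration_s`` are discarded as single-frame
    noise crossings. A constant trace yields no transients and is flagged
    degenerate instead of raising.
    """
    x = np.atleast_2d(np.asarray(filtered_dff, dtype=float))
    n_neurons, n_frames = x.shape
    window = int(round(baseline_window_s * frame_rate))
    if window >= n_frames:
        raise InvalidInputError("trace shorter than the baseline window")
    window = max(window, 1)
    min_frames = max(int(round(min_duration_s * frame_rate)), 1)

    intervals: list[list[tuple[int, int]]] = []
    peaks, integrals = [], []
    masked = np.zeros_like(x)
    baseline_out = np.zeros_like(x)
    sigma = np.zeros((n_iter, n_neurons))
    degenerate = np.zeros(n_neurons, dtype=bool)
    dt = 1.0 / frame_rate

    for i in range(n_neurons):
        trace = x[i]
        mask = np.zeros(n_frames, dtype=bool)  # True inside transients
        ivs: list[tuple[int, int]] = []
        baseline = np.full(n_frames, trace.mean())
        for it in range(n_iter):
            excluded = np.where(mask, np.nan, trace)
            baseline = (
                pd.Series(excluded)
                .rolling(window, center=True, min_periods=1)
                .mean()
                .to_numpy()
            )
            # frames whose whole window was masked: fall back to global mean
            nanb = np.isnan(baseline)
            if nanb.any():
                baseline[nanb] = np.nanmean(excluded)
            resid = trace - baseline
            quiet = resid[~mask]
            s = float(np.std(quiet)) if quiet.size else 0.0
            sigma[it, i] = s
            if s == 0.0:
                degenerate[i] = True
                ivs = []
                mask[:] = False
                break
            ivs = _find_runs(resid, start_k * s, end_k * s, min_frames)
            mask[:] = False
            for st, en in ivs:
                mask[st:en] = True
        intervals.append(ivs)
        baseline_out[i] = baseline
        masked[i, mask] = trace[mask]
        if ivs:
            peaks.append(np.array([trace[s:e].max() for s, e in ivs]))
            integrals.append(np.array([trace[s:e].sum() * dt for s, e in ivs]))
        else:
            peaks.append(np.empty(0))
            integrals.append(np.empty(0))

    return TransientSet(intervals=intervals, peaks=peaks, integrals=integrals,
                        masked=masked, baseline=baseline_out, sigma=sigma,
                        frame_rate=frame_rate, degenerate=degenerate)


def compute_activity(tset: TransientSet, session: Session) -> np.ndarray:
    """Per-neuron activity: integrated significant-transient ΔF/F per cm.

    The significant-transient trace (ΔF/F inside detected transients, zero
    elsewhere) is summed over the session, converted to ΔF/F·s, and divided
    by the total distance travelled.
    """
    distance = session.total_distance
    if distance <= 0:
        raise UndefinedActivityError("total distance travelled is zero")
    return tset.masked.sum(axis=1) / tset.frame_rate / distance
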
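"""Session data model and treadmill telemetry handling.

A :class:`Session` is the unit of analysis everywhere in this package: a set
of per-frame arrays (fluorescence, ΔF/F, optional deconvolved rates) aligned
with the reconstructed position of the mouse on a circular treadmill belt.

Conventions used throughout:

* positions are 0-based centimetres on the half-open circular interval
  ``[0, belt_length)``;
* the corresponding angle is ``theta = 2*pi*x / belt_length``;
* frame times are seconds, strictly increasing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InvalidInputError,
    SchemaVersionError,
    UnknownTagError,
)

SCHEMA_VERSION = 1

__all__ = [
    "Session",
    "PositionTrace",
    "reconstruct_position",
    "compute_dff",
    "bin_position",
    "read_session",
    "write_session",
]


@dataclass
class PositionTrace:
    """Raw treadmill telemetry prior to position reconstruction.

    Parameters
    ----------
    ticks : ndarray
        Encoder increments per telemetry sample, already converted to
        centimetre-equivalents (cm of belt travel per sample).
    sample_times : ndarray
        Time of each telemetry sample (s), strictly increasing.
    frame_times : ndarray
        Time of each imaging frame (s), strictly increasing.
    rfid_events : list of (sample_index, tag_id, position_cm)
        Tag reads fired when the belt crosses a texture boundary. The third
        element is the registered belt position of the tag; ``nan`` marks an
        unregistered tag (an error at reconstruction time).
    """

    ticks: np.ndarray
    sample_times: np.ndarray
    frame_times: np.ndarray
    rfid_events: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ticks = np.asarray(self.ticks, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.ticks.shape != self.sample_times.shape:
            raise InvalidInputError("ticks and sample_times must align")
        for name, t in (("sample_times", self.sample_times),
                        ("frame_times", self.frame_times)):
            if t.size and np.any(np.diff(t) <= 0):
                raise InvalidInputError(f"{name} must be strictly increasing")
        if not np.all(np.isfinite(self.ticks)):
            raise InvalidInputError("encoder increments must be finite")


@dataclass
class Session:
    """Aligned per-frame traces plus position/lap annotation.

    ``dff`` is the primary signal (ΔF/F, dimensionless); ``raw_f`` and
    ``rates`` are optional until the corresponding pipeline stages run.
    """

    dff: np.ndarray
    frame_times: np.ndarray
    position: np.ndarray
    lap_index: np.ndarray
    belt_length: float
    frame_rate: float
    raw_f: Optional[np.ndarray] = None
    rates: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.lap_index = np.asarray(self.lap_index, dtype=int)
        n = self.dff.shape[1]
        for name, arr in (("frame_times", self.frame_times),
                          ("position", self.position),
                          ("lap_index", self.lap_index)):
            if arr.shape != (n,):
                raise InvalidInputError(
                    f"{name} has length {arr.shape}, expected ({n},)")
        if np.any(np.diff(self.frame_times) <= 0):
            raise InvalidInputError("frame_times must be strictly increasing")
        if np.any((self.position < 0) | (self.position >= self.belt_length)):
            raise InvalidInputError(
                "position must lie in [0, belt_length)")
        if np.any(np.diff(self.lap_index) < 0):
            raise InvalidInputError("lap_index must be non-decreasing")
        if self.raw_f is not None:
            self.raw_f = np.atleast_2d(np.asarray(self.raw_f, dtype=float))
            if self.raw_f.shape != self.dff.shape:
                raise InvalidInputError("raw_f must match dff shape")
        if self.rates is not None:
            self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
            if self.rates.shape != self.dff.shape:
                raise InvalidInputError("rates must match dff shape")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def unwrapped_position(self) -> np.ndarray:
        """Monotone position (cm) obtained by undoing belt wraps."""
        return self.position + self.lap_index * self.belt_length

    @property
    def total_distance(self) -> float:
        u = self.unwrapped_position
        return float(u[-1] - u[0])

    @property
    def speed(self) -> np.ndarray:
        """Instantaneous speed (cm/s) from the unwrapped position."""
        return np.gradient(self.unwrapped_position, self.frame_times)

    @property
    def theta(self) -> np.ndarray:
        """Angular position in radians on [0, 2*pi)."""
        return 2.0 * np.pi * self.position / self.belt_length


def reconstruct_position(
    trace: PositionTrace,
    belt_length: float,
    drift_correction: str = "reset",
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct per-frame belt position from encoder ticks and RFID tags.

    The running estimate is the cumulative sum of the encoder increments. At
    every RFID event the estimate is snapped to the tag's registered belt
    position (choosing the lap count that minimises the correction), which
    bounds the accumulated encoder drift by the inter-tag spacing.

    Parameters
    ----------
    drift_correction : {"reset", "linear"}
        ``"reset"`` applies each correction as a step at the event sample
        (default); ``"linear"`` back-distributes it linearly over the samples
        since the previous event.

    Returns
    -------
    position : ndarray
        Per-frame position on ``[0, belt_length)``.
    lap_index : ndarray
        Per-frame lap counter starting at 0, incrementing at each wrap.
    """
    if trace.frame_times.size < 1:
        raise InvalidInputError("need at least one frame")
    if drift_correction not in ("reset", "linear"):
        raise InvalidInputError(f"unknown drift_correction {drift_correction!r}")

    unwrapped = np.cumsum(trace.ticks)
    events = sorted(trace.rfid_events, key=lambda e: e[0])
    prev_idx = 0
    for sample_idx, tag_id, tag_pos in events:
        if tag_pos is None or not np.isfinite(tag_pos):
            raise UnknownTagError(f"RFID tag {tag_id!r} has no registered position")
        if not 0 <= tag_pos < belt_length:
            raise InvalidInputError("tag position outside [0, belt_length)")
        u = unwrapped[sample_idx]
        target = tag_pos + belt_length * np.round((u - tag_pos) / belt_length)
        delta = target - u
        if drift_correction == "reset":
            unwrapped[sample_idx:] += delta
        else:
            span = sample_idx - prev_idx
            if span > 0:
                ramp = np.linspace(delta / span, delta, span)
                unwrapped[prev_idx + 1:sample_idx + 1] += ramp
            else:
                unwrapped[sample_idx] += delta
            unwrapped[sample_idx + 1:] += delta
        prev_idx = sample_idx

    # Encoder is a counter: resample by last observation carried forward.
    idx = np.searchsorted(trace.sample_times, trace.frame_times, side="right") - 1
    u_frames = np.where(idx >= 0, unwrapped[np.clip(idx, 0, None)], 0.0)
    laps = np.floor(u_frames / belt_length).astype(int)
    laps -= laps[0]
    laps = np.maximum.accumulate(np.maximum(laps, 0))
    position = np.mod(u_frames, belt_length)
    return position, laps


def compute_dff(
    raw_f: np.ndarray,
    neuropil: Optional[np.ndarray] = None,
    frame_rate: float = 15.0,
    neuropil_r: float = 0.7,
    baseline_window_s: float = 60.0,
    baseline_percentile: float = 10.0,
    f0_floor: float = 1e-6,
) -> np.ndarray:
    """ΔF/F from raw fluorescence with a rolling-percentile baseline.

    ``dff = (F - r*F_neu - F0) / F0`` where ``F0`` is a centred rolling
    10th-percentile of the neuropil-subtracted trace (window 60 s by
    default) floored at a small positive constant. When no neuropil trace is
    given the coefficient is effectively 0.

    All-zero traces produce all-zero ΔF/F with a warning rather than an
    exception, so a dead ROI does not abort a batch.
    """
    raw_f = np.atleast_2d(np.asarray(raw_f, dtype=float))
    if not np.all(np.isfinite(raw_f)):
        raise InvalidInputError("raw fluorescence must be finite")
    n_frames = raw_f.shape[1]
    window = int(round(baseline_window_s * frame_rate))
    if window >= n_frames:
        raise InvalidInputError("baseline window must be shorter than the session")
    window = max(window, 1)

    f = raw_f.copy()
    if neuropil is not None:
        neuropil = np.atleast_2d(np.asarray(neuropil, dtype=float))
        if neuropil.shape != raw_f.shape:
            raise InvalidInputError("neuropil must match raw_f shape")
        f = f - neuropil_r * neuropil

    dff = np.zeros_like(f)
    q = baseline_percentile / 100.0
    for i in range(f.shape[0]):
        if np.all(f[i] == 0):
            warnings.warn(f"neuron {i}: all-zero trace, ΔF/F set to 0")
            continue
        f0 = (
            pd.Series(f[i])
            .rolling(window, center=True, min_periods=1)
            .quantile(q)
            .to_numpy()
        )
        f0 = np.maximum(f0, f0_floor)
        dff[i] = (f[i] - f0) / f0
    return dff


def bin_position(
    position: np.ndarray, n_bins: int, belt_length: float
) -> np.ndarray:
    """Map positions to equal-width half-open circular bins.

    Bin ``i`` covers ``[i*L/n, (i+1)*L/n)``; a position exactly at
    ``belt_length`` wraps to bin 0 (it is outside the valid domain anyway and
    rejected).
    """
    if n_bins < 2:
        raise InvalidInputError("need at least 2 bins")
    position = np.asarray(position, dtype=float)
    if np.any((position < 0) | (position >= belt_length)):
        raise InvalidInputError("position outside [0, belt_length)")
    labels = np.floor(position * n_bins / belt_length).astype(int)
    # guard against float round-up at the right edge of the last bin
    return np.minimum(labels, n_bins - 1)


def write_session(session: Session, path) -> None:
    """Write a session to an HDF5 container (lossless round trip)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["belt_length"] = session.belt_length
        h5.attrs["frame_rate"] = session.frame_rate
        h5.attrs["metadata"] = json.dumps(session.metadata, default=str)
        h5.create_dataset("dff", data=session.dff)
        h5.create_dataset("frame_times", data=session.frame_times)
        h5.create_dataset("position", data=session.position)
        h5.create_dataset("lap_index", data=session.lap_index)
        if session.raw_f is not None:
            h5.create_dataset("raw_f", data=session.raw_f)
        if session.rates is not None:
            h5.create_dataset("rates", data=session.rates)


def read_session(path) -> Session:
    """Read a session written by :func:`write_session`.

    Raises :class:`SchemaVersionError` on a version mismatch and
    :class:`FormatError` on an unreadable container — never silent NaNs.
    """
    try:
        with h5py.File(path, "r") as h5:
            version = int(h5.attrs.get("schema_version", -1))
            if version != SCHEMA_VERSION:
                raise SchemaVersionError(
                    f"session schema version {version}, expected {SCHEMA_VERSION}")
            return Session(
                dff=h5["dff"][:],
                frame_times=h5["frame_times"][:],
                position=h5["position"][:],
                lap_index=h5["lap_index"][:],
                belt_length=float(h5.attrs["belt_length"]),
                frame_rate=float(h5.attrs["frame_rate"]),
                raw_f=h5["raw_f"][:] if "raw_f" in h5 else None,
                rates=h5["rates"][:] if "rates" in h5 else None,
                metadata=json.loads(h5.attrs["metadata"]),
            )
    except (OSError, KeyError) as exc:
        if isinstance(exc, SchemaVersionError):
            raise
        raise FormatError(f"cannot read session container {path}: {exc}") from exc
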
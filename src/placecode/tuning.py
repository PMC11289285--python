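"""Deconvolved firing rates, occupancy-normalised tuning vectors, tuning index.

The tuning index of a cell is the modulus of the mean resultant of its
occupancy-normalised firing-rate map over 100 circular position bins:

    r = sum_b w_b * exp(i * theta_b) / sum_b w_b,     index = |r|

with ``w_b`` the mean above-noise rate in bin ``b`` and ``theta_b`` the bin
centre angle. Division by ``sum_b w_b`` bounds the index in [0, 1] so it is
comparable across cells; the raw occupancy-normalised resultant (no unit-sum
normalisation) is available behind ``normalization="occupancy"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .session import Session, bin_position

__all__ = ["TuningResult", "deconvolve", "deconvolution_noise_gain",
           "tuning_vector"]


@dataclass
class TuningResult:
    """Per-neuron tuning summary over circular position bins."""

    vector: np.ndarray       # complex mean resultant per neuron
    index: np.ndarray        # |vector|, in [0, 1]
    bin_rates: np.ndarray    # neurons x n_bins occupancy-normalised rates
    occupancy: np.ndarray    # time spent moving in each bin (s)
    bin_angles: np.ndarray   # theta_b, bin centres (radians)
    degenerate: np.ndarray   # True where all thresholded rates were zero

    @property
    def n_bins(self) -> int:
        return self.bin_rates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.bin_rates,
                          columns=[f"bin_{b}" for b in range(self.n_bins)])
        df.insert(0, "index", self.index)
        df.insert(0, "neuron", np.arange(len(self.index)))
        return df


def deconvolve(dff: np.ndarray, frame_rate: float,
               decay_tau: float = 1.0) -> np.ndarray:
    """Nonnegative first-order autoregressive deconvolution.

    Inverts a single-exponential calcium kernel with decay constant
    ``decay_tau``: with ``gamma = exp(-1/(frame_rate*tau))`` the event
    estimate is ``max(0, c_t - gamma*c_{t-1})``, scaled to events/s. The
    operator is positively homogeneous, so rate estimates scale with the
    trace.
    """
    if decay_tau <= 0:
        raise InvalidConfigError("decay_tau must be positive")
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if not np.all(np.isfinite(dff)):
        raise InvalidInputError("dff must be finite")
    gamma = np.exp(-1.0 / (frame_rate * decay_tau))
    s = dff.copy()
    s[:, 1:] -= gamma * dff[:, :-1]
    return np.maximum(s, 0.0) * frame_rate


def deconvolution_noise_gain(frame_rate: float, decay_tau: float) -> float:
    """Std-dev gain of the AR(1) inversion on white noise (pre-rectification).

    Maps a ΔF/F noise sd to the sd of the linear part of
    :func:`deconvolve`'s output, used to carry the transient detector's
    sigma estimate into rate units for thresholding.
    """
    gamma = np.exp(-1.0 / (frame_rate * decay_tau))
    return float(np.sqrt(1.0 + gamma**2) * frame_rate)


def tuning_vector(
    rates: np.ndarray,
    session: Session,
    n_bins: int = 100,
    thresh_k: float = 2.0,
    sigma: np.ndarray | None = None,
    speed_threshold: float = 0.5,
    normalization: str = "resultant",
) -> TuningResult:
    """Occupancy-normalised circular tuning vector and tuning index.

    Rates below ``thresh_k`` noise standard deviations are zeroed so only
    putative firing epochs contribute. ``sigma`` is the per-neuron rate-noise
    sd; when omitted it is estimated robustly (scaled MAD about zero) from
    each rate trace, which is adequate for the sparse activity this analysis
    assumes. Frames with speed below ``speed_threshold`` (cm/s) are excluded
    from both occupancy and rate averaging.

    Unvisited bins are excluded with a warning; a cell whose thresholded
    rates are all zero gets index 0 and a degenerate flag.
    """
    if normalization not in ("resultant", "occupancy"):
        raise InvalidConfigError(f"unknown normalization {normalization!r}")
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if rates.shape[1] != session.n_frames:
        raise InvalidInputError("rates must align with session frames")
    if session.lap_index[-1] < 1:
        raise InvalidInputError("session must contain at least one full lap")

    if sigma is None:
        med = np.median(rates, axis=1, keepdims=True)
        sigma = 1.4826 * np.median(np.abs(rates - med), axis=1)
    sigma = np.asarray(sigma, dtype=float)

    thresholded = np.where(rates > thresh_k * sigma[:, None], rates, 0.0)

    moving = session.speed > speed_threshold
    bins = bin_position(session.position, n_bins, session.belt_length)
    dt = session.dt

    occupancy = np.bincount(bins[moving], minlength=n_bins) * dt
    visited = occupancy > 0
    if not visited.all():
        warnings.warn(f"{int((~visited).sum())} of {n_bins} bins unvisited; "
                      "excluded from the tuning vector")

    n_neurons = rates.shape[0]
    sums = np.zeros((n_neurons, n_bins))
    for b in range(n_bins):
        sel = moving & (bins == b)
        if sel.any():
            sums[:, b] = thresholded[:, sel].sum(axis=1) * dt
    with np.errstate(invalid="ignore", divide="ignore"):
        bin_rates = np.where(visited, sums / occupancy, 0.0)

    theta_b = (np.arange(n_bins) + 0.5) * 2.0 * np.pi / n_bins
    phasors = np.exp(1j * theta_b)[None, :] * visited[None, :]
    numer = (bin_rates * phasors).sum(axis=1)
    total = bin_rates.sum(axis=1)
    degenerate = total <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        resultant = np.where(degenerate, 0.0, numer / np.where(total > 0, total, 1.0))
    vector = numer if normalization == "occupancy" else resultant
    index = np.abs(resultant)
    index[degenerate] = 0.0

    return TuningResult(vector=vector, index=index, bin_rates=bin_rates,
                        occupancy=occupancy, bin_angles=theta_b,
                        degenerate=degenerate)
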
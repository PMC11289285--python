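"""Von Mises tuning-curve fitting, cross-validated goodness of fit, peak width.

The tuning-curve model is the circular analogue of a Gaussian bump on a
constant offset:

    f(theta) = B + A * exp(k * (cos(theta - phi) - 1))

with offset ``B``, peak amplitude ``A >= 0``, concentration ``k >= 0`` and
peak location ``phi``. Goodness of fit is a cross-validated
``R^2 = 1 - ss_res/ss_tot`` computed on held-out lap samples within each of
20 angular bins, reported clipped to [0, 1]; a cell is "well fitted" when
``R^2 > 0.5``. Peak width is the circular variance

    V = 1 - I1(k) / I0(k)

which decreases from 1 (flat) towards 0 as the peak sharpens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import i0e, i1e

from .errors import InvalidConfigError, InvalidInputError
from .session import Session, bin_position

__all__ = ["TuningCurve", "VonMisesFit", "build_tuning_curve",
           "fit_von_mises", "cross_validated_r2", "peak_width",
           "von_mises_profile"]

K_MAX = 50.0  # beyond this the peak is narrower than one 20-bin width
WELL_FITTED_R2 = 0.5


def von_mises_profile(theta, B, A, k, phi):
    """Evaluate B + A*exp(k*(cos(theta - phi) - 1))."""
    return B + A * np.exp(k * (np.cos(theta - phi) - 1.0))


@dataclass
class TuningCurve:
    """Per-lap, per-bin mean ΔF/F samples for a single cell.

    ``lap_bin_means`` is laps x bins with NaN marking lap-bin cells the
    animal never visited; ``mean`` is the across-lap mean per bin.
    """

    lap_bin_means: np.ndarray
    bin_angles: np.ndarray

    def __post_init__(self) -> None:
        self.lap_bin_means = np.atleast_2d(np.asarray(self.lap_bin_means,
                                                      dtype=float))
        self.bin_angles = np.asarray(self.bin_angles, dtype=float)
        if self.lap_bin_means.shape[1] != self.bin_angles.size:
            raise InvalidInputError("bin_angles must match curve bins")

    @property
    def n_laps(self) -> int:
        return self.lap_bin_means.shape[0]

    @property
    def n_bins(self) -> int:
        return self.lap_bin_means.shape[1]

    @property
    def mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.lap_bin_means, axis=0)


@dataclass
class VonMisesFit:
    """Fitted tuning-curve parameters and quality metrics."""

    B: float
    A: float
    kappa: float
    phi: float
    sse: float
    r2_cv: float = np.nan        # clipped to [0, 1]
    r2_cv_raw: float = np.nan    # unclipped, retained for diagnostics
    converged: bool = True
    degenerate: bool = False     # flat curve: A ~ 0, k unidentifiable

    @property
    def peak_width(self) -> float:
        return peak_width(self.kappa)

    @property
    def well_fitted(self) -> bool:
        return bool(self.r2_cv > WELL_FITTED_R2)


def build_tuning_curve(dff_trace: np.ndarray, session: Session,
                       n_bins: int = 20) -> TuningCurve:
    """Lap-by-bin mean unfiltered ΔF/F for one cell.

    A lap-bin cell the animal never visited is NaN and excluded from all
    means downstream.
    """
    if n_bins < 4:
        raise InvalidInputError("need at least 4 bins")
    dff_trace = np.asarray(dff_trace, dtype=float).ravel()
    if dff_trace.size != session.n_frames:
        raise InvalidInputError("trace must align with session frames")
    n_laps = int(session.lap_index.max()) + 1
    if n_laps < 2:
        raise InvalidInputError("need at least 2 laps")
    bins = bin_position(session.position, n_bins, session.belt_length)
    flat = session.lap_index * n_bins + bins
    sums = np.bincount(flat, weights=dff_trace, minlength=n_laps * n_bins)
    counts = np.bincount(flat, minlength=n_laps * n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        lap_bin = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    theta_b = (np.arange(n_bins) + 0.5) * 2.0 * np.pi / n_bins
    return TuningCurve(lap_bin.reshape(n_laps, n_bins), theta_b)


def _initial_guesses(theta: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    ymin, ymax = float(y.min()), float(y.max())
    rng_y = ymax - ymin
    mass = y - ymin
    tot = mass.sum()
    if tot > 0:
        z = (mass * np.exp(1j * theta)).sum() / tot
        phi0 = float(np.angle(z)) % (2 * np.pi)
        r = min(abs(z), 0.99)
        # standard A1-inverse approximation for the concentration
        k0 = r * (2.0 - r**2) / max(1.0 - r**2, 1e-6) if r > 0 else 1.0
        k0 = float(np.clip(k0, 0.5, K_MAX))
    else:
        phi0, k0 = 0.0, 1.0
    phi_peak = float(theta[np.argmax(y)])
    guesses = [
        np.array([ymin, rng_y, k0, phi0]),
        np.array([ymin, rng_y, 4.0, phi_peak]),
        np.array([float(y.mean()), max(rng_y, 1e-3), 1.0, phi_peak]),
        np.array([ymin, rng_y, 15.0, phi_peak]),
    ]
    return guesses


def fit_von_mises(curve: TuningCurve | tuple[np.ndarray, np.ndarray],
                  k_max: float = K_MAX,
                  starts: list[np.ndarray] | None = None,
                  max_nfev: int = 2000) -> VonMisesFit:
    """Least-squares von Mises fit of an across-lap mean tuning curve.

    Multi-start bounded optimisation (A >= 0, 0 <= k <= k_max); ties among
    converged starts are broken by lowest SSE, then lowest ``k``. A flat
    curve returns ``B = mean``, ``A = 0`` with the degenerate flag set since
    ``k`` and ``phi`` are unidentifiable there. ``starts`` overrides the
    default initial guesses (used to warm-start cross-validation refits).
    """
    if isinstance(curve, TuningCurve):
        theta, y = curve.bin_angles, curve.mean
    else:
        theta, y = (np.asarray(a, dtype=float) for a in curve)
    valid = np.isfinite(y)
    theta, y = theta[valid], y[valid]
    if y.size < 4:
        raise InvalidInputError("need at least 4 valid bins to fit")

    if np.ptp(y) == 0.0:
        return VonMisesFit(B=float(y.mean()), A=0.0, kappa=0.0, phi=0.0,
                           sse=0.0, degenerate=True)

    scale = max(np.ptp(y), 1e-12)
    lb = np.array([-np.inf, 0.0, 0.0, -np.inf])
    ub = np.array([np.inf, np.inf, k_max, np.inf])

    def resid(p):
        return von_mises_profile(theta, *p) - y

    def jac(p):
        _, A, k, phi = p
        d = theta - phi
        E = np.exp(k * (np.cos(d) - 1.0))
        return np.column_stack([np.ones_like(theta), E,
                                A * E * (np.cos(d) - 1.0),
                                A * E * k * np.sin(d)])

    best = None
    any_ok = False
    for p0 in (starts if starts is not None else _initial_guesses(theta, y)):
        p0 = np.clip(p0, lb, ub)
        try:
            sol = least_squares(resid, p0, jac=jac, bounds=(lb, ub),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=max_nfev)
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        any_ok = any_ok or sol.success
        cand = (sse, float(sol.x[2]), sol)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return VonMisesFit(B=float(y.mean()), A=0.0, kappa=0.0, phi=0.0,
                           sse=float(np.sum((y - y.mean())**2)),
                           converged=False, degenerate=True)
    sse, _, sol = best
    B, A, k, phi = sol.x
    degenerate = A < 1e-8 * scale
    return VonMisesFit(B=float(B), A=float(A), kappa=float(k),
                       phi=float(phi) % (2 * np.pi), sse=sse,
                       converged=any_ok, degenerate=bool(degenerate))


def cv_splits(valid_counts: np.ndarray, n_splits: int, train_frac: float,
              seed: int):
    """Deterministic per-bin train/test index splits, stratified by lap.

    For split ``s`` the RNG is ``default_rng([seed, s])``; within each bin
    (in bin order) a permutation of that bin's valid lap indices is drawn
    and the first ``round(train_frac * n)`` samples (at least 1, leaving at
    least 1 for test) go to training. Bins with fewer than 2 valid samples
    are excluded from both sides.

    Yields ``(split_index, train_sets, test_sets)`` where the sets are lists
    of per-bin index arrays (into the valid samples of that bin).
    """
    for s in range(n_splits):
        rng = np.random.default_rng([seed, s])
        train_sets, test_sets = [], []
        for n in valid_counts:
            if n < 2:
                train_sets.append(np.empty(0, dtype=int))
                test_sets.append(np.empty(0, dtype=int))
                continue
            perm = rng.permutation(int(n))
            n_train = int(round(train_frac * n))
            n_train = min(max(n_train, 1), int(n) - 1)
            train_sets.append(perm[:n_train])
            test_sets.append(perm[n_train:])
        yield s, train_sets, test_sets


def cross_validated_r2(curve: TuningCurve, n_splits: int = 10,
                       train_frac: float = 0.75, seed: int = 0,
                       ss_tot_mean: str = "heldout",
                       k_max: float = K_MAX) -> tuple[float, float]:
    """Cross-validated R^2 of the von Mises model on held-out lap samples.

    Per split, the model is fitted to the per-bin means of 75% of the lap
    samples within each bin and scored on the held-out 25%:
    ``R^2 = 1 - ss_res/ss_tot`` with ``ss_tot`` taken about the held-out
    grand mean (``ss_tot_mean="full"`` uses the full-data mean instead).
    The mean over splits is returned as ``(clipped, raw)`` where the first
    is clipped to [0, 1] — the reporting convention — and the second keeps
    negative values for diagnostics.
    """
    if not 0.0 < train_frac < 1.0:
        raise InvalidConfigError("train_frac must be in (0, 1)")
    if ss_tot_mean not in ("heldout", "full"):
        raise InvalidConfigError(f"unknown ss_tot_mean {ss_tot_mean!r}")
    lb = curve.lap_bin_means
    samples = [lb[np.isfinite(lb[:, b]), b] for b in range(curve.n_bins)]
    valid_counts = np.array([s.size for s in samples])
    if np.all(valid_counts < 2):
        raise InvalidInputError("no bin has >= 2 lap samples")
    full_mean = float(np.nanmean(lb))

    # warm start every split from the full-data fit; train curves differ
    # from it only by resampling noise
    full_fit = fit_von_mises(curve, k_max=k_max)
    warm = np.array([full_fit.B, full_fit.A, max(full_fit.kappa, 0.5),
                     full_fit.phi])

    r2s = []
    for _, train_sets, test_sets in cv_splits(valid_counts, n_splits,
                                              train_frac, seed):
        train_means, thetas, test_y, test_theta = [], [], [], []
        for b in range(curve.n_bins):
            if train_sets[b].size == 0:
                continue
            train_means.append(samples[b][train_sets[b]].mean())
            thetas.append(curve.bin_angles[b])
            test_y.append(samples[b][test_sets[b]])
            test_theta.append(np.full(test_sets[b].size,
                                      curve.bin_angles[b]))
        tr_theta, tr_y = np.array(thetas), np.array(train_means)
        peak_start = np.array([float(tr_y.min()), float(np.ptp(tr_y)), 4.0,
                               float(tr_theta[np.argmax(tr_y)])])
        fit = fit_von_mises((tr_theta, tr_y), k_max=k_max,
                            starts=[warm, peak_start], max_nfev=300)
        yt = np.concatenate(test_y)
        tt = np.concatenate(test_theta)
        pred = von_mises_profile(tt, fit.B, fit.A, fit.kappa, fit.phi)
        ss_res = float(np.sum((yt - pred)**2))
        centre = float(yt.mean()) if ss_tot_mean == "heldout" else full_mean
        ss_tot = float(np.sum((yt - centre)**2))
        if ss_tot == 0.0:
            r2s.append(1.0 if ss_res == 0.0 else 0.0)
        else:
            r2s.append(1.0 - ss_res / ss_tot)
    raw = float(np.mean(r2s))
    return float(np.clip(raw, 0.0, 1.0)), raw


def peak_width(k) -> float | np.ndarray:
    """Circular variance V = 1 - I1(k)/I0(k) of a von Mises peak.

    Uses exponentially scaled Bessel functions so the ratio is stable for
    large ``k``. V(0) = 1; V decreases monotonically to 0 as the peak
    narrows.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise InvalidInputError("concentration k must be >= 0")
    v = 1.0 - i1e(k) / i0e(k)
    return float(v) if v.ndim == 0 else v


def fit_cell(dff_trace: np.ndarray, session: Session, n_bins: int = 20,
             n_splits: int = 10, train_frac: float = 0.75,
             seed: int = 0) -> VonMisesFit:
    """Convenience: build the 20-bin curve, fit it, attach cross-validated R^2."""
    curve = build_tuning_curve(dff_trace, session, n_bins=n_bins)
    fit = fit_von_mises(curve)
    fit.r2_cv, fit.r2_cv_raw = cross_validated_r2(
        curve, n_splits=n_splits, train_frac=train_frac, seed=seed)
    return fit
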
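"""Position decoding, linear Fisher information, surrogates and thresholds.

Population activity is summarised as a trial tensor: the mean unfiltered
ΔF/F of each neuron in each of 20 position bins on each lap. A multinomial
logistic decoder estimates position from per-frame traces; projecting lap
responses of adjacent bins onto the decoder's pair-relevant weight
direction gives a 1-D signal whose discriminability

    d'^2 = (mu_1 - mu_2)^2 / (0.5 * (s_1^2 + s_2^2))

equals linear Fisher information for that spatial step. Small-sample bias
is removed with the standard correction for a Gaussian d'^2 estimate from
T trials per location and N estimated dimensions:

    d'^2_bc = d'^2_naive * (2T - N - 3) / (2T - 2)  -  2N / T

(N = 1 both for single cells and for the 1-D projected population signal,
whose weights come from independently trained decoder folds). Under the
null (equal means) the corrected estimator has expectation exactly 0, at
the price of occasionally going slightly negative — such values are
reported as-is. Dividing by the squared bin width expresses information per
cm^2, from which the distance discriminated correctly at a criterion level
follows as ``delta* = 2 * Phi^-1(criterion) / sqrt(J)`` for an equal-prior
single-interval ideal observer with proportion correct ``Phi(d'/2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit

from .errors import (
    InsufficientTrialsError,
    InvalidConfigError,
    InvalidInputError,
    SubsampleThresholdError,
)
from .session import Session, bin_position

__all__ = [
    "TrialTensor", "DecodeResult", "build_trial_tensor", "subsample_neurons",
    "decode_position", "population_fisher_info", "single_cell_fisher_info",
    "shuffle_noise_correlations", "mean_noise_correlation",
    "discrimination_threshold",
]


@dataclass
class TrialTensor:
    """Lap-by-bin mean responses: ``responses[neuron, bin, lap]``."""

    responses: np.ndarray
    belt_length: float

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise InvalidInputError("responses must be (neurons, bins, laps)")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_bins(self) -> int:
        return self.responses.shape[1]

    @property
    def n_laps(self) -> int:
        return self.responses.shape[2]

    @property
    def bin_width(self) -> float:
        """delta_s: spatial step between adjacent bin centres (cm)."""
        return self.belt_length / self.n_bins


@dataclass
class DecodeResult:
    """Cross-validated decoding accuracy and the fitted linear readout."""

    accuracy: float
    per_split: np.ndarray
    weights: np.ndarray     # n_bins x n_neurons, averaged over splits
    intercepts: np.ndarray
    n_bins: int
    seed: int = 0
    subsample_sizes: list = field(default_factory=list)


def build_trial_tensor(session: Session, n_bins: int = 20,
                       signal: str = "dff") -> TrialTensor:
    """Lap-by-bin means of the unfiltered ΔF/F (or chosen signal).

    Only complete laps — laps in which every bin was visited — enter the
    tensor, so variance estimates are never taken over missing cells.
    """
    data = getattr(session, signal)
    if data is None:
        raise InvalidInputError(f"session has no {signal!r} signal")
    bins = bin_position(session.position, n_bins, session.belt_length)
    n_laps = int(session.lap_index.max()) + 1
    complete = []
    for lap in range(n_laps):
        sel = session.lap_index == lap
        if np.unique(bins[sel]).size == n_bins:
            complete.append(lap)
    if len(complete) < 2:
        raise InsufficientTrialsError(
            f"only {len(complete)} complete laps; need >= 2")
    n_neurons = data.shape[0]
    tensor = np.empty((n_neurons, n_bins, len(complete)))
    for t, lap in enumerate(complete):
        lap_sel = session.lap_index == lap
        for b in range(n_bins):
            sel = lap_sel & (bins == b)
            tensor[:, b, t] = data[:, sel].mean(axis=1)
    return TrialTensor(tensor, session.belt_length)


def subsample_neurons(tensor: TrialTensor, n: int = 42, n_draws: int = 10,
                      seed: int = 0) -> list[TrialTensor]:
    """Random neuron subsets of fixed size, without replacement within a draw.

    Equalises population size across sessions before comparing decoding or
    information metrics. If the session has exactly ``n`` neurons a single
    draw (the full population) is returned; with fewer neurons the session
    does not meet the subsampling threshold and an explicit error is raised
    rather than silently padding.
    """
    if n > tensor.n_neurons:
        raise SubsampleThresholdError(
            f"requested {n} neurons, only {tensor.n_neurons} available")
    if n == tensor.n_neurons:
        return [tensor]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_draws):
        idx = rng.choice(tensor.n_neurons, size=n, replace=False)
        out.append(TrialTensor(tensor.responses[idx], tensor.belt_length))
    return out


def decode_position(
    session_or_xy,
    n_bins: int = 20,
    n_splits: int = 10,
    train_frac: float = 0.75,
    seed: int = 0,
    C: float = 1.0,
    max_iter: int = 500,
) -> DecodeResult:
    """Multinomial logistic decoding of the position bin from per-frame ΔF/F.

    Accuracy is the mean held-out fraction correct over ``n_splits`` random
    stratified 75/25 splits; stratification guarantees every bin is present
    in every training fold. L2 regularisation strength is fixed (``C``).
    The per-class weight matrix, averaged over splits, is retained for the
    Fisher-information projection.
    """
    if isinstance(session_or_xy, Session):
        X = session_or_xy.dff.T
        y = bin_position(session_or_xy.position, n_bins,
                         session_or_xy.belt_length)
    else:
        X, y = session_or_xy
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
    if X.shape[0] != y.size:
        raise InvalidInputError("X rows must match labels")

    splitter = StratifiedShuffleSplit(n_splits=n_splits,
                                      train_size=train_frac,
                                      random_state=int(seed) % (2**32))
    accs, weight_list, intercept_list = [], [], []
    for train, test in splitter.split(X, y):
        clf = LogisticRegression(C=C, max_iter=max_iter)
        clf.fit(X[train], y[train])
        accs.append(float(clf.score(X[test], y[test])))
        W = np.zeros((n_bins, X.shape[1]))
        b0 = np.zeros(n_bins)
        W[clf.classes_.astype(int)] = clf.coef_
        b0[clf.classes_.astype(int)] = clf.intercept_
        weight_list.append(W)
        intercept_list.append(b0)
    return DecodeResult(
        accuracy=float(np.mean(accs)),
        per_split=np.array(accs),
        weights=np.mean(weight_list, axis=0),
        intercepts=np.mean(intercept_list, axis=0),
        n_bins=n_bins,
        seed=seed,
    )


def _adjacent_pairs(n_bins: int) -> list[tuple[int, int]]:
    """Unordered circularly adjacent bin pairs (deduplicated for n_bins = 2)."""
    pairs = {tuple(sorted((b, (b + 1) % n_bins))) for b in range(n_bins)}
    return sorted(pairs)


def _dprime_sq(z1: np.ndarray, z2: np.ndarray, bias_corrected: bool,
               n_dims: int = 1) -> float:
    """d'^2 between two 1-D samples, optionally bias-corrected."""
    T = z1.size
    v1 = z1.var(ddof=1)
    v2 = z2.var(ddof=1)
    pooled = 0.5 * (v1 + v2)
    if pooled == 0.0:
        return np.nan
    naive = (z1.mean() - z2.mean())**2 / pooled
    if not bias_corrected:
        return float(naive)
    N = n_dims
    return float(naive * (2 * T - N - 3) / (2 * T - 2) - 2 * N / T)


@dataclass
class FisherResult:
    """Per-pair and averaged linear Fisher information."""

    per_pair: np.ndarray       # d'^2 per adjacent bin pair (NaN = skipped)
    mean: float                # average over valid pairs (dimensionless)
    per_cm2: float             # mean / delta_s^2
    bin_width: float


def population_fisher_info(tensor: TrialTensor, weights: np.ndarray,
                           bias_corrected: bool = True) -> FisherResult:
    """Population d'^2 from lap responses projected onto decoder weights.

    For each adjacent bin pair the projection direction is the difference
    of the two classes' decoder weight vectors; the projected lap responses
    of the two bins give the 1-D d'^2, bias-corrected with N = 1 since the
    direction is fixed by the (independently trained) decoder. Pairs whose
    pooled projected variance is zero are skipped with a warning.
    """
    if tensor.n_laps < 3:
        raise InsufficientTrialsError("need T >= 3 laps per bin")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (tensor.n_bins, tensor.n_neurons):
        raise InvalidInputError("weights must be (n_bins, n_neurons)")
    pairs = _adjacent_pairs(tensor.n_bins)
    vals = np.full(len(pairs), np.nan)
    for i, (b1, b2) in enumerate(pairs):
        w = weights[b2] - weights[b1]
        z1 = w @ tensor.responses[:, b1, :]
        z2 = w @ tensor.responses[:, b2, :]
        vals[i] = _dprime_sq(z1, z2, bias_corrected)
    if np.isnan(vals).any():
        warnings.warn(f"{int(np.isnan(vals).sum())} bin pairs skipped "
                      "(zero pooled variance)")
    mean = float(np.nanmean(vals))
    return FisherResult(per_pair=vals, mean=mean,
                        per_cm2=mean / tensor.bin_width**2,
                        bin_width=tensor.bin_width)


def single_cell_fisher_info(tensor: TrialTensor,
                            bias_corrected: bool = True) -> np.ndarray:
    """Bias-corrected signal-to-noise d'^2 per neuron, averaged over pairs.

    Signal is the squared difference of mean activity at two adjacent
    locations; noise is the average variance at each location. Returned per
    neuron, dimensionless (per bin-step); divide by ``bin_width**2`` for
    cm^-2 units.
    """
    if tensor.n_laps < 4:
        raise InsufficientTrialsError("need T >= 4 laps per bin")
    pairs = _adjacent_pairs(tensor.n_bins)
    out = np.empty(tensor.n_neurons)
    for n in range(tensor.n_neurons):
        vals = [
            _dprime_sq(tensor.responses[n, b1, :], tensor.responses[n, b2, :],
                       bias_corrected)
            for b1, b2 in pairs
        ]
        out[n] = np.nanmean(vals)
    return out


def shuffle_noise_correlations(tensor: TrialTensor,
                               seed: int = 0) -> TrialTensor:
    """Destroy noise correlations by permuting laps independently per neuron.

    Within each position bin the lap order of each neuron is permuted
    independently, so every per-neuron per-bin marginal (hence every tuning
    curve) is preserved exactly while cross-neuron within-bin covariance is
    destroyed in expectation.
    """
    rng = np.random.default_rng(seed)
    shuffled = tensor.responses.copy()
    for n in range(tensor.n_neurons):
        for b in range(tensor.n_bins):
            shuffled[n, b] = shuffled[n, b, rng.permutation(tensor.n_laps)]
    return TrialTensor(shuffled, tensor.belt_length)


def mean_noise_correlation(tensor: TrialTensor) -> float:
    """Mean pairwise correlation of within-bin residuals across laps."""
    resid = tensor.responses - tensor.responses.mean(axis=2, keepdims=True)
    per_bin = []
    for b in range(tensor.n_bins):
        r = resid[:, b, :]
        sd = r.std(axis=1)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        c = np.corrcoef(r[ok])
        iu = np.triu_indices_from(c, k=1)
        per_bin.append(float(c[iu].mean()))
    if not per_bin:
        return np.nan
    return float(np.mean(per_bin))


def discrimination_threshold(fi_per_cm2: float, criterion: float = 0.70,
                             observer: str = "single") -> float:
    """Smallest distance discriminated correctly at the criterion level.

    Under the local-linear Gaussian model ``d'(delta) = delta * sqrt(J)``;
    an equal-prior single-interval ideal observer is correct with
    probability ``Phi(d'/2)``, so the criterion distance is
    ``delta* = 2 * Phi^-1(criterion) / sqrt(J)`` (``sqrt(2)`` instead of 2
    for a 2AFC observer, selectable via ``observer="2afc"``). Non-positive
    information yields ``inf`` with a warning.
    """
    if not 0.5 < criterion < 1.0:
        raise InvalidConfigError("criterion must be in (0.5, 1)")
    if observer not in ("single", "2afc"):
        raise InvalidConfigError(f"unknown observer model {observer!r}")
    scale = 2.0 if observer == "single" else np.sqrt(2.0)
    if fi_per_cm2 <= 0:
        warnings.warn("non-positive Fisher information; threshold is infinite")
        return np.inf
    return float(scale * norm.ppf(criterion) / np.sqrt(fi_per_cm2))
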
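"""Nested bootstrap for cells-pooled-within-animals comparisons, and helpers.

Pooling cell-level metrics across animals violates the independence
assumptions of ordinary two-sample tests: cells from one animal share
animal-level effects. The two-level bootstrap here builds the null by
combining the animals of both conditions into one pool; each replicate
draws, per condition, animals with replacement from that pool and then
values with replacement within each drawn animal until the condition's
original number of values is reached, takes the mean, and records the
difference of the two pseudo-condition means. The two-sided p-value is the
fraction of replicates at least as extreme as the observed difference of
means, floored at 1/(n_boot + 1) so it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedDIError

__all__ = ["NestedSample", "BootstrapResult", "nested_bootstrap_test",
           "bonferroni", "discrimination_index"]


@dataclass
class NestedSample:
    """Cell-level values grouped by animal for one experimental condition."""

    condition: str
    values: list[np.ndarray]          # one array per animal
    animals: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise InvalidInputError("need at least one animal")
        self.values = [np.asarray(v, dtype=float).ravel() for v in self.values]
        if any(v.size < 1 for v in self.values):
            raise InvalidInputError("every animal needs at least one value")
        if self.animals is None:
            self.animals = [f"{self.condition}_{i}"
                            for i in range(len(self.values))]

    @property
    def n_values(self) -> int:
        return sum(v.size for v in self.values)

    @property
    def mean(self) -> float:
        return float(np.concatenate(self.values).mean())


@dataclass
class BootstrapResult:
    """Outcome of a nested bootstrap comparison."""

    observed_diff: float
    p_value: float
    n_boot: int
    seed: int
    null_diffs: np.ndarray = field(repr=False, default=None)


def _resample_means(pool_values: np.ndarray, offsets: np.ndarray,
                    lengths: np.ndarray, slot_counts: np.ndarray,
                    n_boot: int, rng: np.random.Generator,
                    nested: bool = True) -> np.ndarray:
    """Vectorised two-level resampling: mean of one pseudo-condition per replicate.

    ``nested=True`` draws one pool animal per original animal slot and then
    ``slot_counts[i]`` values with replacement within that animal, so
    animal-level variance survives into the null. ``nested=False`` draws an
    animal independently for every single value (equivalent to i.i.d. draws
    from the pooled mixture), which flattens the hierarchy.
    """
    n_animals = lengths.size
    n_values = int(slot_counts.sum())
    slot_of_value = np.repeat(np.arange(slot_counts.size), slot_counts)
    means = np.empty(n_boot)
    done = 0
    # chunked so the index matrices stay modest at n_boot = 100000
    chunk_rows = max(1, int(5_000_000 / max(n_values, 1)))
    while done < n_boot:
        m = min(chunk_rows, n_boot - done)
        if nested:
            ai = rng.integers(0, n_animals, size=(m, slot_counts.size))
            av = ai[:, slot_of_value]
        else:
            av = rng.integers(0, n_animals, size=(m, n_values))
        vi = rng.integers(0, lengths[av])
        means[done:done + m] = pool_values[offsets[av] + vi].mean(axis=1)
        done += m
    return means


def nested_bootstrap_test(
    a: NestedSample,
    b: NestedSample,
    n_boot: int = 100_000,
    seed: int = 0,
    pool_animals: bool = True,
    value_resampling: str = "within_animal",
    return_null: bool = False,
) -> BootstrapResult:
    """Two-sided nested bootstrap test of a difference in pooled-cell means.

    ``pool_animals=True`` (default) draws replicate animals from the
    combined pool of both conditions — the null construction in which
    condition labels carry no information at either level;
    ``pool_animals=False`` is a sensitivity variant resampling animals
    within their own condition only (null recentred at zero).
    ``value_resampling="within_animal"`` (default) keeps the hierarchy: one
    pool animal is drawn per original animal slot and that slot's value
    count is resampled within the drawn animal. ``"pooled"`` draws an
    animal anew for every value, which collapses the two levels into
    i.i.d. sampling from the pooled mixture and ignores the nesting — kept
    only for sensitivity analysis, as it is badly anti-conservative when
    animal-level variance is real.
    """
    if n_boot < 100:
        raise InvalidInputError("n_boot < 100 is too unstable to report")
    if value_resampling not in ("within_animal", "pooled"):
        raise InvalidInputError(
            f"unknown value_resampling {value_resampling!r}")
    nested = value_resampling == "within_animal"
    observed = a.mean - b.mean
    rng = np.random.default_rng(seed)

    def flatten(samples: Sequence[np.ndarray]):
        lengths = np.array([v.size for v in samples])
        offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        return np.concatenate(samples), offsets, lengths

    counts_a = np.array([v.size for v in a.values])
    counts_b = np.array([v.size for v in b.values])
    if pool_animals:
        pool, offsets, lengths = flatten(a.values + b.values)
        means_a = _resample_means(pool, offsets, lengths, counts_a,
                                  n_boot, rng, nested)
        means_b = _resample_means(pool, offsets, lengths, counts_b,
                                  n_boot, rng, nested)
    else:
        pa, oa, la = flatten(a.values)
        pb, ob, lb_ = flatten(b.values)
        means_a = _resample_means(pa, oa, la, counts_a, n_boot, rng, nested)
        means_b = _resample_means(pb, ob, lb_, counts_b, n_boot, rng, nested)
        centre = means_a.mean() - means_b.mean()
        means_a = means_a - centre  # centre the within-condition null

    null = means_a - means_b
    p = (np.count_nonzero(np.abs(null) >= abs(observed)) + 1) / (n_boot + 1)
    return BootstrapResult(observed_diff=float(observed), p_value=float(p),
                           n_boot=n_boot, seed=seed,
                           null_diffs=null if return_null else None)


def bonferroni(p_values, m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    return np.minimum(1.0, m * p)


def discrimination_index(freeze_a: float, freeze_b: float) -> float:
    """Behavioural context discrimination: (A - B) / (A + B).

    ``freeze_a`` and ``freeze_b`` are freezing times (s) or percentages in
    the shocked and novel contexts; the index lies in [-1, 1] with positive
    values meaning more freezing in the shocked context.
    """
    if freeze_a < 0 or freeze_b < 0:
        raise InvalidInputError("freezing times must be nonnegative")
    total = freeze_a + freeze_b
    if total == 0:
        raise UndefinedDIError("no freezing in either context")
    return float((freeze_a - freeze_b) / total)
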
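"""Affinity rankings and agreement statistics between energy sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RankingComparison", "FitSummary", "kendall_tau", "rank_by_energy",
           "linear_fit"]


@dataclass
class RankingComparison:
    """Kendall comparison of two orderings of the same items.

    ``dK`` is the number of adjacent swaps needed to turn list B into list A
    (equivalently the number of discordant pairs); the coefficient is
    normalised as tau = 1 - 4 dK / (N (N-1)), giving +1 for identical
    orderings and -1 for exact reversals.
    """

    dK: int
    N: int
    tau: float

    def __post_init__(self):
        if not (0 <= self.dK <= self.N * (self.N - 1) // 2):
            raise ValueError("dK out of range")
        if not (-1.0 - 1e-12 <= self.tau <= 1.0 + 1e-12):
            raise ValueError("tau out of range")


def _count_inversions(perm: list[int]) -> int:
    """Merge-sort inversion count = minimal adjacent-swap distance."""
    def sort(a: list[int]) -> tuple[list[int], int]:
        if len(a) <= 1:
            return a, 0
        mid = len(a) // 2
        left, nl = sort(a[:mid])
        right, nr = sort(a[mid:])
        merged, i, j, inv = [], 0, 0, nl + nr
        while i < len(left) and j < len(right):
            if left[i] <= right[j]:
                merged.append(left[i]); i += 1
            else:
                merged.append(right[j]); j += 1
                inv += len(left) - i
        merged.extend(left[i:]); merged.extend(right[j:])
        return merged, inv

    return sort(list(perm))[1]


def kendall_tau(list_a, list_b) -> RankingComparison:
    """Kendall rank agreement between two orderings of the same ids."""
    list_a, list_b = list(list_a), list(list_b)
    if len(list_a) < 2:
        raise ValueError("need at least 2 items")
    if len(set(list_a)) != len(list_a) or len(set(list_b)) != len(list_b):
        raise ValueError("duplicate ids in ranking")
    if set(list_a) != set(list_b):
        raise ValueError("the two rankings must contain the same ids")
    pos_a = {item: i for i, item in enumerate(list_a)}
    perm = [pos_a[item] for item in list_b]
    dk = _count_inversions(perm)
    n = len(list_a)
    return RankingComparison(dK=dk, N=n, tau=1.0 - 4.0 * dk / (n * (n - 1)))


def rank_by_energy(results: dict[str, float]) -> list[str]:
    """Ids ordered from strongest binder (most negative energy) to weakest.

    Ties are broken lexicographically by id so the ordering is
    deterministic.
    """
    items = list(results.items())
    if any(not np.isfinite(v) for _, v in items):
        raise ValueError("energies must be finite")
    return [k for k, _ in sorted(items, key=lambda kv: (kv[1], kv[0]))]


@dataclass
class FitSummary:
    """Ordinary least-squares agreement between two energy sets."""

    slope: float
    intercept: float
    r_squared: float
    relative_errors: np.ndarray  # (y - x) / x, per pair


def linear_fit(x, y) -> FitSummary:
    """OLS fit of y on x with intercept, plus per-pair relative errors.

    The relative error convention is (y - x)/x with x the reference
    (experimental-structure) energy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched arrays of length >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in x; fit undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (y - x) / x
    if np.var(y) == 0:  # flat response: R^2 = 0 by convention
        return FitSummary(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                          relative_errors=rel)
    res = stats.linregress(x, y)
    return FitSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        relative_errors=rel,
    )
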
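"""Per-sample alpha diversity and nonparametric group comparison.

Three indices are computed on raw per-sample counts at OTU granularity
(Chao1 is undefined on proportions, and aggregation would destroy the
singleton/doubleton structure it relies on):

* Chao1 richness: ``S_obs + F1^2 / (2 F2)`` with the bias-corrected form
  ``S_obs + F1 (F1 - 1) / 2`` when there are no doubletons (F1 =
  singleton count, F2 = doubleton count);
* Shannon–Wiener entropy ``-sum p_i log p_i`` (natural log by default;
  the base is configurable and recorded in output headers);
* Simpson diversity in the Gini–Simpson form ``1 - sum p_i^2``
  (algebraically ``1 - 1/B`` for the Levins breadth B of the same
  profile).

Group differences are assessed with the Kruskal–Wallis rank test
(midrank ties correction; chi-square approximation, with an optional
exact permutation p-value for tiny designs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _iperm

import numpy as np
from scipy import stats

from .io_model import AbundanceTable, ValidationError

__all__ = [
    "DiversityResult",
    "GroupTestResult",
    "chao1",
    "shannon",
    "simpson",
    "alpha_diversity",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    observed_richness: int
    chao1: float
    shannon: float
    simpson: float

    def __post_init__(self) -> None:
        if self.chao1 < self.observed_richness - 1e-9:
            raise ValidationError("chao1 below observed richness")
        if not (0.0 <= self.simpson <= 1.0):
            raise ValidationError("simpson outside [0, 1]")


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    group_ns: tuple[int, ...]


def _positive_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0:
        raise ValidationError("empty sample")
    if not np.issubdtype(c.dtype, np.integer):
        if np.issubdtype(c.dtype, np.floating) and np.all(c == np.floor(c)):
            c = c.astype(np.int64)
        else:
            raise ValidationError("counts must be integers")
    if (c < 0).any():
        raise ValidationError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValidationError("sample has zero total reads")
    return c


def chao1(counts) -> float:
    """Chao1 richness estimate from integer counts of one sample."""
    c = _positive_counts(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts, base: float = math.e) -> float:
    """Shannon–Wiener entropy of one sample (natural log by default)."""
    c = _positive_counts(counts).astype(float)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def simpson(counts) -> float:
    """Gini–Simpson diversity ``1 - sum p_i^2`` of one sample."""
    c = _positive_counts(counts).astype(float)
    p = c / c.sum()
    return float(1.0 - np.dot(p, p))


def alpha_diversity(table: AbundanceTable, base: float = math.e) -> list[DiversityResult]:
    """All three indices for every sample of an abundance table."""
    out = []
    for i, sid in enumerate(table.samples):
        row = table.counts[i]
        out.append(
            DiversityResult(
                sample_id=sid,
                observed_richness=int((row > 0).sum()),
                chao1=chao1(row),
                shannon=shannon(row, base=base),
                simpson=simpson(row),
            )
        )
    return out


def _kw_statistic(values: np.ndarray, group_sizes: list[int]) -> float:
    """Kruskal–Wallis H with midrank ties correction on concatenated values."""
    n = values.size
    ranks = stats.rankdata(values)
    h = 0.0
    start = 0
    for sz in group_sizes:
        r = ranks[start : start + sz].sum()
        h += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0.0:
        return 0.0  # all values identical
    return h / correction


def kruskal_wallis(groups: list[list[float]], *, exact_max_n: int = 0,
                   rng: np.random.Generator | None = None,
                   permutations: int = 9999) -> GroupTestResult:
    """Kruskal–Wallis test across >= 2 groups of values.

    The p-value comes from the chi-square approximation with
    ``len(groups) - 1`` degrees of freedom.  When the total sample size is
    at most *exact_max_n*, an exact permutation p-value is computed
    instead (full enumeration up to 9 observations, otherwise Monte Carlo
    with *permutations* draws from *rng*).
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(s < 1 for s in sizes):
        raise ValidationError("every group needs at least one value")
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = values.size
    if n < 3:
        raise ValidationError("need at least 3 observations in total")
    h = _kw_statistic(values, sizes)
    if exact_max_n and n <= exact_max_n:
        p = _kw_permutation_p(values, sizes, h, rng=rng, permutations=permutations)
    else:
        p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return GroupTestResult(statistic=float(h), p_value=min(p, 1.0), group_ns=tuple(sizes))


def _kw_permutation_p(values, sizes, h_obs, *, rng, permutations) -> float:
    n = values.size
    if n <= 9:  # full enumeration
        count = total = 0
        for perm in _iperm(range(n)):
            h = _kw_statistic(values[list(perm)], sizes)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
        return count / total
    rng = rng or np.random.default_rng(0)
    hits = 0
    v = values.copy()
    for _ in range(permutations):
        rng.shuffle(v)
        if _kw_statistic(v, sizes) >= h_obs - 1e-12:
            hits += 1
    return (hits + 1) / (permutations + 1)
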
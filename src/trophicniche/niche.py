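"""Trophic niche breadth (Levins) and niche overlap (Pianka).

For a diet profile with item proportions :math:`P_i`, the Levins breadth
is :math:`B = 1 / \\sum_i P_i^2`: 1 for a complete specialist, n for a
uniform generalist over n items.  For two consumers j and k with item
proportions :math:`P_{ij}, P_{ik}`, the Pianka overlap is

.. math:: O_{jk} = \\frac{\\sum_i P_{ij} P_{ik}}
                        {\\sqrt{\\sum_i P_{ij}^2 \\; \\sum_i P_{ik}^2}}

i.e. the cosine similarity of the two diet vectors, in [0, 1].  Overlap
strictly above 0.3 is classified *meaningful*, strictly above 0.6
*significant*; at or below 0.3, *none*.

When only the largest few proportions of a diet are known, the breadth of
the full (unknown) composition is constrained to a computable feasibility
interval; :func:`levins_feasible_interval` returns it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io_model import RunConfig, ValidationError
from .taxonomy import CompositionProfile

__all__ = [
    "NicheBreadthResult",
    "OverlapResult",
    "levins_breadth",
    "levins_feasible_interval",
    "pianka_overlap",
    "classify_overlap",
    "overlap_matrix",
]


@dataclass(frozen=True)
class NicheBreadthResult:
    group: str
    rank: str
    food_class: str  # "animal" (COI) or "plant" (RbcL)
    B: float

    def __post_init__(self) -> None:
        if self.B < 1.0 - 1e-12:
            raise ValidationError(f"breadth B={self.B} below 1")


@dataclass(frozen=True)
class OverlapResult:
    group_j: str
    group_k: str
    rank: str
    food_class: str
    O: float
    category: str  # none | meaningful | significant


def levins_breadth(
    profile: CompositionProfile, *, food_class: str = ""
) -> NicheBreadthResult:
    """Levins niche breadth ``B = 1 / sum(P_i^2)`` of a diet profile.

    Exact arithmetic on the given proportions; no smoothing or correction.
    """
    p = np.asarray(profile.proportions, dtype=float)
    if p.size == 0 or not (p > 0).any():
        raise ValidationError("cannot compute breadth of an all-zero profile")
    B = 1.0 / float(np.dot(p, p))
    return NicheBreadthResult(group=profile.group, rank=profile.rank,
                              food_class=food_class, B=B)


def levins_feasible_interval(top_props: list[float] | np.ndarray) -> tuple[float, float]:
    """Bounds on Levins breadth given only the k largest diet proportions.

    *top_props* are the k largest proportions of an otherwise unknown
    composition, in any order, summing to less than 1.  Returns
    ``(B_min, B_max_sup)``:

    * ``B_max_sup = 1 / sum(top^2)`` — the supremum, approached as the
      residual mass is spread over arbitrarily many vanishingly small
      items;
    * ``B_min`` — attained by packing the residual mass m into as few
      items as the top-k constraint allows: ``floor(m / p_min)`` items of
      size ``p_min = min(top_props)`` plus one remainder item, which
      maximises the sum of squares.

    Any complete composition whose top-k equals *top_props* has breadth
    inside this interval.
    """
    top = np.asarray(top_props, dtype=float)
    if top.size == 0 or (top <= 0).any():
        raise ValidationError("top proportions must be positive")
    s = float(top.sum())
    if s > 1.0 + 1e-12:
        raise ValidationError(f"top proportions sum to {s} > 1")
    residual = max(0.0, 1.0 - s)
    sq = float(np.dot(top, top))
    b_max_sup = 1.0 / sq
    p_min = float(top.min())
    # Greedy packing of the residual into the largest admissible items.
    n_full = int(math.floor(residual / p_min + 1e-12))
    remainder = residual - n_full * p_min
    assert remainder <= p_min + 1e-12, "tail construction exceeds p_min"
    tail_sq = n_full * p_min**2 + remainder**2
    b_min = 1.0 / (sq + tail_sq)
    return (b_min, b_max_sup)


def _aligned(profile_j: CompositionProfile, profile_k: CompositionProfile
             ) -> tuple[np.ndarray, np.ndarray]:
    """Align two profiles on the union of their item sets (absent = 0)."""
    union = sorted(set(profile_j.items) | set(profile_k.items))
    dj, dk = profile_j.as_dict(), profile_k.as_dict()
    pj = np.array([dj.get(i, 0.0) for i in union])
    pk = np.array([dk.get(i, 0.0) for i in union])
    return pj, pk


def classify_overlap(O: float, thresholds: tuple[float, float] = (0.3, 0.6)) -> str:
    """Classify a Pianka overlap value against the strict thresholds.

    Thresholds are strict: exactly 0.3 -> ``none``, exactly 0.6 ->
    ``meaningful``.
    """
    if not (-1e-12 <= O <= 1.0 + 1e-12):
        raise ValidationError(f"overlap {O} outside [0, 1]")
    t_meaningful, t_significant = thresholds
    if O > t_significant:
        return "significant"
    if O > t_meaningful:
        return "meaningful"
    return "none"


def pianka_overlap(
    profile_j: CompositionProfile,
    profile_k: CompositionProfile,
    *,
    food_class: str = "",
    thresholds: tuple[float, float] = (0.3, 0.6),
) -> OverlapResult:
    """Pianka overlap of two diet profiles at the same rank.

    Item universes are unioned before the formula; items absent from a
    diet contribute zero (no pseudo-counts).
    """
    if profile_j.rank != profile_k.rank:
        raise ValidationError(
            f"profiles at different ranks: {profile_j.rank!r} vs {profile_k.rank!r}"
        )
    pj, pk = _aligned(profile_j, profile_k)
    nj, nk = float(np.dot(pj, pj)), float(np.dot(pk, pk))
    if nj == 0.0 or nk == 0.0:
        raise ValidationError("zero-norm profile in overlap computation")
    O = float(np.dot(pj, pk) / math.sqrt(nj * nk))
    O = min(max(O, 0.0), 1.0)  # clip fp noise at the Cauchy–Schwarz bounds
    return OverlapResult(
        group_j=profile_j.group,
        group_k=profile_k.group,
        rank=profile_j.rank,
        food_class=food_class,
        O=O,
        category=classify_overlap(O, thresholds),
    )


def overlap_matrix(
    profiles: list[CompositionProfile],
    *,
    food_class: str = "",
    cfg: RunConfig | None = None,
) -> list[OverlapResult]:
    """All C(n,2) pairwise Pianka overlaps among the given group profiles.

    Symmetric by construction; self-overlap is not emitted.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least 2 groups for an overlap matrix")
    thresholds = cfg.overlap_thresholds if cfg else (0.3, 0.6)
    return [
        pianka_overlap(a, b, food_class=food_class, thresholds=thresholds)
        for a, b in combinations(profiles, 2)
    ]
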
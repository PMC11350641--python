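"""Beta diversity: Jaccard distances, nonmetric MDS, ANOSIM.

Sample-to-sample dissimilarity is the Jaccard distance on
presence/absence (a read-count threshold turns counts into presence).
The dissimilarity structure is visualised by nonmetric multidimensional
scaling (NMDS), which seeks low-dimensional coordinates whose pairwise
distances reproduce the *rank order* of the observed dissimilarities.
Goodness of fit is Kruskal stress-1,

.. math:: \\mathrm{stress} = \\sqrt{\\sum (d^* - \\hat d)^2 / \\sum d^{*2}}

where :math:`d^*` are embedded distances and :math:`\\hat d` their
isotonic (monotone) regression on the observed dissimilarity ranks; a
stress below 0.1 is conventionally read as a reliable configuration.
Group separation is tested with ANOSIM: the statistic
:math:`R = (\\bar r_B - \\bar r_W) / (M/2)` compares mean ranks of
between- and within-group dissimilarities (:math:`M = n(n-1)/2` ranked
pairs), with significance from label permutation.

The NMDS optimiser is Kruskal-style iterative majorization (SMACOF steps
toward the isotonic disparities), initialised from classical metric
scaling plus random restarts; deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .io_model import AbundanceTable, RunConfig, ValidationError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "AnosimResult",
    "jaccard_distances",
    "kruskal_stress",
    "nmds_embed",
    "anosim_statistic",
    "anosim",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValidationError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray  # samples x dims, centred at the origin
    stress: float
    converged: bool
    quality_flag: str  # "favorable" iff stress < 0.1
    best_restart: int
    seed: int


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    exact: bool


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------


def jaccard_distances(table: AbundanceTable, cfg: RunConfig | None = None) -> DistanceMatrix:
    """Pairwise Jaccard distances on presence/absence of taxa.

    Presence means count >= ``cfg.presence_min_count`` (default 1).  A
    pair of samples with no present taxa at all gets distance 0 with a
    warning.
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    min_count = cfg.presence_min_count if cfg else 1
    pres = table.counts >= min_count
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = int((pres[i] | pres[j]).sum())
            if union == 0:
                warnings.warn(
                    f"samples {table.samples[i]!r} and {table.samples[j]!r} share no "
                    f"present taxa with any other; Jaccard distance set to 0"
                )
                dij = 0.0
            else:
                inter = int((pres[i] & pres[j]).sum())
                dij = 1.0 - inter / union
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(table.samples), d)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def _classical_scaling(D: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) metric scaling, used as the first NMDS start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    vals_d = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_d)


def kruskal_stress(coords: np.ndarray, dissim: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities.

    *dissim* is condensed (upper-triangle) form; disparities are the
    isotonic regression of embedded distances on the observed
    dissimilarities (ties averaged — Kruskal's primary approach).
    """
    dstar = pdist(coords)
    denom = float(np.dot(dstar, dstar))
    if denom == 0.0:
        return 0.0 if np.allclose(dissim, 0.0) else math.inf
    dhat = IsotonicRegression(increasing=True).fit_transform(dissim, dstar)
    return math.sqrt(float(((dstar - dhat) ** 2).sum()) / denom)


def _smacof_nmds(dissim: np.ndarray, init: np.ndarray, tol: float, max_iter: int
                 ) -> tuple[np.ndarray, float, bool]:
    """Minimise stress-1 by alternating isotonic regression and Guttman steps."""
    n = init.shape[0]
    X = init - init.mean(axis=0)
    iso = IsotonicRegression(increasing=True)
    old_stress = math.inf
    converged = False
    for _ in range(max_iter):
        dstar = pdist(X)
        denom = float(np.dot(dstar, dstar))
        if denom == 0.0:
            break
        dhat = iso.fit_transform(dissim, dstar)
        stress = math.sqrt(float(((dstar - dhat) ** 2).sum()) / denom)
        if old_stress - stress < tol:
            converged = True
            old_stress = min(stress, old_stress)
            break
        old_stress = stress
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dstar > 0, dhat / dstar, 0.0)
        Bm = -squareform(ratio, checks=False)
        np.fill_diagonal(Bm, -Bm.sum(axis=1))
        X = Bm @ X / n
        X -= X.mean(axis=0)
    return X, kruskal_stress(X, dissim), converged


def nmds_embed(D: DistanceMatrix, cfg: RunConfig | None = None, *,
               dims: int | None = None) -> OrdinationResult:
    """NMDS embedding of a distance matrix, best of several restarts.

    The first restart starts from classical metric scaling; the rest from
    seeded random Gaussian configurations.  Deterministic given
    ``cfg.rng_seed``.  If no restart converges the best configuration is
    still returned with ``converged=False`` and a warning.
    """
    cfg = cfg or RunConfig()
    dims = dims if dims is not None else cfg.nmds_dims
    if dims < 1:
        raise ValidationError("dims must be >= 1")
    if cfg.nmds_restarts < 1:
        raise ValidationError("restarts must be >= 1")
    dissim = D.condensed()
    rng = np.random.default_rng(cfg.rng_seed)
    best = None
    for r in range(cfg.nmds_restarts):
        init = (
            _classical_scaling(D.values, dims)
            if r == 0
            else rng.normal(size=(D.n, dims))
        )
        X, stress, conv = _smacof_nmds(dissim, init, cfg.nmds_tol, cfg.nmds_max_iter)
        if best is None or stress < best[1]:
            best = (X, stress, conv, r)
    X, stress, conv, r = best
    if not conv:
        warnings.warn("NMDS did not converge in any restart; returning best configuration")
    return OrdinationResult(
        ids=list(D.ids),
        coordinates=X - X.mean(axis=0),
        stress=stress,
        converged=conv,
        quality_flag="favorable" if stress < 0.1 else "poor",
        best_restart=r,
        seed=cfg.rng_seed,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def anosim_statistic(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    """ANOSIM R from a square matrix of dissimilarity ranks and group labels."""
    n = labels.size
    iu = np.triu_indices(n, k=1)
    within = labels[iu[0]] == labels[iu[1]]
    ranks = rank_matrix[iu]
    m = n * (n - 1) / 2
    if within.all() or not within.any():
        raise ValidationError("need both within- and between-group pairs")
    r_between = ranks[~within].mean()
    r_within = ranks[within].mean()
    return float((r_between - r_within) / (m / 2.0))


def _distinct_label_permutations(labels: np.ndarray):
    """Yield all distinct permutations of a label multiset (lexicographic)."""
    arr = sorted(labels.tolist())
    n = len(arr)
    while True:
        yield np.asarray(arr, dtype=object)
        i = n - 2
        while i >= 0 and arr[i] >= arr[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while arr[j] <= arr[i]:
            j -= 1
        arr[i], arr[j] = arr[j], arr[i]
        arr[i + 1 :] = reversed(arr[i + 1 :])


def _n_distinct_permutations(labels: np.ndarray) -> int:
    total = math.factorial(labels.size)
    for _, cnt in zip(*np.unique(labels, return_counts=True)):
        total //= math.factorial(int(cnt))
    return total


def anosim(D: DistanceMatrix, groups: dict[str, str] | list[str],
           cfg: RunConfig | None = None) -> AnosimResult:
    """ANOSIM test of group separation on a dissimilarity matrix.

    *groups* maps sample id -> group label (or is a label list aligned
    with ``D.ids``).  The p-value is estimated by label permutation with
    the (b+1)/(m+1) estimator, or computed exactly when the number of
    distinct label arrangements is at most 10,000.
    """
    cfg = cfg or RunConfig()
    if isinstance(groups, dict):
        labels = np.asarray([groups[s] for s in D.ids], dtype=object)
    else:
        labels = np.asarray(list(groups), dtype=object)
    if labels.size != D.n:
        raise ValidationError("labels do not match distance matrix")
    if np.unique(labels).size < 2:
        raise ValidationError("all samples in one group")
    from scipy.stats import rankdata

    iu = np.triu_indices(D.n, k=1)
    rank_matrix = np.zeros_like(D.values)
    rank_matrix[iu] = rankdata(D.values[iu])
    rank_matrix += rank_matrix.T
    r_obs = anosim_statistic(rank_matrix, labels)

    n_arrangements = _n_distinct_permutations(labels)
    if n_arrangements <= 10_000:
        hits = total = 0
        for perm in _distinct_label_permutations(labels):
            total += 1
            if anosim_statistic(rank_matrix, perm) >= r_obs - 1e-12:
                hits += 1
        return AnosimResult(R=r_obs, p_value=hits / total,
                            n_permutations=total, exact=True)
    rng = np.random.default_rng(cfg.rng_seed)
    m = cfg.permutations
    hits = 0
    lab = labels.copy()
    for _ in range(m):
        rng.shuffle(lab)
        if anosim_statistic(rank_matrix, lab) >= r_obs - 1e-12:
            hits += 1
    return AnosimResult(R=r_obs, p_value=(hits + 1) / (m + 1),
                        n_permutations=m, exact=False)
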
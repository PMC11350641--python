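"""LEfSe-style differential-abundance (biomarker) discovery.

The procedure screens every taxon, independently at each rank level from
phylum down to genus, for group-discriminating abundance:

1. per-sample abundances at that rank are scaled to a constant total of
   10^6 (so per-sample sequencing effort cancels);
2. a Kruskal–Wallis test across consumer groups keeps features with
   p < alpha;
3. Wilcoxon rank-sum comparisons must show the candidate enriched group
   (largest mean) shifted above every other group (all-against-all
   strict mode; a lenient mode only checks the extreme pair);
4. the effect size is ``log10 |(g_raw + g_proj) / 2|`` where ``g_raw``
   is the gap between the two extreme class means of the feature's
   scaled abundance and ``g_proj`` the gap between the extreme class
   means of sample projections onto the first linear-discriminant axis
   (fit on the surviving features of that rank level, within-class
   scatter ridge-regularised, axis scaled to unit coefficient norm);
5. a feature passes when the effect size reaches ``lda_cutoff``
   (default 2).

This is a deterministic, documented variant of the LEfSe procedure: the
original's bootstrapped LDA with per-run feature perturbation is
replaced by the fixed formula above, trading bug-compatibility for
reproducibility.  Outputs are labelled "LEfSe-style" accordingly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .io_model import AbundanceTable, RunConfig, SampleMetadata, ValidationError
from .taxonomy import UNASSIGNED_PREFIX, aggregate_to_rank

logger = logging.getLogger(__name__)

__all__ = ["BiomarkerRecord", "pairwise_wilcoxon", "lefse_biomarkers"]

SCALE_TOTAL = 1.0e6
BIOMARKER_RANKS = ("phylum", "class", "order", "family", "genus")
_RIDGE = 1e-6  # relative ridge added to the within-class scatter diagonal


@dataclass(frozen=True)
class BiomarkerRecord:
    feature: str
    rank: str
    enriched_group: str
    kw_p: float
    lda_score: float  # log10 effect size; -inf when the screen failed
    passed: bool


def pairwise_wilcoxon(values_a, values_b) -> tuple[float, int]:
    """Two-sided Wilcoxon rank-sum test and direction of the shift.

    Returns ``(p_value, direction)`` with direction +1 when *values_a*
    tends larger, -1 when smaller, 0 for a perfectly balanced rank sum.
    Exact enumeration is used for group sizes below 8 (ties permitting);
    otherwise the normal approximation with midranks and tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty group in Wilcoxon test")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0, 0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) < 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = int(np.sign(res.statistic - a.size * b.size / 2.0))
    return float(res.pvalue), direction


def _first_discriminant_axis(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Unit-norm first LDA axis of features *X* given class *labels*.

    Solves the generalized eigenproblem S_b w = lambda S_w w with a
    small ridge on the within-class scatter to keep it invertible.
    """
    classes = np.unique(labels)
    n, p = X.shape
    mu = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        d = Xc - mc
        Sw += d.T @ d
        Sb += Xc.shape[0] * np.outer(mc - mu, mc - mu)
    ridge = _RIDGE * (np.trace(Sw) / p if np.trace(Sw) > 0 else 1.0)
    Sw_reg = Sw + ridge * np.eye(p)
    vals, vecs = linalg.eigh(Sb, Sw_reg)
    w = vecs[:, -1]
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValidationError("degenerate discriminant axis")
    return w / norm


def _directions_consistent(groups_vals: dict[str, np.ndarray], strict: bool) -> bool:
    """Does the candidate enriched class beat every other class consistently?

    All-against-all strict mode: the class with the largest mean must show
    a Wilcoxon shift in its favour against each other class (a zero shift
    fails).  Lenient mode only requires agreement against the extreme
    opposite class.  Comparisons among non-candidate classes carry no
    signal about the candidate and are not tested.
    """
    names = sorted(groups_vals)
    means = {g: groups_vals[g].mean() for g in names}
    top = max(names, key=lambda g: means[g])
    if strict:
        pairs = [(top, b) for b in names if b != top]
    else:
        bottom = min(names, key=lambda g: means[g])
        pairs = [(top, bottom)] if top != bottom else []
    for a, b in pairs:
        _, direction = pairwise_wilcoxon(groups_vals[a], groups_vals[b])
        if direction != 1:
            return False
    return True


def lefse_biomarkers(
    table: AbundanceTable,
    metadata: list[SampleMetadata],
    cfg: RunConfig | None = None,
    *,
    ranks: tuple[str, ...] = BIOMARKER_RANKS,
    strict: bool = True,
) -> list[BiomarkerRecord]:
    """Run the biomarker screen at every requested rank level.

    Returns one record per feature that reaches the Kruskal–Wallis
    screen's attention (non-constant features), with ``passed`` marking
    those that clear all three gates.  Records are sorted by enriched
    group and then by descending effect size, the order of a typical
    LDA-score bar chart.
    """
    cfg = cfg or RunConfig()
    by_id = {m.sample_id: m for m in metadata}
    labels = np.asarray([by_id[s].consumer_species for s in table.samples], dtype=object)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValidationError("need at least 2 consumer groups")
    sizes = [(labels == g).sum() for g in groups]
    if min(sizes) < 3:
        warnings.warn(
            f"fewer than 3 samples in some groups {dict(zip(groups, sizes))}; "
            f"the rank tests have little power"
        )
    records: list[BiomarkerRecord] = []
    for rank in ranks:
        agg = aggregate_to_rank(table, rank, cfg)
        keep = [j for j, t in enumerate(agg.taxa)
                if not t.taxon_id.startswith(UNASSIGNED_PREFIX)]
        if not keep:
            continue
        X = agg.counts[:, keep].astype(float)
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        X = X / totals * SCALE_TOTAL
        names = [agg.taxa[j].taxon_id for j in keep]

        survivors: list[int] = []
        kw_ps: dict[int, float] = {}
        for j, name in enumerate(names):
            col = X[:, j]
            if np.all(col == col[0]):
                logger.info("skipping constant feature %s at rank %s", name, rank)
                continue
            h = stats.kruskal(*[col[labels == g] for g in groups])
            kw_ps[j] = float(h.pvalue)
            if h.pvalue >= cfg.alpha:
                continue
            gv = {g: col[labels == g] for g in groups}
            if not _directions_consistent(gv, strict):
                continue
            survivors.append(j)

        proj_gap = 0.0
        if survivors:
            Xs = X[:, survivors]
            try:
                w = _first_discriminant_axis(Xs, labels)
                proj = Xs @ w
                cmeans = [proj[labels == g].mean() for g in groups]
                proj_gap = max(cmeans) - min(cmeans)
            except ValidationError:
                proj_gap = 0.0

        for j, kw_p in sorted(kw_ps.items()):
            col = X[:, j]
            cmeans = {g: col[labels == g].mean() for g in groups}
            enriched = max(sorted(cmeans), key=lambda g: cmeans[g])
            raw_gap = max(cmeans.values()) - min(cmeans.values())
            if j in survivors:
                avg = abs(raw_gap + proj_gap) / 2.0
                score = math.log10(avg) if avg > 0 else -math.inf
                passed = score >= cfg.lda_cutoff
            else:
                score = -math.inf
                passed = False
            records.append(
                BiomarkerRecord(
                    feature=names[j],
                    rank=rank,
                    enriched_group=enriched,
                    kw_p=kw_p,
                    lda_score=score,
                    passed=passed,
                )
            )
    records.sort(key=lambda r: (r.enriched_group, -r.lda_score, r.rank, r.feature))
    return records
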
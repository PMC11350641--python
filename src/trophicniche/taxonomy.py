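"""Identity-based rank resolution and rank-level aggregation.

Diet metabarcoding reads are annotated against a reference database; how
deep in the taxonomy an OTU can be trusted depends on its best alignment
identity.  The rule applied here: an OTU is resolved to species when its
identity is at least the species threshold (default 99%) and the best hit
is unambiguous (a single species, and not contradicted by a local-fauna
flag); it is resolved to genus when identity exceeds the genus threshold
(default 98%); otherwise it is only trusted at ranks above genus through
its lineage.

Counts are then aggregated to a target rank and turned into per-consumer
relative-abundance profiles, the inputs of the niche indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_model import (
    RANK_ORDER,
    AbundanceTable,
    RunConfig,
    SampleMetadata,
    TaxonRecord,
    ValidationError,
)

__all__ = [
    "CompositionProfile",
    "resolve_rank_assignment",
    "aggregate_to_rank",
    "group_composition",
    "top_k_items",
]

UNASSIGNED_PREFIX = "Unassigned@"


@dataclass(frozen=True)
class CompositionProfile:
    """Relative-abundance vector of one consumer group at a fixed rank.

    ``proportions`` sums to one; entry i is the proportion of diet item
    ``items[i]`` in the group's pooled diet.
    """

    group: str
    rank: str
    items: tuple[str, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", p)
        if len(self.items) != p.size:
            raise ValidationError("items and proportions length mismatch")
        if len(set(self.items)) != len(self.items):
            raise ValidationError("duplicate items in profile")
        if (p < 0).any():
            raise ValidationError("negative proportions")
        if p.size and abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"proportions sum to {p.sum():.12f}, not 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.items, self.proportions))


def resolve_rank_assignment(taxon: TaxonRecord, cfg: RunConfig) -> str:
    """Resolve the deepest trustworthy rank for *taxon* under the identity rule.

    Returns ``"species"``, ``"genus"``, ``"unresolved_below_genus"`` or,
    when no identity score is available, ``"unscored:<deepest-rank>"``
    (the taxon passes through at the deepest lineage rank present).
    """
    ident = taxon.best_identity_pct
    if ident is None:
        deepest = taxon.deepest_rank()
        return f"unscored:{deepest}" if deepest else "unscored:none"
    if (
        ident >= cfg.identity_species_threshold
        and taxon.single_best_hit is True
        and taxon.locally_distributed is not False
    ):
        return "species"
    if ident > cfg.identity_genus_threshold:
        return "genus"
    return "unresolved_below_genus"


def apply_rank_resolution(table: AbundanceTable, cfg: RunConfig) -> AbundanceTable:
    """Truncate each taxon's lineage to its resolved rank.

    Taxa resolved to genus lose their species name; taxa unresolved below
    genus lose both genus and species and will pool into the unassigned
    bucket at those ranks.  Unscored taxa keep their lineage as is.
    """
    cut_after = {"species": "species", "genus": "genus", "unresolved_below_genus": "family"}
    new_taxa = []
    for t in table.taxa:
        res = resolve_rank_assignment(t, cfg)
        if res.startswith("unscored"):
            new_taxa.append(t)
            continue
        keep_to = RANK_ORDER.index(cut_after[res])
        lineage = {r: n for r, n in t.lineage.items() if RANK_ORDER.index(r) <= keep_to}
        new_taxa.append(replace(t, lineage=lineage))
    return AbundanceTable(list(table.samples), new_taxa, table.counts.copy())


def aggregate_to_rank(table: AbundanceTable, rank: str, cfg: RunConfig | None = None
                      ) -> AbundanceTable:
    """Sum counts of all taxa sharing a name at *rank*.

    Taxa whose lineage does not reach *rank* are pooled into a single
    ``Unassigned@<rank>`` bucket, so total reads per sample are conserved.
    The aggregated table's taxa carry the truncated shared lineage.
    """
    if rank not in RANK_ORDER:
        raise ValidationError(f"rank {rank!r} not in {RANK_ORDER}")
    depth = RANK_ORDER.index(rank)
    groups: dict[str, dict] = {}
    order: list[str] = []
    for j, t in enumerate(table.taxa):
        name = t.name_at(rank)
        if name is None:
            key = UNASSIGNED_PREFIX + rank
            lineage = {}
        else:
            key = name
            lineage = {r: n for r, n in t.lineage.items() if RANK_ORDER.index(r) <= depth}
        if key not in groups:
            groups[key] = {"lineage": lineage, "cols": []}
            order.append(key)
        groups[key]["cols"].append(j)
    taxa = []
    counts = np.zeros((table.n_samples, len(order)), dtype=np.int64)
    for i, key in enumerate(order):
        g = groups[key]
        counts[:, i] = table.counts[:, g["cols"]].sum(axis=1)
        taxa.append(TaxonRecord(taxon_id=key, lineage=g["lineage"], unresolved_gap=True))
    out = AbundanceTable(list(table.samples), taxa, counts)
    assert np.array_equal(out.counts.sum(axis=1), table.counts.sum(axis=1)), (
        "read conservation violated under aggregation"
    )
    return out


def _is_host(taxon: TaxonRecord, host_filter: dict[str, str] | None) -> bool:
    if not host_filter:
        return False
    return all(taxon.lineage.get(r) == n for r, n in host_filter.items())


def group_composition(
    table: AbundanceTable,
    metadata: list[SampleMetadata],
    group: str,
    cfg: RunConfig,
) -> CompositionProfile:
    """Relative-abundance profile of one consumer species at the table's rank.

    Counts are pooled across the group's samples by default (matching a
    pooled-stomach design where per-species proportions are reported once);
    ``cfg.pooling == "mean_of_samples"`` instead averages per-sample
    proportions, for sensitivity analysis.  Unassigned buckets and host
    taxa are excluded before renormalising (configurable).
    """
    sample_ids = [m.sample_id for m in metadata if m.consumer_species == group]
    idx = [table.samples.index(s) for s in sample_ids if s in table.samples]
    if not idx:
        raise ValidationError(f"no samples for group {group!r}")
    keep = [
        j
        for j, t in enumerate(table.taxa)
        if not (cfg.exclude_unassigned and t.taxon_id.startswith(UNASSIGNED_PREFIX))
        and not _is_host(t, cfg.host_lineage_filter)
    ]
    sub = table.counts[np.ix_(idx, keep)].astype(float)
    if cfg.pooling == "mean_of_samples":
        row_tot = sub.sum(axis=1, keepdims=True)
        if (row_tot == 0).any():
            raise ValidationError(f"group {group!r}: a sample has zero retained reads")
        pooled = (sub / row_tot).mean(axis=0)
    else:
        pooled = sub.sum(axis=0)
    total = pooled.sum()
    if total <= 0:
        raise ValidationError(f"group {group!r} has zero total reads after filtering")
    names = [table.taxa[j].taxon_id for j in keep]
    return CompositionProfile(
        group=group,
        rank=table.taxa[keep[0]].deepest_rank() or "otu",
        items=tuple(names),
        proportions=pooled / total,
    )


def top_k_items(profile: CompositionProfile, k: int = 15) -> CompositionProfile:
    """The k largest diet items, remainder pooled as ``Other``.

    Ties at the cut are broken by taxon name (lexicographic), so the
    selection is deterministic across runs.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    ranked = sorted(
        zip(profile.items, profile.proportions), key=lambda t: (-t[1], t[0])
    )
    head, tail = ranked[:k], ranked[k:]
    items = [n for n, _ in head]
    props = [p for _, p in head]
    if tail:
        items.append("Other")
        props.append(float(sum(p for _, p in tail)))
    return CompositionProfile(
        group=profile.group,
        rank=profile.rank,
        items=tuple(items),
        proportions=np.asarray(props, dtype=float),
    )
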
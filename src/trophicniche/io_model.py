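"""Shared data model and tabular I/O.

The pipeline operates on three tab-separated inputs:

* an abundance table — taxa as rows (taxon id + semicolon-delimited
  lineage string), samples as columns, integer read counts;
* an optional taxonomy/identity table carrying the best alignment
  identity per taxon, used by the rank-resolution rule;
* a sample metadata table (consumer species, elevation, marker).

On disk taxa are rows (the QIIME convention); in memory counts are held
samples x taxa.  Counts are raw integers throughout — relative abundances
are always derived, never stored, because the Chao1 estimator needs the
raw count granularity.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RANK_ORDER",
    "ValidationError",
    "ParseError",
    "TaxonRecord",
    "AbundanceTable",
    "SampleMetadata",
    "RunConfig",
    "read_abundance_table",
    "read_identity_table",
    "attach_identities",
    "read_metadata",
    "validate_metadata",
    "write_abundance_table",
    "write_metadata",
    "write_result_tables",
]

#: Taxonomic ranks in nesting order, kingdom outermost.
RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_GG_PREFIXES = {
    "k__": "kingdom",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}

ALLOWED_MARKERS = ("COI", "RbcL")

FLOAT_FORMAT = "%.4f"  # fixed output precision for all result tables


class ValidationError(ValueError):
    """An input violated a structural invariant."""


class ParseError(ValidationError):
    """A file could not be parsed into the data model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon (typically an OTU representative) with its lineage.

    ``lineage`` maps rank name -> taxon name over :data:`RANK_ORDER`;
    missing ranks are simply absent.  Ranks present must form a prefix of
    the rank order (no genus without family) unless ``unresolved_gap`` is
    set, which marks a deliberately gappy lineage.
    """

    taxon_id: str
    lineage: dict[str, str] = field(default_factory=dict)
    best_identity_pct: float | None = None
    single_best_hit: bool | None = None
    locally_distributed: bool | None = None
    unresolved_gap: bool = False

    def __post_init__(self) -> None:
        bad = set(self.lineage) - set(RANK_ORDER)
        if bad:
            raise ValidationError(f"taxon {self.taxon_id!r}: unknown ranks {sorted(bad)}")
        if not self.unresolved_gap:
            present = [r in self.lineage for r in RANK_ORDER]
            if any(present) and any(
                present[i] and not present[i - 1] for i in range(1, len(present))
            ):
                raise ValidationError(
                    f"taxon {self.taxon_id!r}: lineage ranks do not form a prefix "
                    f"of {RANK_ORDER}; pass unresolved_gap=True to allow gaps"
                )
        if self.best_identity_pct is not None and not (0.0 <= self.best_identity_pct <= 100.0):
            raise ValidationError(
                f"taxon {self.taxon_id!r}: identity {self.best_identity_pct} outside [0, 100]"
            )

    def deepest_rank(self) -> str | None:
        """Deepest rank present in the lineage, or ``None`` if empty."""
        for rank in reversed(RANK_ORDER):
            if rank in self.lineage:
                return rank
        return None

    def name_at(self, rank: str) -> str | None:
        return self.lineage.get(rank)


@dataclass
class AbundanceTable:
    """Integer read counts of food taxa per pooled sample.

    ``counts`` is samples x taxa (rows follow ``samples``, columns follow
    ``taxa``).  The single source from which every downstream statistic
    derives.
    """

    samples: list[str]
    taxa: list[TaxonRecord]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.samples), len(self.taxa)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.floor(self.counts)
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValidationError("counts must be integers (raw reads, not proportions)")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate taxon ids")
        empty = [s for s, row in zip(self.samples, self.counts) if row.sum() == 0]
        if empty:
            raise ValidationError(f"samples with zero total reads: {empty}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    def sample_counts(self, sample_id: str) -> np.ndarray:
        try:
            i = self.samples.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample {sample_id!r}") from None
        return self.counts[i]

    def subset_samples(self, keep: list[str]) -> "AbundanceTable":
        idx = [self.samples.index(s) for s in keep]
        return AbundanceTable(list(keep), list(self.taxa), self.counts[idx])


@dataclass(frozen=True)
class SampleMetadata:
    """Design information for one pooled sample."""

    sample_id: str
    consumer_species: str
    elevation_m: int
    marker: str

    def __post_init__(self) -> None:
        if self.marker not in ALLOWED_MARKERS:
            raise ValidationError(
                f"sample {self.sample_id!r}: marker {self.marker!r} not in {ALLOWED_MARKERS}"
            )


@dataclass
class RunConfig:
    """Knobs for one analysis run.

    Identity thresholds implement the annotation rule: species assignment
    needs >= ``identity_species_threshold`` percent identity with a single
    best hit; genus assignment needs identity strictly above
    ``identity_genus_threshold``.  Overlap thresholds classify Pianka
    overlap (strictly above 0.3 -> meaningful, strictly above 0.6 ->
    significant).
    """

    rank: str = "genus"
    presence_min_count: int = 1
    identity_species_threshold: float = 99.0
    identity_genus_threshold: float = 98.0
    overlap_thresholds: tuple[float, float] = (0.3, 0.6)
    alpha: float = 0.05
    lda_cutoff: float = 2.0
    nmds_dims: int = 2
    nmds_restarts: int = 4
    nmds_tol: float = 1e-7
    nmds_max_iter: int = 500
    permutations: int = 999
    rng_seed: int = 0
    host_lineage_filter: dict[str, str] | None = None
    shannon_base: float = np.e
    exclude_unassigned: bool = True
    pooling: str = "pooled_counts"  # or "mean_of_samples"

    def __post_init__(self) -> None:
        t_meaningful, t_significant = self.overlap_thresholds
        if not (0.0 < t_meaningful < t_significant <= 1.0):
            raise ValidationError(
                f"overlap thresholds must satisfy 0 < meaningful < significant <= 1, "
                f"got {self.overlap_thresholds}"
            )
        if self.rank not in RANK_ORDER:
            raise ValidationError(f"rank {self.rank!r} not in {RANK_ORDER}")
        if self.presence_min_count < 1:
            raise ValidationError("presence_min_count must be >= 1")
        if self.pooling not in ("pooled_counts", "mean_of_samples"):
            raise ValidationError(f"unknown pooling mode {self.pooling!r}")

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Lineage parsing
# ---------------------------------------------------------------------------


def parse_lineage(text: str, *, row: str = "?") -> dict[str, str]:
    """Parse a semicolon-delimited lineage string into a rank -> name map.

    Accepts both greengenes-style ``k__Name;p__Name;...`` and bare
    ``Name;Name;...`` dialects; empty segments mark missing ranks.
    """
    lineage: dict[str, str] = {}
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return lineage
    segments = [s.strip() for s in str(text).split(";")]
    if len(segments) > len(RANK_ORDER):
        raise ParseError(
            f"row {row!r}: lineage has {len(segments)} segments, "
            f"more than the {len(RANK_ORDER)} recognised ranks"
        )
    for pos, seg in enumerate(segments):
        if not seg:
            continue
        prefix = seg[:3]
        if prefix in _GG_PREFIXES:
            rank, name = _GG_PREFIXES[prefix], seg[3:].strip()
            if not name:
                continue
        elif "__" in seg[:4]:
            raise ParseError(f"row {row!r}: unrecognised rank prefix in segment {seg!r}")
        else:
            rank, name = RANK_ORDER[pos], seg
        if rank in lineage:
            raise ParseError(f"row {row!r}: rank {rank!r} given twice in lineage")
        lineage[rank] = name
    return lineage


def format_lineage(lineage: dict[str, str]) -> str:
    """Render a lineage as greengenes-style prefixes down to the deepest rank."""
    prefix_of = {v: k for k, v in _GG_PREFIXES.items()}
    deepest = -1
    for i, rank in enumerate(RANK_ORDER):
        if rank in lineage:
            deepest = i
    parts = []
    for rank in RANK_ORDER[: deepest + 1]:
        parts.append(prefix_of[rank] + lineage.get(rank, ""))
    return ";".join(parts)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if df.empty and df.columns.empty:
        raise ValidationError(f"{path}: empty file")
    return df


def read_abundance_table(path) -> AbundanceTable:
    """Read a taxa-as-rows count TSV into an :class:`AbundanceTable`.

    First column: taxon id.  Second column: semicolon-delimited lineage.
    Remaining columns: integer counts, one per sample.
    """
    # pandas deduplicates repeated column names on read, so check the raw header
    with open(path, encoding="utf-8") as fh:
        header = next((ln for ln in fh if ln.strip() and not ln.startswith("#")), "")
    raw_cols = header.rstrip("\n").split("\t")[2:]
    if len(set(raw_cols)) != len(raw_cols):
        raise ValidationError(f"{path}: duplicate sample columns")
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: need taxon_id, lineage and >=1 sample column")
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no taxon rows")
    sample_cols = list(df.columns[2:])
    taxa = []
    for _, r in df.iterrows():
        tid = r.iloc[0]
        taxa.append(TaxonRecord(taxon_id=tid, lineage=parse_lineage(r.iloc[1], row=tid)))
    ids = [t.taxon_id for t in taxa]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate taxon ids {dupes}")
    try:
        counts = df[sample_cols].astype(np.int64).to_numpy().T  # -> samples x taxa
    except (ValueError, TypeError):
        raise ValidationError(f"{path}: non-integer count entries") from None
    return AbundanceTable(samples=sample_cols, taxa=taxa, counts=counts)


def read_identity_table(path) -> dict[str, dict]:
    """Read per-taxon alignment identity annotations.

    Columns: ``taxon_id``, ``best_identity_pct`` and optionally
    ``single_best_hit`` / ``locally_distributed`` (true/false).
    """
    df = _read_tsv(path)
    required = {"taxon_id", "best_identity_pct"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: needs columns {sorted(required)}")
    out: dict[str, dict] = {}
    for _, r in df.iterrows():
        tid = r["taxon_id"]
        if tid in out:
            raise ValidationError(f"{path}: duplicate taxon_id {tid!r}")
        rec: dict = {"best_identity_pct": float(r["best_identity_pct"])}
        for col in ("single_best_hit", "locally_distributed"):
            if col in df.columns and r[col] != "":
                val = str(r[col]).strip().lower()
                if val not in ("true", "false"):
                    raise ValidationError(f"{path}: {col} for {tid!r} must be true/false")
                rec[col] = val == "true"
        out[tid] = rec
    return out


def attach_identities(table: AbundanceTable, identities: dict[str, dict]) -> AbundanceTable:
    """Return a copy of *table* with identity annotations merged onto taxa."""
    taxa = [
        replace(t, **identities[t.taxon_id]) if t.taxon_id in identities else t
        for t in table.taxa
    ]
    return AbundanceTable(list(table.samples), taxa, table.counts.copy())


def read_metadata(path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (sample_id, consumer_species, elevation_m, marker)."""
    df = _read_tsv(path)
    required = ["sample_id", "consumer_species", "elevation_m", "marker"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    records = []
    seen = set()
    for _, r in df.iterrows():
        sid = r["sample_id"]
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            elev = int(r["elevation_m"])
        except ValueError:
            raise ValidationError(f"{path}: non-integer elevation for {sid!r}") from None
        records.append(
            SampleMetadata(
                sample_id=sid,
                consumer_species=r["consumer_species"],
                elevation_m=elev,
                marker=r["marker"],
            )
        )
    return records


def validate_metadata(table: AbundanceTable, metadata: list[SampleMetadata]) -> None:
    """Cross-validate a metadata list against an abundance table.

    Every table sample needs exactly one metadata row, and the marker must
    be uniform within one analysis run.
    """
    by_id = {m.sample_id: m for m in metadata}
    if len(by_id) != len(metadata):
        raise ValidationError("duplicate sample ids in metadata")
    missing = [s for s in table.samples if s not in by_id]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    markers = {by_id[s].marker for s in table.samples}
    if len(markers) > 1:
        raise ValidationError(
            f"multiple markers {sorted(markers)} in one run; analyse markers separately"
        )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write an :class:`AbundanceTable` as the taxa-as-rows TSV dialect read back
    by :func:`read_abundance_table` (exact round-trip)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("taxon_id\tlineage\t" + "\t".join(table.samples) + "\n")
        for j, t in enumerate(table.taxa):
            row = "\t".join(str(int(c)) for c in table.counts[:, j])
            fh.write(f"{t.taxon_id}\t{format_lineage(t.lineage)}\t{row}\n")


def write_metadata(metadata: list[SampleMetadata], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tconsumer_species\televation_m\tmarker\n")
        for m in metadata:
            fh.write(f"{m.sample_id}\t{m.consumer_species}\t{m.elevation_m}\t{m.marker}\n")


def write_result_tables(results: dict[str, pd.DataFrame], out_dir, *, header_comments:
                        dict[str, str] | None = None) -> list[str]:
    """Write each result DataFrame as ``<name>.tsv`` under *out_dir*.

    Floats are rendered at fixed 4-decimal precision.  An empty DataFrame
    produces a headers-only file.  Returns the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise IOError(f"output directory {out_dir!r} is not writable")
    written = []
    for name, df in results.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        buf = io.StringIO()
        if header_comments and name in header_comments:
            for line in header_comments[name].splitlines():
                buf.write(f"# {line}\n")
        df.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(buf.getvalue())
        written.append(path)
    return written
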
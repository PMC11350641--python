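"""End-to-end orchestration: taxonomy -> niche -> diversity -> ordination
-> biomarkers, with a reproducibility manifest.

One run analyses one marker (animal-derived food via COI, plant-derived
via RbcL); the two food classes are analysed in separate runs.  Niche
breadth and overlap are reported at the order and the configured target
rank (default genus), mirroring the two-rank layout of a trophic-niche
breadth table; alpha diversity is computed at the original OTU/taxon
granularity, so it is independent of the rank choice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
import sys

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import lefse_biomarkers
from .diversity import alpha_diversity, kruskal_wallis
from .io_model import (
    AbundanceTable,
    RunConfig,
    SampleMetadata,
    ValidationError,
    validate_metadata,
    write_result_tables,
)
from .niche import levins_breadth, overlap_matrix
from .ordination import anosim, jaccard_distances, nmds_embed
from .taxonomy import (
    aggregate_to_rank,
    apply_rank_resolution,
    group_composition,
    top_k_items,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_pipeline", "write_report"]

FOOD_CLASS = {"COI": "animal", "RbcL": "plant"}


@dataclasses.dataclass
class PipelineReport:
    """All result tables of one run plus the manifest that reproduces it."""

    composition: pd.DataFrame  # group x rank x taxon -> proportion (top-15 + Other)
    breadth: pd.DataFrame
    overlap: pd.DataFrame
    diversity: pd.DataFrame
    diversity_tests: pd.DataFrame
    nmds: pd.DataFrame
    nmds_stress: float
    anosim: pd.DataFrame
    biomarkers: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "composition": self.composition,
            "breadth": self.breadth,
            "overlap": self.overlap,
            "diversity": self.diversity,
            "diversity_tests": self.diversity_tests,
            "nmds_coordinates": self.nmds,
            "anosim": self.anosim,
            "biomarkers": self.biomarkers,
        }


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(
    table: AbundanceTable,
    metadata: list[SampleMetadata],
    cfg: RunConfig | None = None,
    *,
    input_paths: dict[str, str] | None = None,
) -> PipelineReport:
    """Execute the full analysis on a validated table + metadata pair.

    Any stage failure raises with the stage name prefixed; nothing is
    written to disk here (see :func:`write_report`).
    """
    cfg = cfg or RunConfig()
    stage = "validate"
    try:
        validate_metadata(table, metadata)
        by_id = {m.sample_id: m for m in metadata}
        marker = by_id[table.samples[0]].marker
        food_class = FOOD_CLASS[marker]
        groups = sorted({by_id[s].consumer_species for s in table.samples})
        logger.info("%d samples, %d taxa, %d groups, marker %s",
                    table.n_samples, table.n_taxa, len(groups), marker)

        stage = "taxonomy"
        _stage(stage)
        resolved = apply_rank_resolution(table, cfg)
        ranks = list(dict.fromkeys(["order", cfg.rank]))
        comp_rows, breadth_rows, overlap_rows = [], [], []
        for rank in ranks:
            agg = aggregate_to_rank(resolved, rank, cfg)
            profiles = [group_composition(agg, metadata, g, cfg) for g in groups]
            for prof in profiles:
                for item, p in zip(*[top_k_items(prof, 15).items,
                                     top_k_items(prof, 15).proportions]):
                    comp_rows.append(
                        {"food_class": food_class, "rank": rank, "group": prof.group,
                         "taxon": item, "proportion": p}
                    )
                b = levins_breadth(prof, food_class=food_class)
                breadth_rows.append(
                    {"group": b.group, "food_class": food_class, "rank": rank, "B": b.B}
                )
            if len(profiles) >= 2:
                for ov in overlap_matrix(profiles, food_class=food_class, cfg=cfg):
                    overlap_rows.append(
                        {"group_j": ov.group_j, "group_k": ov.group_k,
                         "food_class": food_class, "rank": rank, "O": ov.O,
                         "category": ov.category}
                    )

        stage = "diversity"
        _stage(stage)
        div = alpha_diversity(table, base=cfg.shannon_base)
        div_df = pd.DataFrame(
            {
                "sample_id": [d.sample_id for d in div],
                "group": [by_id[d.sample_id].consumer_species for d in div],
                "observed_richness": [d.observed_richness for d in div],
                "chao1": [d.chao1 for d in div],
                "shannon": [d.shannon for d in div],
                "simpson": [d.simpson for d in div],
            }
        )
        test_rows = []
        for index in ("chao1", "shannon", "simpson"):
            vals = [div_df.loc[div_df["group"] == g, index].tolist() for g in groups]
            if all(len(v) >= 1 for v in vals) and len(groups) >= 2:
                res = kruskal_wallis(vals)
                test_rows.append(
                    {"index": index, "H": res.statistic, "p_value": res.p_value,
                     "groups": ";".join(groups)}
                )

        stage = "ordination"
        _stage(stage)
        dm = jaccard_distances(table, cfg)
        ord_res = nmds_embed(dm, cfg)
        nmds_df = pd.DataFrame(
            ord_res.coordinates,
            columns=[f"NMDS{i + 1}" for i in range(ord_res.coordinates.shape[1])],
        )
        nmds_df.insert(0, "sample_id", ord_res.ids)
        nmds_df.insert(1, "group", [by_id[s].consumer_species for s in ord_res.ids])
        an = anosim(dm, {s: by_id[s].consumer_species for s in dm.ids}, cfg)
        anosim_df = pd.DataFrame(
            [{"R": an.R, "p_value": an.p_value,
              "n_permutations": an.n_permutations, "exact": an.exact}]
        )

        stage = "biomarkers"
        _stage(stage)
        recs = lefse_biomarkers(table, metadata, cfg)
        bio_df = pd.DataFrame(
            [
                {"rank": r.rank, "feature": r.feature, "enriched_group": r.enriched_group,
                 "kw_p": r.kw_p,
                 "lda_score": r.lda_score if np.isfinite(r.lda_score) else float("nan"),
                 "passed": r.passed}
                for r in recs
            ],
            columns=["rank", "feature", "enriched_group", "kw_p", "lda_score", "passed"],
        )
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}").with_traceback(sys.exc_info()[2])

    manifest = {
        "tool": "trophicniche",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "seed": cfg.rng_seed,
        "marker": marker,
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "groups": groups,
        "input_checksums": {
            k: _checksum(p) for k, p in (input_paths or {}).items() if os.path.exists(p)
        },
    }
    return PipelineReport(
        composition=pd.DataFrame(comp_rows),
        breadth=pd.DataFrame(breadth_rows),
        overlap=pd.DataFrame(overlap_rows),
        diversity=div_df,
        diversity_tests=pd.DataFrame(test_rows),
        nmds=nmds_df,
        nmds_stress=ord_res.stress,
        anosim=anosim_df,
        biomarkers=bio_df,
        manifest=manifest,
    )


def write_report(report: PipelineReport, out_dir: str) -> list[str]:
    """Write all result TSVs plus the JSON manifest; on failure nothing
    partial is left behind."""
    os.makedirs(out_dir, exist_ok=True)
    tmp_marker = os.path.join(out_dir, ".partial")
    open(tmp_marker, "w").close()
    try:
        header_comments = {
            "nmds_coordinates": (
                f"Kruskal stress-1 = {report.nmds_stress:.6f} "
                f"({'favorable' if report.nmds_stress < 0.1 else 'poor'}: "
                f"below 0.1 is conventionally reliable)"
            ),
            "diversity": f"shannon computed in base {report.manifest['config']['shannon_base']}",
        }
        written = write_result_tables(report.tables(), out_dir,
                                      header_comments=header_comments)
        manifest_path = os.path.join(out_dir, "manifest.json")
        with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(report.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(manifest_path)
    except Exception:
        for name in list(report.tables()) + ["manifest"]:
            p = os.path.join(out_dir, f"{name}.tsv")
            if os.path.exists(p):
                os.remove(p)
        raise
    finally:
        if os.path.exists(tmp_marker):
            os.remove(tmp_marker)
    return written
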
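"""End-to-end analysis: annotate, profile, cluster and compare site datasets.

Ties the stages together into the report bundle a full study produces:
an annotation summary (region classes + feature hits per dataset), a
repeat summary, TSS-distance profiles, ChIP density profiles, a
chromatin-state summary, a cluster summary and the pairwise Fisher
comparison table, plus a manifest recording configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import io as rio
from .annotate import AnnotationConfig, annotate_sites, region_summary, repeat_summary
from .clusters import call_clusters, cluster_summary, derive_threshold
from .compare import compare_categories
from .core import FeatureTrack, IntegrationSite, SyntheticGenome
from .profiles import ProfileConfig, chip_density, state_summary, tss_profile

logger = logging.getLogger(__name__)

REGION_CATEGORIES = ["intergenic", "tss_proximal", "intragenic"]


@dataclass
class RunConfig:
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    cluster_k: int = 3
    cluster_alpha: float = 0.01
    compare_alpha: float = 0.01
    seed: int = 0


def run_all(
    genome: SyntheticGenome,
    sites_by_dataset: Mapping[str, Sequence[IntegrationSite]],
    outdir,
    config: RunConfig = RunConfig(),
    mark_fragments: Optional[Mapping[str, FeatureTrack]] = None,
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage and write the report bundle to outdir.

    Returns the in-memory tables keyed by report name. Missing mark
    fragments skip the ChIP-density stage with a warning; every other
    stage always runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    repeats = genome.features.get("repeats", FeatureTrack("repeats"))
    feature_classes = [n for n in genome.features if n != "repeats"]

    annotations = {
        ds: annotate_sites(
            list(sites), genome.genes, genome.features, repeats, config.annotation
        )
        for ds, sites in sites_by_dataset.items()
    }

    results["annotation_summary"] = region_summary(annotations, feature_classes)
    rio.write_table(results["annotation_summary"], outdir / "annotation_summary.tsv")

    results["repeat_summary"] = repeat_summary(sites_by_dataset, repeats)
    rio.write_table(results["repeat_summary"], outdir / "repeat_summary.tsv")

    profile_rows = {}
    for ds, anns in annotations.items():
        distances = [a.signed_tss_distance for a in anns]
        for resolution in ("coarse", "fine"):
            prof = tss_profile(distances, config.profile, resolution)
            profile_rows[(ds, resolution)] = pd.Series(
                prof.fraction_per_bin, index=prof.bin_midpoints
            )
    tss_tables = {
        res: pd.DataFrame(
            {ds: s for (ds, r), s in profile_rows.items() if r == res}
        )
        for res in ("coarse", "fine")
    }
    for res, table in tss_tables.items():
        table.index.name = "bin_midpoint"
        results[f"tss_profile_{res}"] = table
        rio.write_table(table, outdir / f"tss_profile_{res}.tsv")

    if mark_fragments:
        chip_tables = []
        for mark, frags in mark_fragments.items():
            for ds, sites in sites_by_dataset.items():
                prof = chip_density(list(sites), frags, config.profile)
                prof.insert(0, "mark", mark)
                prof.insert(1, "dataset", ds)
                chip_tables.append(prof)
        results["chip_density"] = pd.concat(chip_tables, ignore_index=True)
        rio.write_table(results["chip_density"], outdir / "chip_density.tsv", index=False)
    else:
        logger.warning("no mark fragments supplied; ChIP-density stage skipped")

    results["state_summary"] = state_summary(
        sites_by_dataset, genome.marks, config=config.annotation
    )
    rio.write_table(results["state_summary"], outdir / "state_summary.tsv")

    cluster_rows = []
    for ds, sites in sites_by_dataset.items():
        definition = derive_threshold(
            n=len(sites), L=genome.total_length,
            k=config.cluster_k, alpha=config.cluster_alpha,
        )
        clusters = call_clusters(list(sites), definition)
        row = {"dataset": ds, "n": len(sites), "w": definition.w}
        row.update(cluster_summary(clusters, len(sites)))
        cluster_rows.append(row)
    results["cluster_summary"] = pd.DataFrame(cluster_rows).set_index("dataset")
    rio.write_table(results["cluster_summary"], outdir / "cluster_summary.tsv")

    summary = results["annotation_summary"]
    counts = {
        ds: {
            cat: round(summary.loc[ds, f"{cat}_pct"] * summary.loc[ds, "total"] / 100)
            for cat in REGION_CATEGORIES
        }
        for ds in summary.index
    }
    totals = {ds: int(summary.loc[ds, "total"]) for ds in summary.index}
    results["comparisons"] = compare_categories(
        counts, REGION_CATEGORIES, totals, alpha=config.compare_alpha
    )
    rio.write_table(results["comparisons"], outdir / "comparisons.tsv", index=False)

    manifest = {
        "config": {
            "annotation": asdict(config.annotation),
            "profile": asdict(config.profile),
            "cluster_k": config.cluster_k,
            "cluster_alpha": config.cluster_alpha,
            "compare_alpha": config.compare_alpha,
            "seed": config.seed,
        },
        "datasets": {ds: len(s) for ds, s in sites_by_dataset.items()},
        "genome_length": genome.total_length,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return results
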
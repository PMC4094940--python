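"""Site annotation against gene models and feature tracks.

Window conventions (all inclusive, distances in bp from the single site
base):

* TSS-proximal: |signed distance to the nearest TSS| <= 2,500
* intragenic: inside a transcription span and > 2,500 bp from every TSS
* intergenic: everything else
* feature overlap: a feature class is hit when one of its intervals
  overlaps the +/- 1 kb window around the site by >= 1 bp
* target genes: every gene whose TSS lies within +/- 50 kb of the site
* repeats: assigned only when the site base itself falls inside a repeat
  interval (no window)
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import FeatureTrack, GeneModel, IntegrationSite

logger = logging.getLogger(__name__)


class RegionClass(enum.Enum):
    TSS_PROXIMAL = "TSS_PROXIMAL"
    INTRAGENIC = "INTRAGENIC"
    INTERGENIC = "INTERGENIC"


@dataclass(frozen=True)
class AnnotationConfig:
    tss_window: int = 2_500
    feature_window: int = 1_000
    target_gene_window: int = 50_000
    min_overlap: int = 1

    def __post_init__(self) -> None:
        if min(self.tss_window, self.feature_window, self.target_gene_window) <= 0:
            raise ValueError("all windows must be > 0")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class SiteAnnotation:
    site: IntegrationSite
    region: RegionClass
    signed_tss_distance: Optional[int]
    target_genes: list[str] = field(default_factory=list)
    features_hit: set[str] = field(default_factory=set)
    repeat_family: Optional[str] = None


class GeneIndex:
    """Per-chromosome arrays of deduplicated gene models for fast lookup.

    Transcript isoforms sharing (chrom, strand, tss, span) collapse to one
    model so a promoter shared by many isoforms is counted once.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        seen: dict[tuple, GeneModel] = {}
        for g in genes:
            key = (g.chrom, g.strand, g.tss, g.tx_start, g.tx_end)
            seen.setdefault(key, g)
        self.genes: list[GeneModel] = sorted(
            seen.values(), key=lambda g: (g.chrom, g.tx_start, g.gene_id)
        )
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._tss_sorted: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        for chrom, gs in self._by_chrom.items():
            order = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss_sorted[chrom] = (
                np.asarray([g.tss for g in order], dtype=np.int64),
                order,
            )

    def on_chrom(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def genes_with_tss_near(self, chrom: str, pos: int, window: int) -> list[GeneModel]:
        """Genes with |tss - pos| <= window, sorted by |distance| then id."""
        entry = self._tss_sorted.get(chrom)
        if entry is None:
            return []
        tss, order = entry
        lo = int(np.searchsorted(tss, pos - window, side="left"))
        hi = int(np.searchsorted(tss, pos + window, side="right"))
        hits = order[lo:hi]
        return sorted(hits, key=lambda g: (abs(g.tss - pos), g.gene_id))


def _as_index(genes) -> GeneIndex:
    return genes if isinstance(genes, GeneIndex) else GeneIndex(genes)


def classify_region(
    site: IntegrationSite,
    genes,
    config: AnnotationConfig = AnnotationConfig(),
) -> RegionClass:
    """Classify a site as TSS-proximal, intragenic or intergenic.

    Classes are exclusive with precedence TSS_PROXIMAL > INTRAGENIC >
    INTERGENIC across all (possibly overlapping) genes. A chromosome with
    no annotated gene yields INTERGENIC.
    """
    index = _as_index(genes)
    chrom_genes = index.on_chrom(site.chrom)
    if not chrom_genes:
        return RegionClass.INTERGENIC
    near = index.genes_with_tss_near(site.chrom, site.pos, config.tss_window)
    if near:
        return RegionClass.TSS_PROXIMAL
    for g in chrom_genes:
        if g.contains(site.pos):
            return RegionClass.INTRAGENIC
    return RegionClass.INTERGENIC


def tss_distance(
    site: IntegrationSite,
    genes,
    window: Optional[int] = 50_000,
) -> Optional[int]:
    """Signed distance from the site to the nearest TSS within +/- window.

    The sign follows the gene's strand: positive means downstream of the
    TSS in gene orientation. Ties on |distance| break lexicographically on
    gene_id. Returns None when no TSS lies within the window (such sites
    are excluded from distance profiles).
    """
    index = _as_index(genes)
    w = window if window is not None else 2**62
    near = index.genes_with_tss_near(site.chrom, site.pos, w)
    if not near:
        return None
    g = near[0]
    d = site.pos - g.tss
    return int(d if g.strand == "+" else -d)


def annotate_features(
    site: IntegrationSite,
    features: Mapping[str, FeatureTrack],
    config: AnnotationConfig = AnnotationConfig(),
) -> set[str]:
    """Feature classes whose intervals overlap the site's +/- 1 kb window.

    The window around a 1-bp site [pos, pos+1) is
    [pos - feature_window, pos + feature_window + 1); an overlap of
    >= min_overlap bp (default 1) scores a hit.
    """
    w_start = site.pos - config.feature_window
    w_end = site.pos + config.feature_window + 1
    hit: set[str] = set()
    for cls, track in features.items():
        for iv in track.overlapping(site.chrom, w_start, w_end):
            overlap = min(iv.end, w_end) - max(iv.start, w_start)
            if overlap >= config.min_overlap:
                hit.add(cls)
                break
    return hit


def assign_repeat(site: IntegrationSite, repeats: FeatureTrack) -> Optional[str]:
    """Repeat family directly targeted by the site base itself.

    Unlike other features, no window is applied: the site must fall inside
    the repeat interval. Overlapping repeats resolve to the smallest
    interval, then lexicographic family.
    """
    hits = repeats.containing(site.chrom, site.pos)
    if not hits:
        return None
    hits.sort(key=lambda iv: (iv.length, iv.label))
    return hits[0].label


def target_genes(
    site: IntegrationSite,
    genes,
    config: AnnotationConfig = AnnotationConfig(),
) -> list[str]:
    """Gene ids with TSS within +/- target_gene_window, sorted by |distance|."""
    index = _as_index(genes)
    return [
        g.gene_id
        for g in index.genes_with_tss_near(
            site.chrom, site.pos, config.target_gene_window
        )
    ]


def annotate_sites(
    sites: Sequence[IntegrationSite],
    genes,
    features: Mapping[str, FeatureTrack] | None = None,
    repeats: Optional[FeatureTrack] = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> list[SiteAnnotation]:
    """Full annotation of a site list (region, TSS distance, targets, features)."""
    index = _as_index(genes)
    features = features or {}
    out: list[SiteAnnotation] = []
    for site in sites:
        out.append(
            SiteAnnotation(
                site=site,
                region=classify_region(site, index, config),
                signed_tss_distance=tss_distance(
                    site, index, config.target_gene_window
                ),
                target_genes=target_genes(site, index, config),
                features_hit=annotate_features(site, features, config),
                repeat_family=(
                    assign_repeat(site, repeats) if repeats is not None else None
                ),
            )
        )
    return out


def region_summary(
    annotations_by_dataset: Mapping[str, Sequence[SiteAnnotation]],
    feature_classes: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-dataset percentage table: region classes and feature-hit rates.

    One row per dataset with columns Intergenic/TSS-proximal/Intragenic (%)
    which sum to 100, one percentage column per feature class, and the
    dataset size.
    """
    rows = []
    for dataset, anns in annotations_by_dataset.items():
        n = len(anns)
        if n == 0:
            raise ValueError(f"dataset {dataset!r} has no annotated sites")
        counts = {rc: 0 for rc in RegionClass}
        feat_counts = {fc: 0 for fc in feature_classes}
        for a in anns:
            counts[a.region] += 1
            for fc in feature_classes:
                if fc in a.features_hit:
                    feat_counts[fc] += 1
        row = {
            "dataset": dataset,
            "intergenic_pct": 100.0 * counts[RegionClass.INTERGENIC] / n,
            "tss_proximal_pct": 100.0 * counts[RegionClass.TSS_PROXIMAL] / n,
            "intragenic_pct": 100.0 * counts[RegionClass.INTRAGENIC] / n,
        }
        for fc in feature_classes:
            row[f"{fc}_pct"] = 100.0 * feat_counts[fc] / n
        row["total"] = n
        rows.append(row)
    return pd.DataFrame(rows).set_index("dataset")


def repeat_summary(
    sites_by_dataset: Mapping[str, Sequence[IntegrationSite]],
    repeats: FeatureTrack,
    families: Sequence[str] = ("LINE", "SINE", "Satellite", "LTR", "Other"),
) -> pd.DataFrame:
    """Per-dataset percentages of sites inside repeats, split by family."""
    rows = []
    for dataset, sites in sites_by_dataset.items():
        n = len(sites)
        if n == 0:
            raise ValueError(f"dataset {dataset!r} is empty")
        fam_counts = {f: 0 for f in families}
        in_repeat = 0
        for s in sites:
            fam = assign_repeat(s, repeats)
            if fam is not None:
                in_repeat += 1
                fam_counts[fam if fam in fam_counts else "Other"] += 1
        row = {"dataset": dataset, "repeat_pct": 100.0 * in_repeat / n}
        for f in families:
            row[f"{f}_pct"] = 100.0 * fam_counts[f] / n
        row["total"] = n
        rows.append(row)
    return pd.DataFrame(rows).set_index("dataset")


def expressed_target_fraction(
    annotations: Sequence[SiteAnnotation],
    expression: Mapping[str, float],
    threshold: float = 0.0,
) -> Optional[dict]:
    """Fraction of distinct target genes expressed above a threshold.

    Genes absent from the expression table count as not expressed and are
    reported separately. Returns None when no site has any target gene.
    """
    targets: set[str] = set()
    for a in annotations:
        targets.update(a.target_genes)
    if not targets:
        return None
    expressed = sum(1 for g in targets if expression.get(g, -np.inf) > threshold)
    missing = sum(1 for g in targets if g not in expression)
    return {
        "fraction_expressed": expressed / len(targets),
        "n_targets": len(targets),
        "n_missing_from_table": missing,
    }
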
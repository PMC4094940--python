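"""Numerosity-adjusted integration-cluster (hot-spot) calling.

The cluster window is adjusted to the size of each dataset: sites are
modelled as a homogeneous Poisson process of rate n/L on an effective
genome of length L, and w is the largest window such that the probability
of finding >= k-1 further sites within w downstream of a given site is
<= alpha. A cluster is then any maximal chain of >= k sites in which some
k-subset spans <= w bp; chained qualifying windows merge, so clusters of
arbitrary size are representable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import poisson

from .core import IntegrationSite, Interval, sites_to_positions

logger = logging.getLogger(__name__)

_W_CAP = 10**9  # guard for alpha -> 1 (window would diverge)


@dataclass(frozen=True)
class ClusterDefinition:
    """Scan parameters: >= k sites within w bp, at significance alpha for n sites on L bp."""

    k: int
    w: int
    alpha: float
    n: int
    L: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.w <= 0:
            raise ValueError("w must be > 0")
        if self.n < self.k:
            raise ValueError("cluster order exceeds dataset size")


@dataclass(frozen=True)
class Cluster:
    chrom: str
    start: int  # position of the first member site
    end: int  # position of the last member site
    site_count: int
    dataset: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start


def poisson_rate_root(k: int, alpha: float) -> float:
    """Solve P(Poisson(lam) >= k-1) = alpha for the expected count lam."""
    f = lambda lam: poisson.sf(k - 2, lam) - alpha
    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("failed to bracket the Poisson root")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def derive_threshold(
    n: int, L: int, k: int = 3, alpha: float = 0.01
) -> ClusterDefinition:
    """Derive the numerosity-adjusted window w for a dataset of n sites.

    With lam* the root of P(Poisson(lam) >= k-1) = alpha, the window is
    w = floor(lam* . L / n): the largest integer window keeping the
    downstream-neighbour excess probability at or below alpha (1-bp
    resolution). A degenerate sub-bp window (extremely small alpha or very
    dense data) is reported as w = 1 with a warning.
    """
    if L <= 0:
        raise ValueError("L must be > 0")
    if n < k:
        raise ValueError("cluster order exceeds dataset size")
    lam = poisson_rate_root(k, alpha)
    w = math.floor(lam * L / n)
    if w < 1:
        logger.warning(
            "derived window below 1 bp (lam=%.3g, n=%d, L=%d); reporting w=1",
            lam, n, L,
        )
        w = 1
    w = min(w, _W_CAP)
    return ClusterDefinition(k=k, w=w, alpha=alpha, n=n, L=L)


def call_clusters(
    sites: Sequence[IntegrationSite], definition: ClusterDefinition
) -> list[Cluster]:
    """Call maximal clusters of >= k sites where some k-run spans <= w bp.

    Per chromosome, positions are sorted and every run of k consecutive
    sites spanning <= w qualifies; overlapping qualifying runs chain into
    one maximal cluster (equivalent to exhaustive k-subset enumeration with
    transitive merging). Sites belong to at most one cluster. Duplicate
    positions count as distinct sites.
    """
    k, w = definition.k, definition.w
    dataset = sites[0].dataset if sites else ""
    clusters: list[Cluster] = []
    for chrom, pos in sorted(sites_to_positions(sites).items()):
        m = len(pos)
        if m < k:
            continue
        spans_ok = pos[k - 1 :] - pos[: m - k + 1] <= w  # run i covers sites i..i+k-1
        qualifying = np.flatnonzero(spans_ok)
        if len(qualifying) == 0:
            continue
        # runs a < b share a site iff b <= a + k - 1; chain such runs
        breaks = np.flatnonzero(np.diff(qualifying) > k - 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(qualifying) - 1]))
        for s_idx, e_idx in zip(starts, ends):
            first = int(qualifying[s_idx])
            last = int(qualifying[e_idx]) + k - 1
            clusters.append(
                Cluster(
                    chrom=chrom,
                    start=int(pos[first]),
                    end=int(pos[last]),
                    site_count=last - first + 1,
                    dataset=dataset,
                )
            )
    return clusters


def cluster_summary(clusters: Sequence[Cluster], n: int) -> dict:
    """Headline cluster statistics for a dataset of n sites."""
    n_clusters = len(clusters)
    clustered = sum(c.site_count for c in clusters)
    return {
        "n_clusters": n_clusters,
        "pct_sites_in_clusters": 100.0 * clustered / n if n else 0.0,
        "mean_cluster_dimension": clustered / n_clusters if n_clusters else None,
        "max_cluster_dimension": max((c.site_count for c in clusters), default=None),
    }


def locus_report(
    sites_by_dataset: Mapping[str, Sequence[IntegrationSite]],
    loci: Sequence[Interval],
    definitions: Optional[Mapping[str, ClusterDefinition]] = None,
) -> pd.DataFrame:
    """Per-dataset per-locus site counts, cluster counts and site density.

    ``loci`` are named intervals (label = locus name). When cluster
    definitions are supplied (one per dataset), clusters overlapping each
    locus are counted; density is sites per Mb of locus length.
    """
    rows = []
    for dataset, sites in sites_by_dataset.items():
        clusters = (
            call_clusters(sites, definitions[dataset])
            if definitions and dataset in definitions
            else None
        )
        known_chroms = {s.chrom for s in sites}
        for locus in loci:
            if sites and locus.chrom not in known_chroms:
                logger.warning(
                    "locus %s on chromosome %s absent from dataset %s",
                    locus.label, locus.chrom, dataset,
                )
            n_sites = sum(
                1
                for s in sites
                if s.chrom == locus.chrom and locus.start <= s.pos < locus.end
            )
            row = {
                "dataset": dataset,
                "locus": locus.label,
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "n_sites": n_sites,
                "sites_per_mb": n_sites / (locus.length / 1e6),
            }
            if clusters is not None:
                row["n_clusters"] = sum(
                    1
                    for c in clusters
                    if c.chrom == locus.chrom
                    and c.start < locus.end
                    and locus.start <= c.end
                )
            rows.append(row)
    return pd.DataFrame(rows)
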
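"""TSS-distance histograms, ChIP-fragment density profiles and chromatin states.

The distance histogram uses right-closed bins ``(lo, hi]`` (lowest edge
inclusive), so a distance landing exactly on an interior edge is counted
in the bin ending there. ChIP density is mean per-bp fragment coverage per
bin over a fixed window centred on each site, averaged across sites;
profiles are not strand-flipped (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationConfig, annotate_features
from .core import FeatureTrack, IntegrationSite


@dataclass(frozen=True)
class ProfileConfig:
    span: int = 50_000
    coarse_bin: int = 2_500
    fine_span: int = 2_500
    fine_bin: int = 50  # 100 bp also supported
    chip_window: int = 5_000  # total window, i.e. +/- chip_window/2
    chip_bin: int = 50
    flip_by_site_strand: bool = False

    def __post_init__(self) -> None:
        if self.span % self.coarse_bin:
            raise ValueError("span must be divisible by coarse_bin")
        if self.fine_span % self.fine_bin:
            raise ValueError("fine_span must be divisible by fine_bin")
        if self.chip_window % self.chip_bin:
            raise ValueError("chip_window must be divisible by chip_bin")


@dataclass
class DistanceProfile:
    bin_edges: np.ndarray  # len nbins + 1
    fraction_per_bin: np.ndarray  # len nbins, sums to 1 over sites used
    n_sites_used: int
    n_dropped: int = 0

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def tss_profile(
    distances: Sequence[Optional[int]],
    config: ProfileConfig = ProfileConfig(),
    resolution: str = "coarse",
) -> DistanceProfile:
    """Histogram of signed TSS distances over [-span, +span].

    ``resolution`` selects the coarse (span/coarse_bin) or fine
    (fine_span/fine_bin) grid. Distances outside the span, and sites with
    no defined distance, are dropped and counted in ``n_dropped``.
    Fractions are normalised over the sites used.
    """
    if resolution == "coarse":
        span, width = config.span, config.coarse_bin
    elif resolution == "fine":
        span, width = config.fine_span, config.fine_bin
    else:
        raise ValueError("resolution must be 'coarse' or 'fine'")
    vals = np.asarray([d for d in distances if d is not None], dtype=np.int64)
    n_undefined = len(distances) - len(vals)
    in_range = vals[(vals >= -span) & (vals <= span)]
    n_dropped = n_undefined + (len(vals) - len(in_range))
    if len(in_range) == 0:
        raise ValueError("no distances within the profile span; nothing to profile")
    edges = np.arange(-span, span + width, width, dtype=np.int64)
    # right-closed bins (lo, hi]; values equal to -span fall in the first bin
    idx = np.searchsorted(edges, in_range, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return DistanceProfile(
        bin_edges=edges,
        fraction_per_bin=counts / counts.sum(),
        n_sites_used=int(len(in_range)),
        n_dropped=int(n_dropped),
    )


def chip_density(
    sites: Sequence[IntegrationSite],
    fragments: FeatureTrack,
    config: ProfileConfig = ProfileConfig(),
) -> pd.DataFrame:
    """Mean per-bp ChIP-fragment coverage per bin around sites.

    For each site, per-bp coverage is accumulated over the window
    [pos - chip_window/2, pos + chip_window/2) in ``chip_bin``-bp bins and
    averaged across sites. An empty fragment track yields a valid all-zero
    profile. Returns a DataFrame with bin offsets (midpoint relative to the
    site) and mean coverage.
    """
    if not sites:
        raise ValueError("no sites to profile")
    half = config.chip_window // 2
    nbins = config.chip_window // config.chip_bin
    acc = np.zeros(nbins, dtype=float)
    for site in sites:
        w_start = site.pos - half
        cov = np.zeros(config.chip_window, dtype=float)
        for iv in fragments.overlapping(site.chrom, w_start, w_start + config.chip_window):
            lo = max(iv.start - w_start, 0)
            hi = min(iv.end - w_start, config.chip_window)
            cov[lo:hi] += 1.0
        if config.flip_by_site_strand and site.strand == "-":
            cov = cov[::-1]
        acc += cov.reshape(nbins, config.chip_bin).mean(axis=1)
    mean_cov = acc / len(sites)
    offsets = np.arange(nbins) * config.chip_bin - half + config.chip_bin / 2.0
    return pd.DataFrame({"offset": offsets, "mean_coverage": mean_cov})


@dataclass(frozen=True)
class ChromatinStateRule:
    """A state matches when all required marks are present and no forbidden one is."""

    state: str
    required_marks: frozenset[str]
    forbidden_marks: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.required_marks & self.forbidden_marks:
            raise ValueError(
                f"rule {self.state}: required and forbidden marks overlap"
            )

    def matches(self, present: set[str]) -> bool:
        return self.required_marks <= present and not (self.forbidden_marks & present)


def default_state_rules() -> list[ChromatinStateRule]:
    """Promoter/Enhancer/Transcribed/Heterochromatin mark-combination table.

    H3K4me3 marks active promoters, H3K4me1 enhancers, H3K36me3 transcribed
    gene bodies and H3K27me3 repressed chromatin; forbidden sets make the
    states mutually exclusive in the common single-mark cases. Fully
    user-overridable (H3K27ac may be used as a qualifier in custom rules).
    """
    return [
        ChromatinStateRule("Promoter", frozenset({"H3K4me3"})),
        ChromatinStateRule("Enhancer", frozenset({"H3K4me1"}), frozenset({"H3K4me3"})),
        ChromatinStateRule(
            "Transcribed", frozenset({"H3K36me3"}), frozenset({"H3K4me1", "H3K4me3"})
        ),
        ChromatinStateRule(
            "Heterochromatin",
            frozenset({"H3K27me3"}),
            frozenset({"H3K4me1", "H3K4me3", "H3K36me3"}),
        ),
    ]


def assign_chromatin_state(
    site: IntegrationSite,
    mark_tracks: Mapping[str, FeatureTrack],
    rules: Optional[Sequence[ChromatinStateRule]] = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> Optional[str]:
    """State of the site, or None when no rule or several rules match.

    Mark presence uses the same +/- 1 kb window rule as feature annotation.
    A site is assigned only when it is unambiguously associated with exactly
    one chromatin state.
    """
    rules = list(rules) if rules is not None else default_state_rules()
    labels = [r.state for r in rules]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate state labels in rule table")
    present = annotate_features(site, mark_tracks, config)
    matching = [r.state for r in rules if r.matches(present)]
    return matching[0] if len(matching) == 1 else None


def state_summary(
    sites_by_dataset: Mapping[str, Sequence[IntegrationSite]],
    mark_tracks: Mapping[str, FeatureTrack],
    rules: Optional[Sequence[ChromatinStateRule]] = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> pd.DataFrame:
    """Fraction of sites per chromatin state per dataset (plus unassigned).

    Fractions are over ALL sites of the dataset and sum to 1 per row.
    """
    rules = list(rules) if rules is not None else default_state_rules()
    states = [r.state for r in rules]
    rows = []
    for dataset, sites in sites_by_dataset.items():
        n = len(sites)
        if n == 0:
            raise ValueError(f"dataset {dataset!r} is empty")
        counts = {s: 0 for s in states}
        unassigned = 0
        for site in sites:
            state = assign_chromatin_state(site, mark_tracks, rules, config)
            if state is None:
                unassigned += 1
            else:
                counts[state] += 1
        row = {"dataset": dataset}
        row.update({s: counts[s] / n for s in states})
        row["unassigned"] = unassigned / n
        row["total"] = n
        rows.append(row)
    return pd.DataFrame(rows).set_index("dataset")
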
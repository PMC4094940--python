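"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open ``[start, end)`` everywhere. An integration
site is a single genomic base: the first genomic nucleotide flanking the
3'-LTR vector-genome junction, strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
from intervaltree import IntervalTree


@dataclass(frozen=True)
class IntegrationSite:
    """One mapped vector-genome junction.

    ``pos`` is the 0-based coordinate of the first genomic base after the
    LTR junction. ``support`` counts reads collapsed into this site.
    Ambiguous sites (reads mapping to several near-equivalent positions)
    carry a ``match_group`` linking their alternate placements.
    """

    chrom: str
    pos: int
    strand: str
    dataset: str = ""
    support: int = 1
    ambiguous: bool = False
    match_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass(frozen=True)
class GeneModel:
    """A gene/transcript with a strand-aware transcription start site.

    The TSS is ``tx_start`` on the plus strand and ``tx_end - 1`` on the
    minus strand (last base of the half-open span).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"gene {self.gene_id}: tx_start must be < tx_end "
                f"({self.tx_start} >= {self.tx_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos < self.tx_end


@dataclass(frozen=True)
class Interval:
    """A labelled genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class FeatureTrack:
    """A typed set of genomic intervals with fast overlap queries.

    Used for CpG islands, conserved non-coding regions, TFBS, DNase I HS,
    repeat families, histone-mark regions and ChIP fragments alike. Each
    interval may carry a label (e.g. a repeat family).
    """

    def __init__(self, name: str, intervals: Iterable[Interval] = ()):
        self.name = name
        self._intervals: list[Interval] = list(intervals)
        self._trees: Optional[dict[str, IntervalTree]] = None

    def add(self, iv: Interval) -> None:
        self._intervals.append(iv)
        self._trees = None

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._intervals)

    @property
    def intervals(self) -> list[Interval]:
        return list(self._intervals)

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self._intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        """All intervals overlapping [start, end) on chrom by >= 1 bp."""
        tree = self._index().get(chrom)
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.overlap(start, end)),
            key=lambda iv: (iv.start, iv.end, iv.label),
        )

    def containing(self, chrom: str, pos: int) -> list[Interval]:
        """All intervals whose half-open span contains the single base pos."""
        return self.overlapping(chrom, pos, pos + 1)

    def total_length(self) -> int:
        """Total bp covered, counting overlapping intervals once."""
        total = 0
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self._intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            cur_s, cur_e = None, None
            for iv in ivs:
                if cur_e is None or iv.start > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = iv.start, iv.end
                else:
                    cur_e = max(cur_e, iv.end)
            if cur_e is not None:
                total += cur_e - cur_s
        return total


@dataclass
class SyntheticGenome:
    """A miniature genome: chromosome sizes, gene models, feature and mark tracks."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    features: dict[str, FeatureTrack] = field(default_factory=dict)
    marks: dict[str, FeatureTrack] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if not (0 <= g.tx_start < g.tx_end <= self.chrom_sizes[g.chrom]):
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
        for track in list(self.features.values()) + list(self.marks.values()):
            for iv in track:
                if iv.chrom not in self.chrom_sizes:
                    raise ValueError(f"interval on unknown chromosome {iv.chrom}")
                if not (0 <= iv.start < iv.end <= self.chrom_sizes[iv.chrom]):
                    raise ValueError(
                        f"interval [{iv.start},{iv.end}) outside {iv.chrom}"
                    )


def sites_to_positions(sites: Iterable[IntegrationSite]) -> dict[str, np.ndarray]:
    """Group site positions per chromosome as sorted int arrays."""
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}
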
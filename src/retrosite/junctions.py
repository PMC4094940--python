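"""Junction-read processing: filtering, ambiguity calling and site collapsing.

LM-PCR recovers 3'-LTR vector-genome junctions; after alignment each read
carries zero or more genomic hits. This module turns reads + hits into a
de-duplicated set of unique integration sites, and (separately) a
repeat-analysis set that keeps ambiguous reads whose alternate placements
all fall in a single repeat family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import FeatureTrack, IntegrationSite

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class AlignmentHit:
    """One genomic placement of a junction read (BLAST-like hit)."""

    chrom: str
    start: int
    end: int
    strand: str
    identity: float  # percent identity, 0-100
    aligned_length: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad hit coordinates [{self.start}, {self.end})")
        if not 0 <= self.identity <= 100:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class JunctionRead:
    """A raw junction read and its genomic placements (may be unmapped)."""

    read_id: str
    sequence: str
    genomic_hits: list[AlignmentHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id}: non-ACGTN characters {bad}")

    def best_hit(self) -> Optional[AlignmentHit]:
        if not self.genomic_hits:
            return None
        return max(self.genomic_hits, key=lambda h: (h.identity, h.aligned_length))


@dataclass(frozen=True)
class JunctionConfig:
    """Processing thresholds.

    ``min_genomic_length``: reads whose best hit aligns fewer genomic bp are
    dropped as too short to place uniquely. ``ambiguity_identity_delta``:
    a read is ambiguous when a second placement sits within this many
    percentage points of identity of the best one.
    """

    min_genomic_length: int = 20
    ambiguity_identity_delta: float = 2.0

    def __post_init__(self) -> None:
        if self.min_genomic_length < 1:
            raise ValueError("min_genomic_length must be >= 1")
        if self.ambiguity_identity_delta <= 0:
            raise ValueError("ambiguity_identity_delta must be > 0")


def filter_reads(
    reads: Iterable[JunctionRead], config: JunctionConfig = JunctionConfig()
) -> list[JunctionRead]:
    """Drop unmapped reads and reads whose best hit is too short.

    Order is preserved; the input is not mutated. Records whose hits carry
    malformed coordinates are rejected with a warning rather than raising.
    """
    kept: list[JunctionRead] = []
    for read in reads:
        try:
            best = read.best_hit()
        except (ValueError, TypeError) as exc:  # malformed hit data
            logger.warning("rejecting read %s: %s", read.read_id, exc)
            continue
        if best is None:
            continue
        if best.aligned_length >= config.min_genomic_length:
            kept.append(read)
    return kept


def classify_ambiguity(
    read: JunctionRead, config: JunctionConfig = JunctionConfig()
) -> str:
    """Classify a read as 'unique', 'ambiguous' or 'unmapped'.

    A read is ambiguous when >= 2 placements lie within
    ``ambiguity_identity_delta`` percentage points of the best identity;
    unique when the best placement beats the runner-up by at least delta
    (or is the only one). Hit order is irrelevant.
    """
    if not read.genomic_hits:
        return "unmapped"
    if len(read.genomic_hits) == 1:
        return "unique"
    identities = sorted((h.identity for h in read.genomic_hits), reverse=True)
    if identities[0] - identities[1] >= config.ambiguity_identity_delta:
        return "unique"
    return "ambiguous"


def junction_position(hit: AlignmentHit) -> int:
    """Strand-aware junction base of a hit: start on +, end-1 on -."""
    return hit.start if hit.strand == "+" else hit.end - 1


def _ambiguous_placements(
    read: JunctionRead, config: JunctionConfig
) -> list[AlignmentHit]:
    best = read.best_hit()
    assert best is not None
    return [
        h
        for h in read.genomic_hits
        if best.identity - h.identity < config.ambiguity_identity_delta
    ]


def collapse_to_sites(
    reads: Iterable[JunctionRead],
    dataset: str,
    config: JunctionConfig = JunctionConfig(),
) -> list[IntegrationSite]:
    """Collapse redundant reads to unique integration sites.

    Unique reads sharing (chrom, junction pos, strand) collapse into one
    site whose ``support`` counts the collapsed reads — identical
    coordinates collapse even when the sheared-fragment read lengths
    differ. Ambiguous reads emit one flagged site per near-equivalent
    placement, sharing a ``match_group`` (the read id).
    """
    unique_counts: dict[tuple[str, int, str], int] = {}
    ambiguous_sites: list[IntegrationSite] = []
    for read in reads:
        status = classify_ambiguity(read, config)
        if status == "unmapped":
            continue
        if status == "unique":
            best = read.best_hit()
            key = (best.chrom, junction_position(best), best.strand)
            unique_counts[key] = unique_counts.get(key, 0) + 1
        else:
            for hit in _ambiguous_placements(read, config):
                ambiguous_sites.append(
                    IntegrationSite(
                        chrom=hit.chrom,
                        pos=junction_position(hit),
                        strand=hit.strand,
                        dataset=dataset,
                        support=1,
                        ambiguous=True,
                        match_group=read.read_id,
                    )
                )
    sites = [
        IntegrationSite(chrom=c, pos=p, strand=s, dataset=dataset, support=n)
        for (c, p, s), n in unique_counts.items()
    ]
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    ambiguous_sites.sort(key=lambda s: (s.match_group, s.chrom, s.pos))
    return sites + ambiguous_sites


def build_repeat_set(
    sites: Iterable[IntegrationSite], repeats: FeatureTrack
) -> list[IntegrationSite]:
    """Build the repeat-analysis site set.

    Keeps every non-ambiguous site, plus one representative per ambiguous
    match group whose placements ALL fall inside repeat intervals of the
    same family; groups spanning several families (or any placement outside
    a repeat) are dropped. The representative is the group's first
    placement in genome order, de-flagged.
    """
    out: list[IntegrationSite] = []
    groups: dict[str, list[IntegrationSite]] = {}
    for s in sites:
        if not s.ambiguous:
            out.append(s)
        else:
            if s.match_group is None:
                raise ValueError("ambiguous site without match_group")
            groups.setdefault(s.match_group, []).append(s)

    for group_sites in groups.values():
        families: set[str] = set()
        resolvable = True
        for s in group_sites:
            hits = repeats.containing(s.chrom, s.pos)
            if not hits:
                resolvable = False
                break
            # a placement inside several repeats: smallest interval wins
            hits.sort(key=lambda iv: (iv.length, iv.label))
            families.add(hits[0].label)
        if resolvable and len(families) == 1:
            rep = min(group_sites, key=lambda s: (s.chrom, s.pos, s.strand))
            out.append(
                IntegrationSite(
                    chrom=rep.chrom,
                    pos=rep.pos,
                    strand=rep.strand,
                    dataset=rep.dataset,
                    support=rep.support,
                    ambiguous=False,
                    match_group=rep.match_group,
                )
            )
    return out
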
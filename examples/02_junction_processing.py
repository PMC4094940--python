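"""Process toy junction reads: filter, resolve ambiguity, collapse to sites.

Builds a handful of reads with alignment hits, removes reads whose best
hit aligns fewer than 20 genomic bp, collapses redundant reads mapping to
the same (chrom, position, strand) into one supported site, and keeps
ambiguous reads only in the repeat-analysis set when all their placements
target the same repeat family.
"""

from retrosite import (
    AlignmentHit,
    FeatureTrack,
    Interval,
    JunctionConfig,
    JunctionRead,
    build_repeat_set,
    collapse_to_sites,
    filter_reads,
)

reads = [
    # three redundant reads (sheared-DNA duplicates) -> one site, support 3
    JunctionRead("r1", "ACGT" * 15, [AlignmentHit("chr1", 10_000, 10_060, "+", 99.0, 60)]),
    JunctionRead("r2", "ACGT" * 12, [AlignmentHit("chr1", 10_000, 10_048, "+", 98.5, 48)]),
    JunctionRead("r3", "ACGT" * 20, [AlignmentHit("chr1", 10_000, 10_080, "+", 99.5, 80)]),
    # too short to place: dropped
    JunctionRead("r4", "ACGTACGTACGTACG", [AlignmentHit("chr1", 500, 515, "+", 100.0, 15)]),
    # ambiguous (identities within 2 points): both placements in SINEs
    JunctionRead("r5", "ACGT" * 15, [
        AlignmentHit("chr1", 20_000, 20_060, "+", 98.0, 60),
        AlignmentHit("chr2", 30_000, 30_060, "+", 97.0, 60),
    ]),
]

config = JunctionConfig(min_genomic_length=20, ambiguity_identity_delta=2.0)
sites = collapse_to_sites(filter_reads(reads, config), "toy", config)
unique = [s for s in sites if not s.ambiguous]
print(f"{len(reads)} reads -> {len(unique)} unique sites "
      f"(+{len(sites) - len(unique)} ambiguous placements)")
for s in unique:
    print(f"  {s.chrom}:{s.pos}({s.strand}) support={s.support}")

repeats = FeatureTrack("repeats", [
    Interval("chr1", 19_900, 20_500, "SINE"),
    Interval("chr2", 29_900, 30_500, "SINE"),
])
repeat_set = build_repeat_set(sites, repeats)
print(f"repeat-analysis set: {len(repeat_set)} sites "
      "(ambiguous read kept: all placements hit the same SINE family)")
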
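"""File I/O: BED, refFlat-style gene tables, chrom.sizes, hits tables, bedGraph.

All genomic output is 0-based half-open. Sites travel as BED6 (one-bp
intervals, name = dataset label, score = read support); feature tracks as
BED4 (name = class/family label); genes as a refFlat-style TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import FeatureTrack, GeneModel, IntegrationSite, Interval
from .junctions import AlignmentHit, JunctionRead

HITS_COLUMNS = [
    "read_id", "chrom", "start", "end", "strand", "identity", "aligned_length",
]


def read_chrom_sizes(path) -> dict[str, int]:
    """UCSC two-column chrom.sizes."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, size = line.split()[:2]
        sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{s}\n" for c, s in sizes.items())
    )


def write_sites_bed(sites: Iterable[IntegrationSite], path) -> None:
    """Sites as BED6: 1-bp intervals, name=dataset, score=support."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.dataset}\t{s.support}\t{s.strand}\n"
            )


def read_sites_bed(path, dataset: Optional[str] = None) -> list[IntegrationSite]:
    sites = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        sites.append(
            IntegrationSite(
                chrom=f[0],
                pos=int(f[1]),
                strand=f[5] if len(f) > 5 else "+",
                dataset=dataset if dataset is not None else (f[3] if len(f) > 3 else ""),
                support=int(f[4]) if len(f) > 4 else 1,
            )
        )
    return sites


def write_track_bed(track: FeatureTrack, path) -> None:
    """Feature track as BED4 (name = interval label)."""
    with open(path, "w") as fh:
        for iv in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_track_bed(path, name: Optional[str] = None) -> FeatureTrack:
    track = FeatureTrack(name or Path(path).stem)
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        track.add(
            Interval(f[0], int(f[1]), int(f[2]), label=f[3] if len(f) > 3 else "")
        )
    return track


def write_genes_refflat(genes: Iterable[GeneModel], path) -> None:
    """refFlat-style TSV: gene, chrom, strand, txStart, txEnd (with header)."""
    with open(path, "w") as fh:
        fh.write("#gene\tchrom\tstrand\ttxStart\ttxEnd\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n")


def read_genes_refflat(path) -> list[GeneModel]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        genes.append(
            GeneModel(
                gene_id=f[0], chrom=f[1], strand=f[2],
                tx_start=int(f[3]), tx_end=int(f[4]),
            )
        )
    return genes


def read_fasta_reads(path) -> list[JunctionRead]:
    """Toy junction reads from an (uncompressed) FASTA file."""
    reads: list[JunctionRead] = []
    rid, seq = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if rid is not None:
                reads.append(JunctionRead(rid, "".join(seq)))
            rid, seq = line[1:].split()[0], []
        elif line.strip():
            seq.append(line.strip())
    if rid is not None:
        reads.append(JunctionRead(rid, "".join(seq)))
    return reads


def read_hits_table(
    path, column_map: Optional[Mapping[str, str]] = None
) -> dict[str, list[AlignmentHit]]:
    """BLAST-outfmt-6-like hits TSV -> read_id -> hits.

    Expected columns: read_id, chrom, start, end, strand, identity,
    aligned_length; ``column_map`` renames dialect columns onto these.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in HITS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hits table missing columns: {missing}")
    hits: dict[str, list[AlignmentHit]] = {}
    for row in df.itertuples(index=False):
        hits.setdefault(str(row.read_id), []).append(
            AlignmentHit(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                identity=float(row.identity),
                aligned_length=int(row.aligned_length),
            )
        )
    return hits


def attach_hits(
    reads: Sequence[JunctionRead], hits: Mapping[str, list[AlignmentHit]]
) -> list[JunctionRead]:
    return [
        JunctionRead(r.read_id, r.sequence, list(hits.get(r.read_id, [])))
        for r in reads
    ]


def write_bedgraph(profile: pd.DataFrame, chrom: str, anchor: int, path) -> None:
    """Write a density profile as bedGraph around a genomic anchor."""
    with open(path, "w") as fh:
        step = profile["offset"].diff().dropna().iloc[0] if len(profile) > 1 else 1
        for _, row in profile.iterrows():
            start = int(anchor + row["offset"] - step / 2)
            fh.write(f"{chrom}\t{start}\t{int(start + step)}\t{row['mean_coverage']:.6g}\n")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """TSV with a commented schema header line."""
    with open(path, "w") as fh:
        cols = (list(df.index.names) if index and df.index.name else []) + list(df.columns)
        fh.write("#schema: " + "\t".join(str(c) for c in cols) + "\n")
        df.to_csv(fh, sep="\t", index=index)
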
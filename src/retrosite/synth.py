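"""Synthetic genome annotation and integration-site generator.

Builds a miniature genome (chromosome sizes, non-overlapping gene models,
feature tracks, histone-mark domains) and draws integration-site datasets
from a three-component mixture emulating the canonical retroviral
profiles:

* TSS component — Gaussian placement around a uniformly chosen TSS
  (gamma-retroviral / MLV-like preference for promoters),
* gene-body component — uniform within a uniformly chosen transcription
  span (lentiviral / HIV-like preference for transcribed genes),
* uniform component — uniform over the genome (alpha-retroviral-like /
  random control).

Coordinates only; no nucleotide sequence is simulated. All outputs are
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureTrack, GeneModel, IntegrationSite, Interval, SyntheticGenome

# Track densities for the generated annotation (per Mb of genome unless noted).
_CPG_AT_TSS_FRACTION = 0.6  # fraction of genes given a CpG island at the TSS
_SCATTER_PER_MB = {"CNC": 20, "TFBS": 60, "DNase": 30}
_SCATTER_LEN = {"CNC": 300, "TFBS": 200, "DNase": 500}
_REPEAT_FAMILIES = ("LINE", "SINE", "Satellite", "LTR", "Other")
_REPEAT_WEIGHTS = (0.35, 0.30, 0.05, 0.15, 0.15)
_REPEAT_TARGET_COVERAGE = 0.45  # fraction of genome covered by repeat intervals
_REPEAT_MEAN_LEN = 400


@dataclass(frozen=True)
class SiteGeneratorConfig:
    """Mixture weights and shape parameters for one site dataset."""

    n_sites: int
    p_tss: float = 0.0
    p_genebody: float = 0.0
    p_uniform: float = 1.0
    tss_spread: float = 500.0
    seed: int = 0
    dataset: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        w = (self.p_tss, self.p_genebody, self.p_uniform)
        if min(w) < 0:
            raise ValueError("mixture weights must be >= 0")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(w)}")


def _place_genes(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    n_genes: int,
    gene_len_range: tuple[int, int],
    max_attempts_factor: int = 200,
) -> list[GeneModel]:
    """Place n_genes non-overlapping gene spans, bounded retries."""
    chroms = list(chrom_sizes)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    attempts = 0
    max_attempts = max_attempts_factor * max(n_genes, 1)
    while len(genes) < n_genes:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_genes} non-overlapping genes of length "
                f"{gene_len_range} in {sum(chrom_sizes.values())} bp "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        size = chrom_sizes[chrom]
        if size <= length:
            continue
        start = int(rng.integers(0, size - length))
        end = start + length
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"G{len(genes):04d}",
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=end,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genes


def _clip_interval(start: int, end: int, size: int) -> tuple[int, int] | None:
    s, e = max(0, start), min(size, end)
    return (s, e) if s < e else None


def _scatter_track(
    rng: np.random.Generator,
    name: str,
    chrom_sizes: dict[str, int],
    per_mb: float,
    length: int,
) -> FeatureTrack:
    track = FeatureTrack(name)
    for chrom, size in chrom_sizes.items():
        n = rng.poisson(per_mb * size / 1e6)
        for start in np.sort(rng.integers(0, max(size - length, 1), size=n)):
            clipped = _clip_interval(int(start), int(start) + length, size)
            if clipped:
                track.add(Interval(chrom, *clipped, label=name))
    return track


def make_genome(
    n_chroms: int = 2,
    chrom_len: int = 1_000_000,
    n_genes: int = 50,
    seed: int = 0,
    gene_len_range: tuple[int, int] = (5_000, 30_000),
) -> SyntheticGenome:
    """Generate a miniature genome with genes, feature and mark tracks.

    Feature tracks: CpG islands of 1 kb centred on 60% of TSSs; CNC, TFBS
    and DNase intervals scattered uniformly at fixed per-Mb densities;
    repeat intervals (LINE/SINE/Satellite/LTR/Other) covering ~45% of the
    genome. Mark tracks mimic the canonical promoter/enhancer/gene-body/
    heterochromatin layout: H3K4me3 at TSS +/- 1 kb, H3K4me1 on the 4-kb
    flanks of the promoter, H3K36me3 over the gene body beyond 2.5 kb of
    the TSS, H3K27me3 in randomly chosen intergenic blocks.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": int(chrom_len) for i in range(n_chroms)}
    genes = _place_genes(rng, chrom_sizes, n_genes, gene_len_range)

    features: dict[str, FeatureTrack] = {}
    cpg = FeatureTrack("CpG")
    for g in genes:
        if rng.random() < _CPG_AT_TSS_FRACTION:
            clipped = _clip_interval(g.tss - 500, g.tss + 500, chrom_sizes[g.chrom])
            if clipped:
                cpg.add(Interval(g.chrom, *clipped, label="CpG"))
    features["CpG"] = cpg
    for name, per_mb in _SCATTER_PER_MB.items():
        features[name] = _scatter_track(
            rng, name, chrom_sizes, per_mb, _SCATTER_LEN[name]
        )

    repeats = FeatureTrack("repeats")
    for chrom, size in chrom_sizes.items():
        covered = 0
        target = int(_REPEAT_TARGET_COVERAGE * size)
        pos = int(rng.integers(0, 2 * _REPEAT_MEAN_LEN))
        while covered < target and pos < size - 50:
            length = int(rng.integers(_REPEAT_MEAN_LEN // 2, 2 * _REPEAT_MEAN_LEN))
            clipped = _clip_interval(pos, pos + length, size)
            if clipped is None:
                break
            fam = str(rng.choice(_REPEAT_FAMILIES, p=_REPEAT_WEIGHTS))
            repeats.add(Interval(chrom, *clipped, label=fam))
            covered += clipped[1] - clipped[0]
            # gap sized so repeats cover ~the target fraction overall
            gap = int(
                rng.integers(1, max(2, int(length / _REPEAT_TARGET_COVERAGE - length)))
            )
            pos = clipped[1] + gap
    features["repeats"] = repeats

    marks: dict[str, FeatureTrack] = {
        m: FeatureTrack(m) for m in ("H3K4me3", "H3K4me1", "H3K36me3", "H3K27me3")
    }
    for g in genes:
        size = chrom_sizes[g.chrom]
        for s, e in [(g.tss - 1_000, g.tss + 1_000)]:
            clipped = _clip_interval(s, e, size)
            if clipped:
                marks["H3K4me3"].add(Interval(g.chrom, *clipped, label="H3K4me3"))
        for s, e in [(g.tss - 5_000, g.tss - 1_000), (g.tss + 1_000, g.tss + 5_000)]:
            clipped = _clip_interval(s, e, size)
            if clipped:
                marks["H3K4me1"].add(Interval(g.chrom, *clipped, label="H3K4me1"))
        if g.strand == "+":
            body = (g.tx_start + 2_500, g.tx_end)
        else:
            body = (g.tx_start, g.tx_end - 2_500)
        clipped = _clip_interval(*body, size)
        if clipped:
            marks["H3K36me3"].add(Interval(g.chrom, *clipped, label="H3K36me3"))
    for chrom, size in chrom_sizes.items():
        n_blocks = max(1, int(size / 1e6 * 5))
        for _ in range(n_blocks):
            start = int(rng.integers(0, max(size - 20_000, 1)))
            clipped = _clip_interval(start, start + 20_000, size)
            if clipped:
                marks["H3K27me3"].add(Interval(chrom, *clipped, label="H3K27me3"))

    genome = SyntheticGenome(
        chrom_sizes=chrom_sizes, genes=genes, features=features, marks=marks
    )
    genome.validate()
    return genome


def _uniform_position(
    rng: np.random.Generator, chrom_sizes: dict[str, int]
) -> tuple[str, int]:
    chroms = list(chrom_sizes)
    lengths = np.asarray([chrom_sizes[c] for c in chroms], dtype=float)
    chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
    return chrom, int(rng.integers(0, chrom_sizes[chrom]))


def generate_sites(
    genome: SyntheticGenome, config: SiteGeneratorConfig
) -> list[IntegrationSite]:
    """Draw integration sites from the TSS/gene-body/uniform mixture."""
    if (config.p_tss > 0 or config.p_genebody > 0) and not genome.genes:
        raise ValueError("TSS/gene-body components require a genome with genes")
    rng = np.random.default_rng(config.seed)
    components = rng.choice(
        3, size=config.n_sites, p=[config.p_tss, config.p_genebody, config.p_uniform]
    )
    sites: list[IntegrationSite] = []
    genes = genome.genes
    for comp in components:
        if comp == 0:
            g = genes[rng.integers(len(genes))]
            pos = int(round(g.tss + rng.normal(0.0, config.tss_spread)))
            pos = min(max(pos, 0), genome.chrom_sizes[g.chrom] - 1)
            chrom = g.chrom
        elif comp == 1:
            g = genes[rng.integers(len(genes))]
            chrom = g.chrom
            pos = int(rng.integers(g.tx_start, g.tx_end))
        else:
            chrom, pos = _uniform_position(rng, genome.chrom_sizes)
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(
            IntegrationSite(
                chrom=chrom, pos=pos, strand=strand, dataset=config.dataset
            )
        )
    return sites


def generate_mark_fragments(
    genome: SyntheticGenome,
    mark: str,
    fragment_length: int = 200,
    depth: int = 10_000,
    seed: int = 0,
    enrichment: float = 10.0,
) -> FeatureTrack:
    """Sample ChIP fragments for a mark: enriched regions + uniform background.

    ``enrichment`` is the per-bp rate ratio between the mark's enriched
    regions and the rest of the genome; 1.0 yields a uniform
    (all-background) track. Returns exactly ``depth`` fragments of fixed
    length.
    """
    if mark not in genome.marks:
        raise KeyError(
            f"unknown mark {mark!r}; available: {sorted(genome.marks)}"
        )
    if enrichment < 1.0:
        raise ValueError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    track = FeatureTrack(f"{mark}_fragments")
    if depth == 0:
        return track
    enriched = genome.marks[mark].intervals
    e_len = sum(iv.length for iv in enriched)
    total = genome.total_length
    b_len = max(total - e_len, 0)
    p_enriched = (enrichment * e_len) / (enrichment * e_len + b_len) if e_len else 0.0
    weights = (
        np.asarray([iv.length for iv in enriched], dtype=float) / e_len
        if e_len
        else None
    )
    for _ in range(depth):
        if weights is not None and rng.random() < p_enriched:
            iv = enriched[rng.choice(len(enriched), p=weights)]
            center = int(rng.integers(iv.start, iv.end))
            chrom = iv.chrom
        else:
            chrom, center = _uniform_position(rng, genome.chrom_sizes)
        start = center - fragment_length // 2
        clipped = _clip_interval(
            start, start + fragment_length, genome.chrom_sizes[chrom]
        )
        if clipped is None:  # degenerate at chromosome edge; resample uniformly
            chrom, center = _uniform_position(rng, genome.chrom_sizes)
            clipped = _clip_interval(
                center, center + fragment_length, genome.chrom_sizes[chrom]
            )
        track.add(Interval(chrom, *clipped, label=mark))
    return track
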
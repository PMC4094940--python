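"""Annotation window conventions, against brute-force oracles."""

import numpy as np
import pytest

from retrosite import (
    AnnotationConfig,
    FeatureTrack,
    GeneModel,
    IntegrationSite,
    Interval,
    RegionClass,
    annotate_features,
    annotate_sites,
    assign_repeat,
    classify_region,
    expressed_target_fraction,
    region_summary,
    target_genes,
    tss_distance,
)

CFG = AnnotationConfig()


def site(pos, chrom="chr1"):
    return IntegrationSite(chrom, pos, "+", "d")


# ---------------------------------------------------------------- oracles
def oracle_region(s, genes, cfg=CFG):
    """Exhaustive per-gene scan applying the exclusive-class precedence."""
    near_tss = any(
        g.chrom == s.chrom and abs(s.pos - g.tss) <= cfg.tss_window for g in genes
    )
    if near_tss:
        return RegionClass.TSS_PROXIMAL
    inside = any(
        g.chrom == s.chrom and g.tx_start <= s.pos < g.tx_end for g in genes
    )
    return RegionClass.INTRAGENIC if inside else RegionClass.INTERGENIC


def oracle_features(s, features, cfg=CFG):
    lo, hi = s.pos - cfg.feature_window, s.pos + cfg.feature_window + 1
    hit = set()
    for cls, track in features.items():
        for iv in track:
            if iv.chrom == s.chrom and min(iv.end, hi) - max(iv.start, lo) >= cfg.min_overlap:
                hit.add(cls)
    return hit


def random_layout(rng, n_genes=50, n_sites=1000, length=1_000_000):
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, length - 20_000))
        end = start + int(rng.integers(2_000, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i:03d}", "chr1", strand, start, end))
    sites = [site(int(p)) for p in rng.integers(0, length, size=n_sites)]
    return genes, sites


# ---------------------------------------------------------------- region
class TestClassifyRegion:
    GENE = GeneModel("G1", "chr1", "+", 10_000, 20_000)  # tss 10,000

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (11_500, RegionClass.TSS_PROXIMAL),  # 1,500 <= 2,500
            (15_000, RegionClass.INTRAGENIC),  # inside, 5,000 > 2,500
            (12_500, RegionClass.TSS_PROXIMAL),  # inclusive boundary
            (12_501, RegionClass.INTRAGENIC),
            (50_000, RegionClass.INTERGENIC),
            (8_000, RegionClass.TSS_PROXIMAL),  # upstream within window
            (7_499, RegionClass.INTERGENIC),
        ],
    )
    def test_window_rule(self, pos, expected):
        assert classify_region(site(pos), [self.GENE]) is expected

    def test_no_genes_on_chromosome_is_intergenic(self):
        assert classify_region(site(100, "chrX"), [self.GENE]) is RegionClass.INTERGENIC

    def test_tss_proximal_precedence_over_intragenic(self):
        # site inside gene B body but near gene A's TSS
        a = GeneModel("A", "chr1", "+", 30_000, 40_000)
        b = GeneModel("B", "chr1", "+", 10_000, 35_000)
        assert classify_region(site(29_000), [a, b]) is RegionClass.TSS_PROXIMAL

    def test_matches_brute_force_on_random_layout(self, rng):
        genes, sites = random_layout(rng)
        for s in sites:
            assert classify_region(s, genes) is oracle_region(s, genes)

    def test_translation_invariance(self, rng):
        genes, sites = random_layout(rng, n_genes=20, n_sites=100)
        offset = 12_345
        genes2 = [GeneModel(g.gene_id, g.chrom, g.strand,
                            g.tx_start + offset, g.tx_end + offset) for g in genes]
        for s in sites:
            assert classify_region(s, genes) is classify_region(
                site(s.pos + offset), genes2
            )

    def test_region_classes_partition_dataset(self, rng):
        genes, sites = random_layout(rng, n_sites=500)
        anns = annotate_sites(sites, genes)
        table = region_summary({"d": anns})
        total_pct = (
            table.loc["d", "intergenic_pct"]
            + table.loc["d", "tss_proximal_pct"]
            + table.loc["d", "intragenic_pct"]
        )
        assert total_pct == pytest.approx(100.0, abs=1e-9)


# ---------------------------------------------------------------- distance
class TestTssDistance:
    def test_minus_strand_downstream_is_positive(self):
        g = GeneModel("G", "chr1", "-", 10_000, 20_001)  # tss 20,000
        assert tss_distance(site(18_000), [g]) == 2_000

    def test_plus_strand_sign(self):
        g = GeneModel("G", "chr1", "+", 10_000, 20_000)
        assert tss_distance(site(12_000), [g]) == 2_000
        assert tss_distance(site(8_000), [g]) == -2_000

    def test_site_exactly_at_tss_is_zero(self):
        g = GeneModel("G", "chr1", "+", 10_000, 20_000)
        assert tss_distance(site(10_000), [g]) == 0

    def test_nearest_tss_wins(self):
        g1 = GeneModel("far", "chr1", "+", 13_000, 20_000)  # tss 13,000: +3,000
        g2 = GeneModel("near", "chr1", "-", 5_000, 9_001)  # tss 9,000: -1,000
        # site between two TSSs at signed distances +3,000 and -1,000
        assert tss_distance(site(10_000), [g1, g2]) == -1_000

    def test_outside_target_window_is_absent(self):
        g = GeneModel("G", "chr1", "+", 200_000, 210_000)
        assert tss_distance(site(100_000), [g], window=50_000) is None


# ---------------------------------------------------------------- features
class TestAnnotateFeatures:
    def test_overlap_by_one_bp_within_1kb_window(self):
        features = {"CpG": FeatureTrack("CpG", [Interval("chr1", 5_000, 5_200, "CpG")])}
        assert annotate_features(site(6_100), features) == {"CpG"}

    def test_zero_overlap_at_window_boundary(self):
        features = {"CpG": FeatureTrack("CpG", [Interval("chr1", 5_000, 5_099, "CpG")])}
        assert annotate_features(site(6_100), features) == set()

    def test_interval_touching_window_end_included(self):
        # window of pos 6,100 is [5,100, 7,101): base 7,100 still overlaps
        features = {"X": FeatureTrack("X", [Interval("chr1", 7_100, 7_300, "X")])}
        assert annotate_features(site(6_100), features) == {"X"}

    def test_matches_brute_force_on_random_tracks(self, rng):
        features = {
            cls: FeatureTrack(cls, [
                Interval("chr1", int(p), int(p) + int(rng.integers(50, 2_000)), cls)
                for p in rng.integers(0, 500_000, size=60)
            ])
            for cls in ("CpG", "CNC", "TFBS", "DNase")
        }
        for p in rng.integers(0, 500_000, size=300):
            s = site(int(p))
            assert annotate_features(s, features) == oracle_features(s, features)

    def test_monotone_in_feature_window(self, rng):
        features = {
            "X": FeatureTrack("X", [
                Interval("chr1", int(p), int(p) + 200, "X")
                for p in rng.integers(0, 100_000, size=40)
            ])
        }
        small = AnnotationConfig(feature_window=500)
        large = AnnotationConfig(feature_window=2_000)
        for p in rng.integers(0, 100_000, size=200):
            s = site(int(p))
            assert annotate_features(s, features, small) <= annotate_features(
                s, features, large
            )


# ---------------------------------------------------------------- repeats
class TestAssignRepeat:
    def test_direct_target_only(self):
        repeats = FeatureTrack("repeats", [Interval("chr1", 100, 400, "SINE")])
        assert assign_repeat(site(250), repeats) == "SINE"
        assert assign_repeat(site(400), repeats) is None  # half-open end
        assert assign_repeat(site(99), repeats) is None  # no 1kb window here

    def test_nested_repeats_resolve_to_smallest(self):
        repeats = FeatureTrack("repeats", [
            Interval("chr1", 0, 10_000, "LINE"),
            Interval("chr1", 4_000, 5_000, "SINE"),
        ])
        assert assign_repeat(site(4_500), repeats) == "SINE"
        assert assign_repeat(site(2_000), repeats) == "LINE"


# ---------------------------------------------------------------- targets
class TestTargetGenes:
    def test_50kb_boundary_inclusive(self):
        pos = 100_000
        inside = GeneModel("in", "chr1", "+", pos + 49_999, pos + 60_000)
        outside = GeneModel("out", "chr1", "+", pos + 50_001, pos + 70_000)
        assert target_genes(site(pos), [inside, outside]) == ["in"]

    def test_sorted_by_absolute_distance_matches_linear_scan(self, rng):
        genes, sites = random_layout(rng, n_genes=40, n_sites=100)
        for s in sites[:50]:
            got = target_genes(s, genes)
            expected = sorted(
                (g.gene_id for g in genes if abs(g.tss - s.pos) <= 50_000),
                key=lambda gid: (
                    abs(next(g.tss for g in genes if g.gene_id == gid) - s.pos),
                    gid,
                ),
            )
            assert got == expected

    def test_isoforms_sharing_tss_deduplicated(self):
        g1 = GeneModel("iso1", "chr1", "+", 10_000, 20_000)
        g2 = GeneModel("iso1", "chr1", "+", 10_000, 20_000)
        assert target_genes(site(10_500), [g1, g2]) == ["iso1"]


# ---------------------------------------------------------------- expression
class TestExpressedTargetFraction:
    def _annotations(self, gene_ids):
        g = [GeneModel(gid, "chr1", "+", 100 * i + 10_000, 100 * i + 12_000)
             for i, gid in enumerate(gene_ids)]
        return annotate_sites([site(15_000)], g)

    def test_known_fraction_recovered(self):
        gene_ids = [f"G{i}" for i in range(100)]
        anns = self._annotations(gene_ids)
        expression = {gid: (10.0 if i < 70 else 0.0) for i, gid in enumerate(gene_ids)}
        res = expressed_target_fraction(anns, expression, threshold=1.0)
        assert res["fraction_expressed"] == pytest.approx(0.70)
        assert res["n_targets"] == 100

    def test_all_and_none_extremes(self):
        anns = self._annotations(["A", "B"])
        assert expressed_target_fraction(anns, {"A": 5, "B": 5}, 1.0)["fraction_expressed"] == 1.0
        assert expressed_target_fraction(anns, {"A": 0, "B": 0}, 1.0)["fraction_expressed"] == 0.0

    def test_missing_genes_counted_unexpressed_and_reported(self):
        anns = self._annotations(["A", "B"])
        res = expressed_target_fraction(anns, {"A": 5.0}, 1.0)
        assert res == {"fraction_expressed": 0.5, "n_targets": 2, "n_missing_from_table": 1}

    def test_empty_target_set_absent(self):
        assert expressed_target_fraction([], {}, 1.0) is None
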
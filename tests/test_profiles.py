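"""Distance histograms, ChIP density and chromatin-state rules."""

import numpy as np
import pytest

from retrosite import (
    AnnotationConfig,
    ChromatinStateRule,
    FeatureTrack,
    IntegrationSite,
    Interval,
    ProfileConfig,
    SiteGeneratorConfig,
    assign_chromatin_state,
    chip_density,
    default_state_rules,
    generate_sites,
    state_summary,
    tss_distance,
    tss_profile,
)

CFG = ProfileConfig()


def site(pos, chrom="chr1", strand="+"):
    return IntegrationSite(chrom, pos, strand, "d")


class TestTssProfile:
    def test_all_zero_distances_in_one_bin(self):
        prof = tss_profile([0] * 10, CFG, "coarse")
        assert prof.fraction_per_bin.sum() == pytest.approx(1.0)
        assert (prof.fraction_per_bin > 0).sum() == 1

    def test_hand_binned_example(self):
        # right-closed bins: -3000 in (-5000,-2500], -1000 in (-2500,0],
        # +1000 in (0,2500], +30000 in (27500,30000]
        prof = tss_profile([-3_000, -1_000, 1_000, 30_000], CFG, "coarse")
        nz = {
            (int(prof.bin_edges[i]), int(prof.bin_edges[i + 1])): f
            for i, f in enumerate(prof.fraction_per_bin) if f > 0
        }
        assert nz == {
            (-5_000, -2_500): 0.25,
            (-2_500, 0): 0.25,
            (0, 2_500): 0.25,
            (27_500, 30_000): 0.25,
        }

    def test_out_of_span_dropped_and_counted(self):
        prof = tss_profile([0, 100, 60_000, None], CFG, "coarse")
        assert prof.n_sites_used == 2
        assert prof.n_dropped == 2
        assert prof.fraction_per_bin.sum() == pytest.approx(1.0)

    def test_fine_profile_of_tss_biased_data_peaks_at_zero(self, genome):
        sites = generate_sites(
            genome,
            SiteGeneratorConfig(n_sites=5_000, p_tss=1.0, p_uniform=0.0,
                                tss_spread=500.0, seed=8),
        )
        distances = [tss_distance(s, genome.genes) for s in sites]
        prof = tss_profile(distances, CFG, "fine")
        mode = prof.bin_midpoints[int(np.argmax(prof.fraction_per_bin))]
        assert abs(mode) <= 500

    def test_bin_size_change_preserves_total_mass(self):
        distances = list(range(-2_000, 2_000, 37))
        for fine_bin in (50, 100):
            cfg = ProfileConfig(fine_bin=fine_bin)
            prof = tss_profile(distances, cfg, "fine")
            assert prof.fraction_per_bin.sum() == pytest.approx(1.0)
            assert prof.n_sites_used == len(distances)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="nothing to profile"):
            tss_profile([], CFG, "coarse")


class TestChipDensity:
    def test_uniform_tiling_gives_flat_profile(self):
        # non-overlapping 100-bp fragments tiling the window: depth exactly 1
        frags = FeatureTrack("t", [
            Interval("chr1", p, p + 100) for p in range(0, 20_000, 100)
        ])
        prof = chip_density([site(10_000)], frags, CFG)
        assert np.allclose(prof["mean_coverage"], 1.0)

    def test_single_central_fragment_hits_two_central_bins(self):
        s = site(10_000)
        frags = FeatureTrack("t", [Interval("chr1", 9_950, 10_050)])
        prof = chip_density([s], frags, CFG)
        nz = prof[prof["mean_coverage"] > 0]
        assert list(nz["offset"]) == [-25.0, 25.0]
        assert np.allclose(nz["mean_coverage"], 1.0)

    def test_linear_in_disjoint_fragment_tracks(self, rng):
        sites = [site(int(p)) for p in rng.integers(5_000, 95_000, size=20)]
        a = FeatureTrack("a", [Interval("chr1", int(p), int(p) + 200)
                               for p in rng.integers(0, 100_000, size=100)])
        b = FeatureTrack("b", [Interval("chr1", int(p) + 200_000, int(p) + 200_200)
                               for p in rng.integers(0, 100_000, size=100)])
        both = FeatureTrack("ab", a.intervals + b.intervals)
        pa = chip_density(sites, a, CFG)["mean_coverage"]
        pb = chip_density(sites, b, CFG)["mean_coverage"]
        pab = chip_density(sites, both, CFG)["mean_coverage"]
        assert np.allclose(pab, pa + pb)

    def test_empty_track_gives_all_zero_profile(self):
        prof = chip_density([site(10_000)], FeatureTrack("empty"), CFG)
        assert (prof["mean_coverage"] == 0).all()

    def test_tss_enriched_fragments_peak_at_center(self, genome):
        from retrosite import generate_mark_fragments

        frags = generate_mark_fragments(genome, "H3K4me3", fragment_length=200,
                                        depth=20_000, seed=3, enrichment=10.0)
        sites = [IntegrationSite(g.chrom, g.tss, g.strand, "d")
                 for g in genome.genes]
        prof = chip_density(sites, frags, CFG)
        center = prof["mean_coverage"][(prof["offset"].abs() < 500)].mean()
        edge = prof["mean_coverage"][(prof["offset"].abs() > 2_000)].mean()
        assert center / max(edge, 1e-12) > 2


class TestChromatinStates:
    def _tracks(self, marks_present, pos=10_000):
        return {
            m: FeatureTrack(m, [Interval("chr1", pos - 100, pos + 100, m)])
            for m in marks_present
        }

    @pytest.mark.parametrize(
        "present,expected",
        [
            ({"H3K4me3"}, "Promoter"),
            ({"H3K4me1"}, "Enhancer"),
            ({"H3K4me3", "H3K36me3"}, "Promoter"),  # Transcribed blocked
            ({"H3K36me3"}, "Transcribed"),
            ({"H3K27me3"}, "Heterochromatin"),
            (set(), None),  # no rule matches
            # Promoter requires only H3K4me3 and Enhancer forbids it, so a
            # promoter+enhancer mark combination still matches exactly one rule
            ({"H3K4me3", "H3K4me1"}, "Promoter"),
        ],
    )
    def test_default_rule_table(self, present, expected):
        assert assign_chromatin_state(site(10_000), self._tracks(present)) == expected

    def test_assigned_state_never_has_forbidden_mark_present(self, rng):
        marks = ["H3K4me1", "H3K4me3", "H3K36me3", "H3K27me3"]
        rules = {r.state: r for r in default_state_rules()}
        for _ in range(100):
            present = {m for m in marks if rng.random() < 0.5}
            got = assign_chromatin_state(site(10_000), self._tracks(present))
            if got is not None:
                assert not (rules[got].forbidden_marks & present)
                assert rules[got].required_marks <= present

    def test_duplicate_state_labels_rejected(self):
        rules = [
            ChromatinStateRule("X", frozenset({"H3K4me3"})),
            ChromatinStateRule("X", frozenset({"H3K4me1"})),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            assign_chromatin_state(site(10_000), {}, rules)

    def test_conflicting_rule_definition_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ChromatinStateRule("bad", frozenset({"a"}), frozenset({"a"}))

    def test_mark_presence_uses_1kb_window(self):
        tracks = {"H3K4me3": FeatureTrack("H3K4me3",
                                          [Interval("chr1", 11_500, 12_000)])}
        # interval overlaps [9,000, 11,001)? no; window config widens it
        assert assign_chromatin_state(site(10_000), tracks) is None
        wide = AnnotationConfig(feature_window=2_000)
        assert assign_chromatin_state(site(10_000), tracks, config=wide) == "Promoter"


class TestStateSummary:
    def test_no_mark_tracks_means_all_unassigned(self):
        table = state_summary({"d": [site(1_000), site(2_000)]}, {})
        assert table.loc["d", "unassigned"] == 1.0

    def test_fractions_sum_to_one(self, genome):
        sites = generate_sites(genome, SiteGeneratorConfig(n_sites=500, seed=14))
        table = state_summary({"u": sites}, genome.marks)
        states = [r.state for r in default_state_rules()] + ["unassigned"]
        assert table.loc["u", states].sum() == pytest.approx(1.0)

    def test_tss_biased_sites_more_promoter_enhancer_than_uniform(self, genome):
        tss_sites = generate_sites(
            genome, SiteGeneratorConfig(n_sites=2_000, p_tss=0.9, p_genebody=0.0,
                                        p_uniform=0.1, seed=15, dataset="mlv"))
        uni = generate_sites(
            genome, SiteGeneratorConfig(n_sites=2_000, seed=16, dataset="uni"))
        table = state_summary({"mlv": tss_sites, "uni": uni}, genome.marks)
        reg = table["Promoter"] + table["Enhancer"]
        assert reg["mlv"] > reg["uni"]
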
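"""TSS-distance profiles, ChIP-fragment density and chromatin states.

Generates a promoter-biased dataset and a uniform control, histograms
their signed distances to the nearest TSS, profiles synthetic H3K4me3
ChIP fragments around the biased sites, and summarises chromatin-state
assignment (a site gets a state only when exactly one mark-combination
rule matches its +/- 1 kb window).
"""

import numpy as np

from retrosite import (
    ProfileConfig,
    SiteGeneratorConfig,
    chip_density,
    generate_mark_fragments,
    generate_sites,
    make_genome,
    state_summary,
    tss_distance,
    tss_profile,
)

genome = make_genome(seed=5)
biased = generate_sites(genome, SiteGeneratorConfig(
    n_sites=3_000, p_tss=0.9, p_uniform=0.1, tss_spread=500.0, seed=6, dataset="biased"))
uniform = generate_sites(genome, SiteGeneratorConfig(
    n_sites=3_000, seed=7, dataset="uniform"))

cfg = ProfileConfig()
for name, sites in (("biased", biased), ("uniform", uniform)):
    distances = [tss_distance(s, genome.genes) for s in sites]
    prof = tss_profile(distances, cfg, resolution="fine")
    mode = prof.bin_midpoints[int(np.argmax(prof.fraction_per_bin))]
    central = prof.fraction_per_bin[np.abs(prof.bin_midpoints) <= 500].sum()
    print(f"{name:8s} fine profile: mode at {mode:+.0f} bp, "
          f"{100 * central:.1f}% of profiled sites within 500 bp of a TSS "
          f"({prof.n_sites_used} sites used)")

frags = generate_mark_fragments(genome, "H3K4me3", fragment_length=200,
                                depth=20_000, seed=8, enrichment=10.0)
prof = chip_density(biased, frags, cfg)
center = prof["mean_coverage"][prof["offset"].abs() < 500].mean()
edge = prof["mean_coverage"][prof["offset"].abs() > 2_000].mean()
print(f"\nH3K4me3 density around biased sites: centre {center:.3f} vs "
      f"edge {edge:.3f} mean coverage (ratio {center / edge:.1f}) — promoter "
      "fragments pile up over promoter-targeted integrations")

states = state_summary({"biased": biased, "uniform": uniform}, genome.marks)
print("\nChromatin-state fractions (rows sum to 1):")
print(states.round(3).to_string())
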
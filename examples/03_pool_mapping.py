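"""Pooled sequencing and HMM linkage mapping of one selected pool.

Selects the 22 best segregants of a simulated screen, samples 100x pooled
read counts, smooths the superior-allele frequency track, and calls linked
regions with the 3-state binomial-emission HMM.
"""

from bsamap import (HmmParams, build_pool, call_regions, default_trait_model,
                    hmm_posteriors, sample_read_counts, select_superior,
                    simulate_f1_population, simulate_parental_genomes,
                    smooth_track, variant_frequency)
from bsamap.sim_cross import assign_phenotypes

snp_map = simulate_parental_genomes(16, 350, 750_000, 2.7, seed=1)
model = default_trait_model(snp_map)
pop = simulate_f1_population(snp_map, 260, seed=6)
pheno = assign_phenotypes(pop, model, seed=7)
best = set(select_superior(pheno).nsmallest(22, "glycerol_rel")["strain"])
members = [s for s in pop if s.strain_id in best]

pool = build_pool(members, "selected_22")
counts = sample_read_counts(pool, snp_map, mean_depth=100.0, seed=8)
track = variant_frequency(counts)
smoothed = smooth_track(track, bandwidth=30_000)

params = HmmParams()        # p_link 0.9, lambda 20 kb, threshold 0.95
posteriors = hmm_posteriors(counts, params)
regions = call_regions(posteriors, counts, params)

print(f"pool of {pool.n_segregants} selected segregants, "
      f"mean depth {counts.n.mean():.0f}x over {counts.n_markers} markers")
print(f"{len(regions)} candidate linked regions (posterior >= {params.posterior_threshold}):")
for r in regions:
    print(f"  chr {r.chrom:2d}  {r.start:>7,}-{r.end:<7,}  {r.direction:8s} "
          f"posterior {r.mean_posterior:.3f}  ({r.n_markers} markers)")
print("\nupward deviations from 0.5 mark linkage to the superior parent; the")
print("planted minor loci sit mid-chromosome on chromosomes 2, 4 and 13.")
print("Calls overlapping them are real; the rest are single-pool random")
print("coincidences (a 22-segregant pool is noisy), which is why candidate")
print("regions are only trusted after multi-pool concordance filtering.")
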
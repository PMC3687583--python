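"""Simulate the backcross: SNP map, F1 segregants, inbred F5 segregants.

Builds a yeast-scale marker map (16 chromosomes, 5,600 informative SNPs),
draws F1 segregants of the superior x inferior hybrid, runs four rounds of
random inbreeding, and shows how recombination junctions accumulate.
"""

import numpy as np

from bsamap import (default_trait_model, inbreed, junction_count,
                    simulate_f1_population, simulate_parental_genomes)

snp_map = simulate_parental_genomes(n_chromosomes=16, markers_per_chromosome=350,
                                    chrom_lengths=750_000, map_lengths=2.7, seed=1)
print(f"map: {snp_map.n_markers} informative markers on "
      f"{len(snp_map.chromosomes)} chromosomes")

f1 = simulate_f1_population(snp_map, 260, seed=2)
f5 = inbreed(f1, rounds=4, snp_map=snp_map, seed=3)

j1 = np.mean([junction_count(s, snp_map) for s in f1])
j5 = np.mean([junction_count(s, snp_map) for s in f5])
print(f"mean recombination junctions per genome: F1 {j1:.1f}, F5 {j5:.1f}")
print("inbreeding multiplies breakpoints, which narrows linked blocks and")
print("hence the QTL intervals the pooled analysis can resolve.")

model = default_trait_model(snp_map)
print(f"\ntrait model: {len(model.causal_loci)} focal loci with effects "
      f"{model.effects} (the 15-point major is epistatically masked),")
print(f"plus {len(model.background_loci)} one-point background loci.")
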
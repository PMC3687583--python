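"""The complete in-silico pooled-segregant experiment.

Screen -> select -> pool -> sequence -> smooth/HMM-map -> concordance
validation -> marker scoring, with a deterministic provenance manifest.
"""

from bsamap import ExperimentConfig, run_experiment

config = ExperimentConfig(seed=1)
bundle = run_experiment(config)      # pass output_dir=... to write all TSV/BED

m = bundle.manifest
print(f"config hash {m['config_hash']}, seed {m['seed']}")
print(f"screened {m['n_screened']} -> cut-off passers {m['n_selected']}")
print(f"pool sizes {m['pool_sizes']}")
print(f"candidate regions per pool: {m['n_candidate_regions']}")

print(f"\n{m['n_validated_regions']} regions validated by multi-pool concordance:")
for r in bundle.validated_regions:
    print(f"  chr {r.chrom:2d}  {r.start:>7,}-{r.end:<7,}  {r.direction}"
          f"  posterior {r.mean_posterior:.3f}")
truth = [(int(bundle.snp_map.chrom[l]), int(bundle.snp_map.pos[l]), e)
         for l, e in zip(bundle.trait_model.causal_loci, bundle.trait_model.effects)]
print(f"planted causal loci (chrom, bp, effect): {truth}")

if bundle.marker_scores is not None:
    all70 = bundle.marker_scores[bundle.marker_scores["group"].str.startswith("all-")]
    print("\nper-marker exact binomial tests in all selected segregants:")
    print(all70[["marker", "n", "k", "frequency", "p_superior"]].to_string(index=False))
print("\nsingle-pool candidates abound (pools of 22 are noisy); only regions")
print("replicated across selected pools and absent from the unselected control")
print("survive, and those coincide with the planted minor loci.")
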
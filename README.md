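# bsamap

Pooled-segregant whole-genome QTL mapping (BSA-seq) for haploid crosses,
built around the design used to dissect low-glycerol/high-ethanol yield in
an industrial yeast backcross: screen hundreds of meiotic segregants for an
extreme phenotype, pool the best ones, sequence the pools, and look for
genome regions where the selected pool's allele frequency deviates from the
0.5 expected under fair segregation.

The package is for geneticists who want to *plan or stress-test* such an
experiment in silico — how many segregants, what sequencing depth, how many
independent pools are needed before a minor-effect locus separates from the
random allele-frequency excursions that small pools inevitably produce —
and for analysing real per-SNP allele-count tables (TSV or a VCF/AD
dialect) with the same machinery.

## The model and statistics

**Cross simulation.** Two parental haplotypes differ at an ordered SNP map
(default: 16 chromosomes × 350 informative markers). Meiosis follows the
Haldane model — crossover counts Poisson with mean equal to the genetic map
length, positions uniform, no interference — implemented as the equivalent
two-state Markov chain along markers (switch probability
r = (1 − e^(−2d))/2 at genetic distance d). Random inbreeding (mating +
sporulation, one spore per mating) accumulates recombination junctions,
narrowing linked blocks: F5 genomes carry ~3× the breakpoints of F1.

**Trait model.** Relative glycerol yield (reference strain = 100 %) is
additive over causal loci: each locus adds δ_j points when the
inferior-parent allele is carried, unless epistatically masked — the
default major locus (δ = 15) is silenced whenever either strong minor locus
carries the superior allele. Ethanol yield is inversely coupled,
`ethanol% = 100 − c·Σδ_j x_j m_j + ε′` with c ≈ 0.041, producing the
inverse glycerol–ethanol correlation seen in segregant screens.

**Mapping.** Pool counts at marker i are n_i ~ Poisson(depth) reads with
k_i ~ Binomial(n_i, f_i) superior-parent reads. The variant-frequency track
k_i/n_i is smoothed (coverage-weighted tricube kernel with a 95 % band) and
segmented by a 3-state hidden Markov model with binomial emissions —
neutral (p = 0.5), linked-superior (p = p_link = 0.9), linked-inferior
(1 − p_link) — and distance-decaying transitions
T(d) = e^(−d/λ)·I + (1 − e^(−d/λ))·1π. Posterior decoding (forward–backward
in log space) calls maximal runs with linked posterior ≥ 0.95. This HMM is
a documented substitute for the unpublished segmentation model used in the
original analyses; all parameters are explicit.

**Validation.** Individual segregants are scored at candidate markers and
tested with the *exact* one-sided binomial tail under p = 0.5 (both
directions always reported). Because a 22-segregant pool produces genuine
~0.73-frequency blocks by composition noise alone, candidate regions are
only trusted when concordant-direction calls replicate across ≥ 2
independent selected pools and are absent from the unselected control pool.

**Allele analysis.** Selected segregants are grouped by their combination
of superior alleles (mean yields per group), allele frequencies are binned
along the phenotype axis, loci are ranked by potency (frequency in the
lowest-glycerol bin, ties broken by the next), and an epistasis contrast
compares a focal locus's effect between permissive and suppressive genetic
backgrounds with a permutation test.

## Worked example

`examples/` holds one short script per capability. The full in-silico
experiment (`python examples/06_full_experiment.py`):

```
config hash 33ca2f0ea294d6cb, seed 1
screened {'F1-initial': 260, 'F1-additional': 400, 'F5': 400} -> cut-off passers {'F1-initial': 39, 'F1-additional': 61, 'F5': 48}
pool sizes {'selected_f1_a': 17, 'selected_f1_b': 22, 'selected_f5': 21, 'unselected': 22}
candidate regions per pool: {'selected_f1_a': 25, 'selected_f1_b': 57, 'selected_f5': 30, 'unselected': 30}

13 regions validated by multi-pool concordance:
  chr  2  438,077-471,801  superior  posterior 0.999
  chr  4  354,892-396,807  superior  posterior 1.000
  ...
  chr 13  375,429-378,750  superior  posterior 0.999
planted causal loci (chrom, bp, effect): [(8, 375314, 15.0), (4, 374987, 8.0), (13, 375429, 6.0), (2, 374989, 5.0)]
```

Reading the numbers: of 1,060 screened segregants, ~14 % pass the cut-offs
(glycerol < 120 %, ethanol > 99 % of the reference) and the best 60 form
three selected pools. Each pool alone yields dozens of candidate regions —
mostly random coincidences of the small pool — but concordance filtering
collapses them onto intervals on chromosomes 2, 4 and 13, where the three
minor loci were planted (validated intervals fragment into several
sub-intervals around each locus, including linkage "shoulders" dragged
along by selection). The masked major locus on chromosome 8 is *not*
mapped: its effect is suppressed in nearly all selected segregants, exactly
the behaviour that motivates the epistasis contrast
(`examples/05_allele_combinations.py`). The per-marker table shows why
pooling three selections matters: at a variant frequency of 0.70, 22
segregants cannot reject fair segregation (p ≈ 0.07) but 60–70 can
(p ≈ 10⁻³).

## Command line

A thin CLI wraps the library for shell use:

```sh
bsamap run --config config.yaml --out runs/exp1        # full pipeline
bsamap phenotype --fermentations ferm.tsv --out yields.tsv
bsamap map --counts pool_counts.tsv --out-prefix pool  # smoothing + HMM
bsamap validate --selected a.tsv --selected b.tsv --unselected u.tsv --out ok.tsv
```

## Layout

```
src/bsamap/
  sim_cross.py        SNP maps, meiosis, inbreeding, trait model
  phenotyping.py      yields, normalisation, selection cut-offs
  poolseq.py          pools, read-count sampling, variant frequencies
  qtl_map.py          kernel smoothing, binomial-emission HMM, region calls
  validation.py       exact binomial tests, multi-pool concordance
  allele_analysis.py  combination groups, binned frequencies, epistasis
  orchestration.py    end-to-end experiment with provenance manifest
  io.py               TSV / VCF-dialect / BED readers and writers
  cli.py, plotting.py
docs/methods.md       model assumptions, defaults, limitations
examples/             one narrative script per capability
```
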
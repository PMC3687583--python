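# Methods

This note records the models behind `bsamap`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices a user should know before trusting or changing them.

## Cross and meiosis

Segregants are haploid meiotic products of a cross between a "superior"
and an "inferior" parent that differ at every marker of an ordered SNP map.
Crossovers follow the Haldane model: per chromosome, a Poisson number of
crossovers with mean equal to the genetic map length (Morgans), positions
uniform on the chromosome, no interference, and a fair coin for the
starting parent. At marker resolution this process is exactly a two-state
Markov chain whose switch probability between adjacent markers at genetic
distance *d* is the recombination fraction (1 − e^(−2d))/2; the
implementation uses that chain because it vectorises over whole populations
and — by the Markov property — simulating a marker *subset* reproduces the
exact marginal law of the full map. Monte-Carlo analyses that only need the
trait-relevant loci therefore run on a 40-marker subset of the 5,600-marker
genome without approximation. Junction counts are reported at marker
resolution; an even number of crossovers falling between two adjacent
markers is invisible there (a negligible deficit at the default marker
spacing of ~2 kb ≈ 0.001 Morgans).

Random inbreeding mates random distinct pairs and keeps one meiotic
product per mating (population size preserved, matching random-spore
harvesting); four rounds turn F1 into F5 and roughly triple the junction
count, which is what narrows mapped intervals in advanced generations.

Defaults: 16 chromosomes, 350 markers each (5,600 informative markers, the
scale of the informative-SNP set in the motivating cross), 750 kb and
2.7 Morgans per chromosome (≈ 0.36 cM/kb, the yeast genome-wide average).

## Trait model

Relative glycerol yield is `100 + Σ_j δ_j·x_j·m_j + ε`, with x_j = 1 iff
the inferior allele is carried at causal locus j, m_j = 0 iff the locus is
masked (its suppressor rule — default "any", i.e. at least one suppressor
locus superior — is met), and ε ~ N(0, σ_G). Relative ethanol yield is
`100 − c·(Σ_j δ_j·x_j·m_j) + ε′`: coupled to the *genetic* glycerol
component only, so measurement noise on the two yields is independent.

Defaults: focal effects δ = (15, 8, 6, 5) percentage points, the 15-point
major masked by the two strongest minors; σ_G = 8, σ_E = 0.4; coupling
c = 0.041 (the printed parent contrast of 1.9 ethanol points per 46
glycerol points). In addition the default model carries a polygenic
background of 36 one-point loci spread over the genome, standing in for
the unmapped minor QTLs the source screen itself inferred. The background
size was calibrated once, before any test was written, so that the
fraction of F1 segregants passing the printed cut-offs (<120 % glycerol,
>99 % ethanol) matches the observed screen rate (~13 %; without a
background a masked-major model centres near 112 % and ~70 % of segregants
pass). The trade-off is explicit: the simulated all-inferior genotype sits
at 170 % rather than the printed 146 % parental mean. We prioritised the
population-level quantities the pipeline actually consumes (selection
rate, spread, coupling) over the single parental datum; both the locus set
and the background are fully configurable.

Two consequences of this model worth knowing:

* The F1 glycerol distribution is *mildly right-skewed* (generating
  skewness ≈ 0.43): the masked major adds +15 points to the one-eighth of
  segregants whose suppressor loci are both inferior. A Shapiro–Wilk test
  at n = 260 detects this in roughly half of screens, so "approximately
  Gaussian" is asserted via loose moment bounds (|skew| < 0.75, |excess
  kurtosis| < 1.5 on pooled screens), not via a normality test.
* Selection depletes the permissive background, so the epistasis contrast
  (below) must be run on unselected panels or constructed designs, never
  on the selected segregants alone.

## Screening and selection

The screen mirrors the source design: 260 + 400 F1 segregants and 400
advanced segregants (four inbreeding rounds) are phenotyped once; passers
of the strict cut-offs (glycerol < 120 %, ethanol > 99 %) are *retested*
with triplicate-mean noise (σ/√3) and the cut-offs re-applied; the
lowest-glycerol confirmed segregants form the pools (caps 22/22/26 — the
retest may confirm fewer, as in the original 34 → 22 step). An unselected
control pool draws 22 random F1 segregants. All downstream
allele-combination analyses use the retest (replicate-mean) values, as the
source figures did. Replicate fermentation rows in real input tables are
averaged, and relative yields are computed against the reference strain
run in the same batch.

## Pooled sequencing

Pools weight members equally; the pool's true frequency at a marker is the
mean of member origin indicators. Coverage is Poisson per marker (default
100×), allele counts binomial with a symmetric substitution error (default
0.002). Markers drawn with zero coverage are carried as missing — never as
0/0 — and skipped by smoothing; the HMM carries them with unit emission
likelihood, which is mathematically identical to skipping them because the
transition family is multiplicative in distance. What is *not* modelled:
reads, base qualities, mapping bias, duplicates, or diploid intermediates.

## Smoothing and the linkage HMM

The smoother is a coverage-weighted tricube kernel (default bandwidth
30 kb) with a 95 % band from the window's effective binomial sample size
(normal approximation, clipped to [0, 1]); it is a transparent stand-in
for the unpublished smoothing of the original pipeline and is used for
visualisation, not detection.

Detection uses a 3-state HMM with binomial emissions at probabilities
(0.5, p_link, 1 − p_link), stationary prior π = (0.98, 0.01, 0.01) that
also initialises each chromosome, and transitions
T(d) = e^(−d/λ)·I + (1 − e^(−d/λ))·1π between adjacent markers at physical
distance d. Defaults: p_link = 0.9, λ = 20 kb (the scale of the mapped
intervals), posterior threshold 0.95, minimum 3 markers per region.
Forward–backward runs in log space (depth-100 likelihoods over thousands
of markers underflow otherwise); the rank-one structure of T(d) gives a
closed-form update per step, verified against exhaustive path enumeration
to 10⁻¹⁰. Mirror symmetry holds exactly: replacing k by n − k swaps
superior and inferior calls.

With 22-member pools the *data* genuinely contain ~0.73-frequency blocks
from pool composition alone, so single pools produce on the order of
15–30 candidate regions per genome, most of them short random
coincidences — reproducing the false-QTL problem the multi-pool design
exists to solve. Detection is reliable for region frequencies above
≈ 0.75 at 100× and decays quickly below.

## Concordance validation

A candidate region is validated iff same-direction regions in ≥ 2 selected
pools support it and no same-direction region of the unselected pool
touches it; the reported interval is the intersection of supporters.
Support requires the overlap to cover ≥ 25 % of the *shorter* of the two
intervals. The fraction is an artifact choice; the shorter-interval basis
is deliberate: advanced-generation pools call systematically narrower
intervals around the same locus (that is the point of inbreeding), and a
longer-interval ("reciprocal") basis rejects those genuine F1/F5 matches —
measured at study conditions it drops replicated-region retention from
~98 % to ~83 %. Validated intervals can fragment into several
sub-intervals around one locus, including linkage shoulders dragged along
by selection; they are reported as called, without post-hoc merging.

Measured at the defaults (20 seeds): ≥ 2 of the 3 planted minor loci are
recovered by the mapping stage in 20/20 seeds; planted regions replicated
in ≥ 2 pools survive the filter in ~98 % of cases; ~98 % of spurious
single-pool regions under a null trait are rejected. Per-seed, however,
some cross-pool coincidence survives in roughly a quarter of null genomes
— with three small pools the filter thins false QTLs dramatically but does
not guarantee an empty null call set.

## Marker tests and their power

The per-marker linkage test is the exact one-sided binomial tail under
p = 0.5, computed by integer summation (no approximation) and reported in
both directions; no multiple-testing correction is applied by default
(markers are few and pre-selected by the HMM; a Bonferroni flag exists).
The attained false-call rate (either direction, group of 22, α = 0.05) is
2·P(X ≥ 16) ≈ 0.052. Power ordering at the planted effects: all three
minor markers reach p < 0.05 in ~60–80 % of replicate screens with 22
scored segregants and in ~100 % with 70 — the quantitative version of why
the source study accumulated three selection rounds.

## Allele-combination analyses

Groups are the 2^L superior-allele combinations over the scored loci, with
replicate-mean yields per group. Binned allele frequencies keep the
published fixed-edge interface (first bin open below its edge, default
9 bins from 96.5 % in 2.3 % steps); because the published edges realise an
equal-occupancy rule on that study's own data, simulation-facing analyses
derive edges from the simulated distribution's quantiles instead — with
the fixed published edges the simulation's lowest bin is empty, since the
simulated reference (100 %) *is* the genetic optimum, unlike the real
reference strain. Potency ranks loci by superior-allele frequency in the
lowest-glycerol bin, ties broken by subsequent bins.

These ordinal statistics are noisy at n = 70: the all-superior group has
the lowest mean glycerol in ~72 % of replicate screens (small occupied
groups of 2–3 strains undercut it by chance), and the full three-way
potency ranking of effects separated by 2–3 points is recovered in ~50 %
(the top locus alone in ~75 %). The package reports these rates as
measured; a screen of this size supports the qualitative enrichment
pattern, not a reliable strict ordering.

The epistasis contrast estimates the focal-locus effect (inferior minus
superior allele, difference of means) separately in strains lacking vs
carrying superior alleles at the suppressor loci, with a one-sided
permutation test (focal genotype shuffled within background strata,
default 1,000 permutations). On noise-free masked data it returns exactly
(δ, 0); on unmasked data the contrast is centred on zero.

## Determinism and provenance

A single experiment seed deterministically derives every stage's stream
(numpy `SeedSequence` spawning; derived seeds kept below 2³¹). Re-running
a configuration is bit-identical, and the manifest records the
configuration hash, per-stage seeds and stage record counts. Monte-Carlo
test sizes (20 pipeline seeds, 200 replicate screens, 1,000 instances for
the enumeration and null checks) were chosen to keep the full suite around
two minutes while leaving the assertions' Monte-Carlo error well inside
their margins.

## Known limitations

* No crossover interference, no mitochondrial or mating-type genetics, no
  sequence-level read simulation.
* The trait model is additive with hard masking; partial suppression or
  locus-by-environment effects are out of scope.
* The HMM is a documented substitute for the original unpublished
  segmentation model; absolute posterior values are comparable only within
  this model family.
* Real-data entry starts at per-SNP allele counts; read mapping and SNP
  calling are upstream of this package.
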
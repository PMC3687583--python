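"""Simulation of a yeast backcross: parental SNP maps, meiotic segregants
and quantitative phenotypes.

The simulator emulates a haploid-segregant mapping population derived from
two parent strains ("superior" and "inferior") that differ at a genome-wide
set of informative SNP markers.  Meiosis follows the Haldane model: crossover
counts are Poisson with mean equal to the chromosome's genetic map length
(in Morgans) and crossover positions are uniform, with no interference.  At
marker resolution this process is exactly a two-state Markov chain along
each chromosome whose switch probability between adjacent markers at genetic
distance ``d`` Morgans is the recombination fraction ``(1 - exp(-2 d)) / 2``;
that equivalent chain is what is implemented, because it vectorises over
whole populations and marginalises exactly onto any marker subset.

Phenotypes follow an additive polygenic model with optional epistatic
masking: each causal locus adds ``delta_j`` percentage points of glycerol
yield when the inferior-parent allele is carried, unless the locus is masked
because superior alleles are present at its suppressor loci.  Ethanol yield
is inversely coupled to the genetic glycerol component.  Both yields are
expressed relative to the superior parent (= 100 %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ORIGIN_SUPERIOR",
    "ORIGIN_INFERIOR",
    "SnpMap",
    "SegregantGenome",
    "EpistasisMask",
    "TraitModel",
    "simulate_parental_genomes",
    "simulate_meiosis",
    "simulate_f1_population",
    "inbreed",
    "assign_phenotype",
    "assign_phenotypes",
    "default_trait_model",
    "subset_trait_model",
    "origins_matrix",
    "genotype_frame",
    "junction_count",
    "as_rng",
]

#: integer codes for the parental origin of a marker allele
ORIGIN_SUPERIOR = 1
ORIGIN_INFERIOR = 0

#: genotype symbols used in tabular output
SYMBOL_SUPERIOR = "S"
SYMBOL_INFERIOR = "I"

_BASES = np.array(list("ACGT"))


def as_rng(seed) -> np.random.Generator:
    """Return a numpy Generator from a seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# SNP map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpMap:
    """Ordered set of informative markers on a multi-chromosome genome.

    Markers must be sorted by (chromosome, position) with strictly
    increasing positions within a chromosome, and every marker must be
    informative (the two parental alleles differ).

    Parameters
    ----------
    chrom, pos
        Per-marker chromosome id (1-based) and bp position (1-based).
    superior_allele, inferior_allele
        Per-marker allele labels of the two parents.
    chrom_lengths, map_lengths
        Physical length (bp) and genetic map length (Morgans) per
        chromosome, aligned with :attr:`chromosomes`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    superior_allele: np.ndarray
    inferior_allele: np.ndarray
    chrom_lengths: np.ndarray
    map_lengths: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=np.int64))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        object.__setattr__(self, "superior_allele", np.asarray(self.superior_allele, dtype=object))
        object.__setattr__(self, "inferior_allele", np.asarray(self.inferior_allele, dtype=object))
        object.__setattr__(self, "chrom_lengths", np.asarray(self.chrom_lengths, dtype=np.int64))
        object.__setattr__(self, "map_lengths", np.asarray(self.map_lengths, dtype=float))
        self._validate()

    def _validate(self):
        if self.chrom.ndim != 1 or len({len(self.chrom), len(self.pos), len(self.superior_allele), len(self.inferior_allele)}) != 1:
            raise ValueError("marker columns must be 1-D and equal length")
        chroms = self.chromosomes
        if len(self.chrom_lengths) != len(chroms) or len(self.map_lengths) != len(chroms):
            raise ValueError("need one physical and one map length per chromosome")
        if np.any(self.chrom_lengths <= 0) or np.any(self.map_lengths < 0):
            raise ValueError("chromosome lengths must be positive and map lengths non-negative")
        if np.any(self.chrom[:-1] > self.chrom[1:]):
            raise ValueError("markers must be sorted by chromosome")
        for c, sl in self.chromosome_slices().items():
            p = self.pos[sl]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions must be strictly increasing on chromosome {c}")
            if p[0] < 1 or p[-1] > self.length_of(c):
                raise ValueError(f"marker position outside chromosome {c} (length {self.length_of(c)})")
        if np.any(self.superior_allele == self.inferior_allele):
            raise ValueError("all markers must be informative (parental alleles differ)")

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chromosome_slices(self) -> dict[int, slice]:
        """Contiguous marker slice per chromosome, in chromosome order."""
        out: dict[int, slice] = {}
        bounds = np.searchsorted(self.chrom, self.chromosomes, side="left")
        bounds = np.append(bounds, self.n_markers)
        for i, c in enumerate(self.chromosomes):
            out[int(c)] = slice(int(bounds[i]), int(bounds[i + 1]))
        return out

    def _chrom_index(self, c: int) -> int:
        idx = np.searchsorted(self.chromosomes, c)
        if idx >= len(self.chromosomes) or self.chromosomes[idx] != c:
            raise KeyError(f"no such chromosome: {c}")
        return int(idx)

    def length_of(self, c: int) -> int:
        return int(self.chrom_lengths[self._chrom_index(c)])

    def map_length_of(self, c: int) -> float:
        return float(self.map_lengths[self._chrom_index(c)])

    def marker_index(self, chrom: int, pos: int) -> int:
        """Index of the marker at an exact (chrom, pos); KeyError if absent."""
        sl = self.chromosome_slices().get(int(chrom))
        if sl is None:
            raise KeyError(f"no such chromosome: {chrom}")
        p = self.pos[sl]
        j = int(np.searchsorted(p, pos))
        if j >= len(p) or p[j] != pos:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return sl.start + j

    def subset(self, indices: Sequence[int]) -> "SnpMap":
        """Restrict the map to a marker subset (exact marginalisation).

        The Markov property of the Haldane crossover process makes
        simulation on a subset distributionally identical to simulating the
        full map and discarding the other markers.
        """
        idx = np.sort(np.asarray(indices, dtype=np.int64))
        kept = np.unique(self.chrom[idx])
        which = [self._chrom_index(int(c)) for c in kept]
        return SnpMap(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            superior_allele=self.superior_allele[idx],
            inferior_allele=self.inferior_allele[idx],
            chrom_lengths=self.chrom_lengths[which],
            map_lengths=self.map_lengths[which],
        )

    def switch_probabilities(self) -> dict[int, np.ndarray]:
        """Recombination fraction between adjacent markers, per chromosome."""
        out: dict[int, np.ndarray] = {}
        for c, sl in self.chromosome_slices().items():
            d_bp = np.diff(self.pos[sl]).astype(float)
            d_m = self.map_length_of(c) * d_bp / self.length_of(c)
            out[c] = 0.5 * (1.0 - np.exp(-2.0 * d_m))
        return out


def simulate_parental_genomes(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chrom_lengths=750_000,
    map_lengths=2.7,
    seed=None,
) -> SnpMap:
    """Draw a random informative SNP map for a two-parent cross.

    Marker positions are uniform without replacement within each chromosome;
    parental alleles are distinct random nucleotides.  Deterministic for a
    fixed ``seed``.

    ``chrom_lengths`` (bp) and ``map_lengths`` (Morgans) may be scalars or
    per-chromosome sequences.  Defaults approximate a yeast chromosome
    (0.36 cM/kb).
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("need at least one chromosome and one marker per chromosome")
    lengths = np.broadcast_to(np.asarray(chrom_lengths, dtype=np.int64), (n_chromosomes,)).copy()
    morgans = np.broadcast_to(np.asarray(map_lengths, dtype=float), (n_chromosomes,)).copy()
    if np.any(lengths <= 0) or np.any(morgans < 0):
        raise ValueError("chromosome lengths must be positive and map lengths non-negative")
    if np.any(lengths < markers_per_chromosome):
        raise ValueError("chromosome shorter than the number of requested markers")
    rng = as_rng(seed)
    chrom, pos, sup, inf = [], [], [], []
    for c in range(1, n_chromosomes + 1):
        p = np.sort(rng.choice(lengths[c - 1], size=markers_per_chromosome, replace=False)) + 1
        a = rng.integers(0, 4, size=markers_per_chromosome)
        b = (a + rng.integers(1, 4, size=markers_per_chromosome)) % 4  # always differs
        chrom.append(np.full(markers_per_chromosome, c))
        pos.append(p)
        sup.append(_BASES[a])
        inf.append(_BASES[b])
    return SnpMap(
        chrom=np.concatenate(chrom),
        pos=np.concatenate(pos),
        superior_allele=np.concatenate(sup),
        inferior_allele=np.concatenate(inf),
        chrom_lengths=lengths,
        map_lengths=morgans,
    )


# ---------------------------------------------------------------------------
# Segregants and meiosis
# ---------------------------------------------------------------------------


@dataclass
class SegregantGenome:
    """Haploid segregant: parental origin (0/1) at every map marker."""

    origins: np.ndarray
    generation: str = "F1"
    strain_id: str = ""

    def __post_init__(self):
        self.origins = np.asarray(self.origins, dtype=np.uint8)
        if not np.all((self.origins == ORIGIN_SUPERIOR) | (self.origins == ORIGIN_INFERIOR)):
            raise ValueError("origins must be 0 (inferior) or 1 (superior)")


def _recombination_patterns(snp_map: SnpMap, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, n_markers) matrix of gamete choice patterns (0/1 per marker).

    Per chromosome the starting parent is a fair coin and the pattern
    switches between adjacent markers with the Haldane recombination
    fraction for their genetic distance.
    """
    out = np.empty((n, snp_map.n_markers), dtype=np.uint8)
    switch = snp_map.switch_probabilities()
    for c, sl in snp_map.chromosome_slices().items():
        m = sl.stop - sl.start
        start = (rng.random(n) < 0.5).astype(np.uint8)
        if m == 1:
            out[:, sl] = start[:, None]
            continue
        flips = (rng.random((n, m - 1)) < switch[c]).astype(np.uint8)
        parity = np.cumsum(flips, axis=1, dtype=np.int64) & 1
        block = np.empty((n, m), dtype=np.uint8)
        block[:, 0] = start
        block[:, 1:] = start[:, None] ^ parity.astype(np.uint8)
        out[:, sl] = block
    return out


def simulate_meiosis(snp_map: SnpMap, seed=None, parent_a: np.ndarray | None = None,
                     parent_b: np.ndarray | None = None) -> SegregantGenome:
    """One haploid meiotic product of a diploid.

    Without explicit parent haplotypes this is a gamete of the
    superior x inferior hybrid, i.e. the pattern of parental origins itself.
    """
    rng = as_rng(seed)
    pattern = _recombination_patterns(snp_map, 1, rng)[0]
    if parent_a is None and parent_b is None:
        origins = pattern
    else:
        a = np.asarray(parent_a, dtype=np.uint8)
        b = np.asarray(parent_b, dtype=np.uint8)
        if len(a) != snp_map.n_markers or len(b) != snp_map.n_markers:
            raise ValueError("parent haplotypes must match the marker count")
        origins = np.where(pattern == 1, a, b).astype(np.uint8)
    return SegregantGenome(origins=origins, generation="F1")


def simulate_f1_population(snp_map: SnpMap, n: int, seed=None,
                           id_prefix: str = "F1") -> list[SegregantGenome]:
    """``n`` independent F1 segregants of the superior x inferior hybrid."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = as_rng(seed)
    pats = _recombination_patterns(snp_map, n, rng)
    return [SegregantGenome(origins=pats[i], generation="F1", strain_id=f"{id_prefix}_{i:04d}")
            for i in range(n)]


def origins_matrix(population: Sequence[SegregantGenome]) -> np.ndarray:
    """Stack a population into an (n_strains, n_markers) origin matrix."""
    return np.stack([s.origins for s in population])


def junction_count(genome: SegregantGenome, snp_map: SnpMap) -> int:
    """Number of origin switches between adjacent markers, summed over
    chromosomes (marker-resolution crossover junctions)."""
    total = 0
    for _, sl in snp_map.chromosome_slices().items():
        o = genome.origins[sl]
        total += int(np.sum(o[:-1] != o[1:]))
    return total


def _next_generation_tag(tag: str) -> str:
    if tag.startswith("F") and tag[1:].isdigit():
        return f"F{int(tag[1:]) + 1}"
    return tag + "+1"


def inbreed(population: Sequence[SegregantGenome], rounds: int, snp_map: SnpMap,
            seed=None) -> list[SegregantGenome]:
    """Random inbreeding: each round mates random pairs of distinct
    segregants and keeps one meiotic product per mating, preserving the
    population size.  Four rounds turn F1 into F5.
    """
    if len(population) < 2:
        raise ValueError("inbreeding needs a population of at least 2")
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if rounds == 0:
        return list(population)
    rng = as_rng(seed)
    mat = origins_matrix(population)
    tag = population[0].generation
    n = len(population)
    for _ in range(rounds):
        ia = rng.integers(0, n, size=n)
        ib = (ia + 1 + rng.integers(0, n - 1, size=n)) % n  # distinct mate
        pats = _recombination_patterns(snp_map, n, rng)
        mat = np.where(pats == 1, mat[ia], mat[ib]).astype(np.uint8)
        tag = _next_generation_tag(tag)
    return [SegregantGenome(origins=mat[i], generation=tag, strain_id=f"{tag}_{i:04d}")
            for i in range(n)]


# ---------------------------------------------------------------------------
# Trait model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpistasisMask:
    """Suppression of a causal locus by superior alleles elsewhere.

    ``rule='any'``: the locus is masked when at least one suppressor locus
    carries the superior allele ("and/or" epistasis); ``rule='all'``
    requires every suppressor to be superior.
    """

    suppressors: tuple[int, ...]
    rule: str = "any"

    def __post_init__(self):
        if self.rule not in ("any", "all"):
            raise ValueError("mask rule must be 'any' or 'all'")
        if not self.suppressors:
            raise ValueError("a mask needs at least one suppressor locus")


@dataclass(frozen=True)
class TraitModel:
    """Polygenic glycerol/ethanol trait with epistatic masking.

    The all-superior genotype sits at the reference level (100 %).  Each
    causal locus j adds ``effects[j]`` percentage points of glycerol yield
    when the inferior allele is carried and the locus is not masked.
    Ethanol yield is ``100 - ethanol_coupling * (genetic glycerol
    component)`` plus independent noise, producing the inverse
    glycerol/ethanol correlation seen in segregant screens.

    ``background_loci`` model additional unmapped minor QTLs; they follow
    the same additive rule but are not targets of the mapping analyses.
    """

    causal_loci: tuple[int, ...]
    effects: tuple[float, ...]
    masks: Mapping[int, EpistasisMask] = field(default_factory=dict)
    background_loci: tuple[int, ...] = ()
    background_effects: tuple[float, ...] = ()
    sigma_glycerol: float = 8.0
    ethanol_coupling: float = 0.041
    sigma_ethanol: float = 0.4
    reference_level: float = 100.0

    def __post_init__(self):
        if len(self.causal_loci) != len(self.effects):
            raise ValueError("one effect per causal locus required")
        if len(self.background_loci) != len(self.background_effects):
            raise ValueError("one effect per background locus required")
        if any(e < 0 for e in self.effects) or any(e < 0 for e in self.background_effects):
            raise ValueError("effect sizes must be >= 0")
        if self.sigma_glycerol < 0 or self.sigma_ethanol < 0 or self.ethanol_coupling < 0:
            raise ValueError("noise SDs and coupling must be >= 0")
        causal = set(self.causal_loci)
        for locus, mask in self.masks.items():
            if locus not in causal:
                raise ValueError(f"masked locus {locus} is not a causal locus")
            if not set(mask.suppressors) <= causal:
                raise ValueError(f"suppressors of locus {locus} must be causal loci")
            if locus in mask.suppressors:
                raise ValueError(f"locus {locus} cannot suppress itself")

    def genetic_values(self, origins: np.ndarray) -> np.ndarray:
        """Genetic glycerol component (percentage points above reference)
        for an (n, n_markers) origin matrix."""
        origins = np.atleast_2d(origins)
        total = np.zeros(origins.shape[0])
        for locus, delta in zip(self.causal_loci, self.effects):
            x = origins[:, locus] == ORIGIN_INFERIOR
            mask = self.masks.get(locus)
            if mask is not None:
                sup = origins[:, list(mask.suppressors)] == ORIGIN_SUPERIOR
                suppressed = sup.any(axis=1) if mask.rule == "any" else sup.all(axis=1)
                x = x & ~suppressed
            total += delta * x
        for locus, delta in zip(self.background_loci, self.background_effects):
            total += delta * (origins[:, locus] == ORIGIN_INFERIOR)
        return total


def assign_phenotype(segregant: SegregantGenome, trait_model: TraitModel, seed=None,
                     replicates: int = 1) -> tuple[float, float]:
    """Relative (glycerol %, ethanol %) yields of one segregant.

    ``replicates`` > 1 reports the mean of that many replicate
    fermentations (measurement noise shrinks by 1/sqrt(replicates))."""
    rng = as_rng(seed)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    g = float(trait_model.genetic_values(segregant.origins[None, :])[0])
    scale = math.sqrt(replicates)
    gly = trait_model.reference_level + g + rng.normal(0.0, trait_model.sigma_glycerol / scale)
    eth = trait_model.reference_level - trait_model.ethanol_coupling * g \
        + rng.normal(0.0, trait_model.sigma_ethanol / scale)
    return gly, eth


def assign_phenotypes(population: Sequence[SegregantGenome], trait_model: TraitModel,
                      seed=None, replicates: int = 1):
    """Phenotype a whole population; returns a DataFrame with columns
    ``strain, glycerol_rel, ethanol_rel, generation``.  ``replicates`` as in
    :func:`assign_phenotype`."""
    import pandas as pd

    rng = as_rng(seed)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    mat = origins_matrix(population)
    g = trait_model.genetic_values(mat)
    scale = math.sqrt(replicates)
    gly = trait_model.reference_level + g \
        + rng.normal(0.0, trait_model.sigma_glycerol / scale, len(g))
    eth = trait_model.reference_level - trait_model.ethanol_coupling * g \
        + rng.normal(0.0, trait_model.sigma_ethanol / scale, len(g))
    return pd.DataFrame({
        "strain": [s.strain_id for s in population],
        "glycerol_rel": gly,
        "ethanol_rel": eth,
        "generation": [s.generation for s in population],
    })


def genotype_frame(population: Sequence[SegregantGenome], markers: Sequence[int] | None = None):
    """Genotype table (strains x markers, symbols S/I) as a DataFrame."""
    import pandas as pd

    mat = origins_matrix(population)
    if markers is not None:
        markers = list(markers)
        mat = mat[:, markers]
        cols = markers
    else:
        cols = list(range(mat.shape[1]))
    sym = np.where(mat == ORIGIN_SUPERIOR, SYMBOL_SUPERIOR, SYMBOL_INFERIOR)
    return pd.DataFrame(sym, index=[s.strain_id for s in population], columns=cols)


def subset_trait_model(model: TraitModel, indices: Sequence[int]) -> TraitModel:
    """Re-express a trait model on a marker subset (see ``SnpMap.subset``).

    All causal and background loci must be members of ``indices``; locus
    indices are remapped to their positions within the sorted subset.
    """
    ordered = sorted(set(int(i) for i in indices))
    index_of = {g: i for i, g in enumerate(ordered)}
    referenced = list(model.causal_loci) + list(model.background_loci)
    missing = [l for l in referenced if l not in index_of]
    if missing:
        raise ValueError(f"subset lacks trait loci: {missing}")
    return TraitModel(
        causal_loci=tuple(index_of[l] for l in model.causal_loci),
        effects=model.effects,
        masks={index_of[l]: EpistasisMask(
            suppressors=tuple(index_of[s] for s in m.suppressors), rule=m.rule)
            for l, m in model.masks.items()},
        background_loci=tuple(index_of[l] for l in model.background_loci),
        background_effects=model.background_effects,
        sigma_glycerol=model.sigma_glycerol,
        ethanol_coupling=model.ethanol_coupling,
        sigma_ethanol=model.sigma_ethanol,
        reference_level=model.reference_level,
    )


def _middle_marker(snp_map: SnpMap, chrom: int, fraction: float = 0.5) -> int:
    sl = snp_map.chromosome_slices()[chrom]
    target = fraction * snp_map.length_of(chrom)
    j = int(np.argmin(np.abs(snp_map.pos[sl] - target)))
    return sl.start + j

def default_trait_model(snp_map: SnpMap) -> TraitModel:
    """Study-condition trait model for the default 16-chromosome map.

    Three minor causal loci (8, 6 and 5 points, echoing the potency order
    of the mapped glycerol alleles) on chromosomes 4, 13 and 2; one major
    locus (15 points) on chromosome 8 whose effect is epistatically masked
    whenever either of the two strongest minor loci carries the superior
    allele; and a polygenic background of 36 one-point loci spread over the
    genome, standing in for unmapped minor QTLs.  The background is
    calibrated so the fraction of F1 segregants passing the screening
    cut-offs (<120 % glycerol, >99 % ethanol) matches the observed screen
    (~13 %).
    """
    chroms = snp_map.chromosomes
    need = {2, 4, 8, 13}
    if not need <= set(int(c) for c in chroms):
        raise ValueError("default trait model expects chromosomes 2, 4, 8 and 13 in the map")
    minor1 = _middle_marker(snp_map, 4)    # delta 8
    minor2 = _middle_marker(snp_map, 13)   # delta 6
    minor3 = _middle_marker(snp_map, 2)    # delta 5
    major = _middle_marker(snp_map, 8)     # delta 15, masked
    background = []
    for c in chroms:
        background.append(_middle_marker(snp_map, int(c), 0.25))
        background.append(_middle_marker(snp_map, int(c), 0.75))
    for c in (1, 3, 5, 7):
        if c in set(int(x) for x in chroms):
            background.append(_middle_marker(snp_map, c, 0.5))
    background = tuple(b for b in dict.fromkeys(background)
                       if b not in {minor1, minor2, minor3, major})
    return TraitModel(
        causal_loci=(major, minor1, minor2, minor3),
        effects=(15.0, 8.0, 6.0, 5.0),
        masks={major: EpistasisMask(suppressors=(minor1, minor2), rule="any")},
        background_loci=background,
        background_effects=tuple(1.0 for _ in background),
    )
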
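"""Pool assembly and pooled-sequencing read counts.

A pool combines selected (or random control) segregants with equal weight,
mimicking pooling equal amounts of cells; the pool's true superior-allele
frequency at a marker is the mean of the members' origin indicators.
Sequencing is emulated by Poisson coverage per marker and binomial allele
counts with a symmetric substitution error; the variant frequency of a
marker is the superior-allele read count divided by the total aligned
reads, 0.5 in expectation under no linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sim_cross import ORIGIN_SUPERIOR, SegregantGenome, SnpMap, as_rng, origins_matrix

__all__ = [
    "Pool",
    "PoolCounts",
    "VariantFrequencyTrack",
    "build_pool",
    "sample_read_counts",
    "variant_frequency",
    "filter_informative",
]


@dataclass
class Pool:
    """Composition of a segregant pool: per-marker true superior-allele
    frequency plus membership metadata."""

    pool_id: str
    frequencies: np.ndarray
    n_segregants: int
    selected: bool = True
    generations: Mapping[str, int] = field(default_factory=dict)
    member_ids: tuple[str, ...] = ()

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any((self.frequencies < 0) | (self.frequencies > 1)):
            raise ValueError("pool frequencies must lie in [0, 1]")


@dataclass
class PoolCounts:
    """Per-marker superior-allele (k) and total (n) read counts of a pool."""

    pool_id: str
    chrom: np.ndarray
    pos: np.ndarray
    k: np.ndarray
    n: np.ndarray
    n_segregants: int | None = None
    selected: bool | None = None
    generations: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if not (len(self.chrom) == len(self.pos) == len(self.k) == len(self.n)):
            raise ValueError("count columns must have equal length")
        if np.any(self.k < 0) or np.any(self.n < 0):
            raise ValueError("read counts must be >= 0")
        if np.any(self.k > self.n):
            bad = int(np.argmax(self.k > self.n))
            raise ValueError(
                f"corrupt counts at {self.chrom[bad]}:{self.pos[bad]}: k={self.k[bad]} > n={self.n[bad]}")

    @property
    def n_markers(self) -> int:
        return len(self.pos)


@dataclass
class VariantFrequencyTrack:
    """Raw superior-allele frequency per marker; NaN where uncovered."""

    chrom: np.ndarray
    pos: np.ndarray
    freq: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freq = np.asarray(self.freq, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        covered = self.coverage > 0
        f = self.freq[covered]
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if not np.all(np.isnan(self.freq[~covered])):
            raise ValueError("frequency must be missing (NaN) where coverage is 0")

    @property
    def n_markers(self) -> int:
        return len(self.pos)


def build_pool(segregants: Sequence[SegregantGenome], pool_id: str,
               selected: bool = True) -> Pool:
    """Equal-weight pool of segregants; frequency at marker i is the mean of
    the members' superior-origin indicators."""
    if len(segregants) == 0:
        raise ValueError("cannot build a pool from zero segregants")
    mat = origins_matrix(segregants)
    freqs = (mat == ORIGIN_SUPERIOR).mean(axis=0)
    generations: dict[str, int] = {}
    for s in segregants:
        generations[s.generation] = generations.get(s.generation, 0) + 1
    return Pool(pool_id=pool_id, frequencies=freqs, n_segregants=len(segregants),
                selected=selected, generations=generations,
                member_ids=tuple(s.strain_id for s in segregants))


def sample_read_counts(pool: Pool, snp_map: SnpMap, mean_depth: float,
                       error_rate: float = 0.002, seed=None) -> PoolCounts:
    """Pooled-sequencing counts: coverage n_i ~ Poisson(mean_depth), and
    superior-allele reads k_i ~ Binomial(n_i, f_i(1-e) + (1-f_i)e) with a
    symmetric substitution error rate e.  Markers drawn with zero coverage
    are carried as missing downstream, never as 0/0 frequencies.
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must lie in [0, 0.5)")
    if len(pool.frequencies) != snp_map.n_markers:
        raise ValueError("pool frequencies must match the marker count")
    rng = as_rng(seed)
    n = rng.poisson(mean_depth, size=snp_map.n_markers)
    p = pool.frequencies * (1.0 - error_rate) + (1.0 - pool.frequencies) * error_rate
    k = rng.binomial(n, p)
    return PoolCounts(pool_id=pool.pool_id, chrom=snp_map.chrom, pos=snp_map.pos,
                      k=k, n=n, n_segregants=pool.n_segregants, selected=pool.selected,
                      generations=dict(pool.generations))


def variant_frequency(counts: PoolCounts) -> VariantFrequencyTrack:
    """Superior-allele variant frequency k_i / n_i, missing where n_i = 0."""
    freq = np.full(counts.n_markers, np.nan)
    covered = counts.n > 0
    freq[covered] = counts.k[covered] / counts.n[covered]
    return VariantFrequencyTrack(chrom=counts.chrom, pos=counts.pos,
                                 freq=freq, coverage=counts.n)


def filter_informative(track: VariantFrequencyTrack, parent_a_genotypes: Sequence,
                       parent_b_genotypes: Sequence) -> VariantFrequencyTrack:
    """Retain only markers where the two parents carry different alleles.

    Genomic stretches identical between the parents carry no mapping
    information and appear as gaps in the filtered track.
    """
    a = np.asarray(parent_a_genotypes, dtype=object)
    b = np.asarray(parent_b_genotypes, dtype=object)
    if len(a) != track.n_markers or len(b) != track.n_markers:
        raise ValueError("parent genotype vectors must match the marker count")
    keep = a != b
    return VariantFrequencyTrack(chrom=track.chrom[keep], pos=track.pos[keep],
                                 freq=track.freq[keep], coverage=track.coverage[keep])
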
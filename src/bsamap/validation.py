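"""Per-marker linkage validation and multi-pool concordance.

Candidate QTLs from pooled sequencing are confirmed by scoring individual
segregants at selected markers and testing the superior-allele count k out
of n scored segregants against the fair-segregation null p = 0.5 with an
exact one-sided binomial tail, separately toward each parent.  Because
small selected pools throw up spurious allele-frequency excursions by
random coincidence, regions are additionally required to replicate across
independent selected pools and to be absent from the unselected control
pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qtl_map import QtlRegion

__all__ = [
    "MarkerScore",
    "score_marker",
    "binomial_linkage_test",
    "evaluate_groups",
    "concordance_filter",
    "reciprocal_overlap",
]


@dataclass(frozen=True)
class MarkerScore:
    """Superior-allele count at one marker in one segregant group, with
    exact one-sided binomial p-values toward each parent."""

    marker: int
    group: str
    n: int
    k: int
    frequency: float
    p_superior: float
    p_inferior: float


def binomial_linkage_test(k: int, n: int, direction: str) -> float:
    """Exact one-sided binomial tail under fair segregation (p = 0.5).

    ``direction='superior'`` returns P(X >= k), ``'inferior'`` returns
    P(X <= k), both by exact integer summation of the Binomial(n, 1/2) mass
    (no normal approximation).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n]; got k={k}, n={n}")
    if direction == "superior":
        tail = sum(math.comb(n, i) for i in range(k, n + 1))
    elif direction == "inferior":
        tail = sum(math.comb(n, i) for i in range(0, k + 1))
    else:
        raise ValueError("direction must be 'superior' or 'inferior'")
    # exact rational tail / 2^n evaluated in floating point
    return tail / (1 << n)


def score_marker(genotypes: pd.DataFrame, marker: int, group: Sequence[str],
                 group_label: str = "") -> MarkerScore:
    """Count superior-allele carriers at a marker within a segregant group.

    ``genotypes`` is a strains x markers table of 'S'/'I' symbols (missing
    calls as NaN); missing genotypes are excluded from n.
    """
    if marker not in genotypes.columns:
        raise ValueError(f"marker {marker} not in the genotype table")
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    absent = [s for s in group if s not in genotypes.index]
    if absent:
        raise ValueError(f"no genotype row for strains: {absent}")
    calls = genotypes.loc[group, marker]
    scored = calls[calls.notna()]
    n = int(len(scored))
    k = int((scored == "S").sum())
    if n == 0:
        raise ValueError(f"no scored genotype at marker {marker} in group {group_label!r}")
    return MarkerScore(
        marker=marker, group=group_label, n=n, k=k, frequency=k / n,
        p_superior=binomial_linkage_test(k, n, "superior"),
        p_inferior=binomial_linkage_test(k, n, "inferior"),
    )


def evaluate_groups(genotypes: pd.DataFrame, markers: Sequence[int],
                    group_defs: Mapping[str, Sequence[str]], alpha: float = 0.05,
                    bonferroni: bool = False) -> pd.DataFrame:
    """Score every marker in every segregant group.

    Returns one row per marker x group with counts, variant frequency, the
    two one-sided exact p-values and significance flags at ``alpha`` (per
    direction; optional Bonferroni correction over the marker list).
    """
    if not group_defs:
        raise ValueError("no segregant groups defined")
    rows = []
    threshold = alpha / len(markers) if (bonferroni and len(markers)) else alpha
    for label, strains in group_defs.items():
        if strains is None or len(list(strains)) == 0:
            raise ValueError(f"group {label!r} is undefined or empty")
        for marker in markers:
            ms = score_marker(genotypes, marker, strains, label)
            rows.append({
                "marker": ms.marker, "group": ms.group, "n": ms.n, "k": ms.k,
                "frequency": ms.frequency, "p_superior": ms.p_superior,
                "p_inferior": ms.p_inferior,
                "sig_superior": ms.p_superior < threshold,
                "sig_inferior": ms.p_inferior < threshold,
            })
    columns = ["marker", "group", "n", "k", "frequency", "p_superior",
               "p_inferior", "sig_superior", "sig_inferior"]
    return pd.DataFrame(rows, columns=columns)


def reciprocal_overlap(a: QtlRegion, b: QtlRegion) -> float:
    """Overlap as a fraction of the *longer* interval (0 if disjoint or on
    different chromosomes); >= f means each interval is covered >= f."""
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return inter / max(a.length, b.length)


def _overlaps(a: QtlRegion, b: QtlRegion) -> bool:
    return a.chrom == b.chrom and min(a.end, b.end) >= max(a.start, b.start)


def _support_overlap(a: QtlRegion, b: QtlRegion) -> float:
    """Overlap as a fraction of the *shorter* interval.

    Pools of inbred segregants call systematically narrower intervals than
    F1 pools around the same locus (recombination accumulation shrinks the
    linked block), so concordance support is containment-tolerant: a short
    interval nested in a long one counts as full support.
    """
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a.length, b.length)


def concordance_filter(region_sets_selected: Sequence[Sequence[QtlRegion]],
                       region_set_unselected: Sequence[QtlRegion],
                       min_pools: int = 2, overlap: float = 0.25) -> list[QtlRegion]:
    """Keep regions that replicate across independent selected pools and do
    not appear in the unselected control pool.

    A region is validated iff concordant-direction regions in at least
    ``min_pools`` selected sets support it — support meaning the overlap
    covers >= ``overlap`` of the shorter of the two intervals (see
    ``_support_overlap``: advanced-generation pools call narrower intervals
    around the same locus) — and no same-direction region of the unselected
    set touches it.  The reported interval is the intersection of the
    supporting intervals; a support group is reported once.
    """
    if min_pools > len(region_sets_selected):
        raise ValueError(f"min_pools={min_pools} exceeds the {len(region_sets_selected)} selected sets")
    if min_pools < 1:
        raise ValueError("min_pools must be >= 1")
    validated: list[QtlRegion] = []
    seen: set[tuple] = set()
    for region_set in region_sets_selected:
        for region in region_set:
            supporters: list[QtlRegion] = []
            n_support = 0
            for other_set in region_sets_selected:
                best = None
                for other in other_set:
                    if other.direction != region.direction:
                        continue
                    frac = _support_overlap(region, other)
                    if frac >= overlap and (best is None or frac > _support_overlap(region, best)):
                        best = other
                if best is not None:
                    n_support += 1
                    supporters.append(best)
            if n_support < min_pools:
                continue
            if any(_overlaps(region, u) for u in region_set_unselected
                   if u.direction == region.direction):
                continue
            start = max(s.start for s in supporters)
            end = min(s.end for s in supporters)
            key = (region.chrom, start, end, region.direction)
            if key in seen or start > end:
                continue
            seen.add(key)
            validated.append(QtlRegion(
                chrom=region.chrom, start=start, end=end, direction=region.direction,
                mean_posterior=float(np.mean([s.mean_posterior for s in supporters])),
                n_markers=min(s.n_markers for s in supporters),
                pool_id="+".join(s.pool_id for s in supporters if s.pool_id) or region.pool_id,
            ))
    validated.sort(key=lambda r: (r.chrom, r.start, r.end, r.direction))
    return validated
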
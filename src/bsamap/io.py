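"""Readers and writers for the pipeline's tabular formats.

All formats are plain text: TSV for marker maps, genotype matrices,
phenotypes, pool counts, smoothed tracks and marker scores; BED (0-based,
half-open) and TSV (1-based, inclusive) for candidate regions; and a
minimal VCF dialect for pool counts with one sample per pool and the
superior/inferior read counts in the AD field.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .poolseq import PoolCounts, VariantFrequencyTrack
from .qtl_map import QtlRegion, SmoothedTrack
from .sim_cross import SnpMap

__all__ = [
    "write_snp_map", "read_snp_map",
    "write_genotypes", "read_genotypes",
    "write_phenotypes", "read_phenotypes",
    "write_counts_tsv", "read_counts_tsv",
    "write_counts_vcf", "read_counts_vcf",
    "write_regions_tsv", "read_regions_tsv", "write_regions_bed",
    "write_smoothed_tsv", "write_marker_scores",
]


# -- SNP map ----------------------------------------------------------------

def write_snp_map(snp_map: SnpMap, path: str) -> None:
    """TSV with columns chrom, pos, superior_allele, inferior_allele and
    per-chromosome physical/genetic lengths in ``##chromosome`` headers."""
    with open(path, "w") as fh:
        for i, c in enumerate(snp_map.chromosomes):
            fh.write(f"##chromosome\t{int(c)}\t{int(snp_map.chrom_lengths[i])}\t"
                     f"{float(snp_map.map_lengths[i])!r}\n")
        fh.write("chrom\tpos\tsuperior_allele\tinferior_allele\n")
        for c, p, a, b in zip(snp_map.chrom, snp_map.pos,
                              snp_map.superior_allele, snp_map.inferior_allele):
            fh.write(f"{c}\t{p}\t{a}\t{b}\n")


def read_snp_map(path: str) -> SnpMap:
    lengths: dict[int, int] = {}
    morgans: dict[int, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("##chromosome"):
            _, c, ln, m = line.rstrip("\n").split("\t")
            lengths[int(c)] = int(ln)
            morgans[int(c)] = float(m)
            body_start = i + 1
        else:
            break
    from io import StringIO
    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    chroms = sorted(lengths)
    return SnpMap(
        chrom=df["chrom"].to_numpy(),
        pos=df["pos"].to_numpy(),
        superior_allele=df["superior_allele"].to_numpy(dtype=object),
        inferior_allele=df["inferior_allele"].to_numpy(dtype=object),
        chrom_lengths=np.array([lengths[c] for c in chroms]),
        map_lengths=np.array([morgans[c] for c in chroms]),
    )


# -- genotypes & phenotypes -------------------------------------------------

def write_genotypes(genotypes: pd.DataFrame, path: str) -> None:
    genotypes.to_csv(path, sep="\t", index_label="strain")


def read_genotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="strain")
    df.columns = [int(c) for c in df.columns]
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path: str) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- pool counts ------------------------------------------------------------

def write_counts_tsv(counts: PoolCounts, path: str) -> None:
    pd.DataFrame({
        "chrom": counts.chrom, "pos": counts.pos,
        "superior_count": counts.k, "total_count": counts.n,
        "pool_id": counts.pool_id,
    }).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str) -> PoolCounts:
    df = pd.read_csv(path, sep="\t")
    pool_ids = df["pool_id"].unique()
    if len(pool_ids) != 1:
        raise ValueError(f"count table must hold exactly one pool; found {list(pool_ids)}")
    return PoolCounts(pool_id=str(pool_ids[0]), chrom=df["chrom"].to_numpy(),
                      pos=df["pos"].to_numpy(), k=df["superior_count"].to_numpy(),
                      n=df["total_count"].to_numpy())


def write_counts_vcf(counts: PoolCounts, path: str, snp_map: SnpMap | None = None) -> None:
    """Minimal VCF: REF = superior allele, ALT = inferior allele (N/N when
    no map is given), one sample named after the pool, counts in AD as
    (superior, inferior)."""
    chroms, idx = np.unique(counts.chrom, return_index=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsamap\n")
        for c in chroms[np.argsort(idx)]:
            length = snp_map.length_of(int(c)) if snp_map is not None else int(
                counts.pos[counts.chrom == c].max())
            fh.write(f"##contig=<ID={int(c)},length={length}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Read depth per allele (superior,inferior)">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{counts.pool_id}\n")
        for i in range(counts.n_markers):
            if snp_map is not None:
                ref = snp_map.superior_allele[i]
                alt = snp_map.inferior_allele[i]
            else:
                ref, alt = "N", "N"
            fh.write(f"{counts.chrom[i]}\t{counts.pos[i]}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                     f"AD\t{counts.k[i]},{counts.n[i] - counts.k[i]}\n")


def read_counts_vcf(path: str) -> PoolCounts:
    """Read a one-sample VCF with per-allele depths in AD; the first AD
    entry is taken as the superior-parent allele count."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    if len(vcf.samples) != 1:
        raise ValueError(f"expected a single-pool VCF; found samples {vcf.samples}")
    pool_id = vcf.samples[0]
    chrom, pos, k, n = [], [], [], []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks the AD field")
        counts = [int(x) for x in np.ravel(ad) if x >= 0]
        chrom.append(int(rec.CHROM))
        pos.append(rec.POS)
        k.append(counts[0])
        n.append(sum(counts))
    vcf.close()
    return PoolCounts(pool_id=pool_id, chrom=np.array(chrom), pos=np.array(pos),
                      k=np.array(k), n=np.array(n))


# -- regions ----------------------------------------------------------------

def write_regions_tsv(regions: Sequence[QtlRegion], path: str) -> None:
    """1-based inclusive coordinates with direction, posterior support and
    marker count."""
    columns = ["chrom", "start", "end", "direction", "mean_posterior",
               "n_markers", "pool_id"]
    pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end, "direction": r.direction,
        "mean_posterior": r.mean_posterior, "n_markers": r.n_markers, "pool_id": r.pool_id,
    } for r in regions], columns=columns).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path: str) -> list[QtlRegion]:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []
    return [QtlRegion(chrom=int(r.chrom), start=int(r.start), end=int(r.end),
                      direction=str(r.direction), mean_posterior=float(r.mean_posterior),
                      n_markers=int(r.n_markers),
                      pool_id="" if pd.isna(r.pool_id) else str(r.pool_id))
            for r in df.itertuples()]


def write_regions_bed(regions: Sequence[QtlRegion], path: str) -> None:
    """BED export (0-based half-open): start-1, end unchanged."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.direction}|{r.pool_id}" if r.pool_id else r.direction
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{r.mean_posterior:.4f}\n")


# -- tracks and scores ------------------------------------------------------

def write_smoothed_tsv(track: SmoothedTrack, path: str) -> None:
    pd.DataFrame({
        "chrom": track.chrom, "pos": track.pos, "smoothed": track.smoothed,
        "lower": track.lower, "upper": track.upper,
    }).to_csv(path, sep="\t", index=False)


def write_marker_scores(scores: pd.DataFrame, path: str) -> None:
    scores.to_csv(path, sep="\t", index=False)
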
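"""End-to-end in-silico pooled-segregant experiment.

Reproduces the study design: screen an initial batch of F1 segregants for
low glycerol / high ethanol yield, screen an additional F1 batch, inbreed
the F1 population for several rounds and screen the resulting advanced
(F5) segregants, sequence the selected pools and an unselected control
pool, map candidate linked regions per pool with the binomial-emission
HMM, validate them by multi-pool concordance and per-marker binomial
tests, and summarise causative-allele combinations among all selected
segregants.

Every stage derives its random stream deterministically from the single
experiment seed, so re-running a configuration reproduces the run bit for
bit; the provenance manifest records the configuration hash and per-stage
seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as bio
from .allele_analysis import BinnedFrequency, binned_allele_frequency, group_by_combination, potency_order
from .phenotyping import select_superior
from .poolseq import Pool, PoolCounts, VariantFrequencyTrack, build_pool, sample_read_counts, variant_frequency
from .qtl_map import HmmParams, QtlRegion, SmoothedTrack, call_regions, hmm_posteriors, smooth_track
from .sim_cross import (EpistasisMask, SegregantGenome, SnpMap, TraitModel, assign_phenotypes,
                        default_trait_model, genotype_frame, inbreed,
                        simulate_f1_population, simulate_parental_genomes)
from .validation import concordance_filter, evaluate_groups

__all__ = ["ExperimentConfig", "ExperimentBundle", "ScreenResult", "simulate_screen",
           "run_experiment"]

logger = logging.getLogger("bsamap")


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of the in-silico experiment, validated up front.

    The defaults are the study conditions: a 16-chromosome yeast-scale map
    with 5,600 informative markers, screens of 260 + 400 F1 segregants and
    400 advanced segregants after four inbreeding rounds, selected pools of
    22/22/26 plus an unselected pool of 22, and 100x pooled sequencing.
    """

    n_chromosomes: int = 16
    markers_per_chromosome: int = 350
    chrom_length: int = 750_000
    map_length: float = 2.7
    trait: Any = "default"          # "default" or a mapping (see trait_model())
    n_f1_initial: int = 260
    n_f1_additional: int = 400
    inbreeding_rounds: int = 4
    n_f5_screen: int = 400
    pool_size_f1: int = 22
    pool_size_f5: int = 26
    unselected_pool_size: int = 22
    mean_depth: float = 100.0
    error_rate: float = 0.002
    glycerol_max: float = 120.0
    ethanol_min: float = 99.0
    hmm: HmmParams = field(default_factory=HmmParams)
    bandwidth: float = 30_000.0
    min_pools: int = 2
    overlap: float = 0.25
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chromosomes, self.markers_per_chromosome, self.chrom_length) < 1:
            raise ValueError("map sizes must be >= 1")
        if min(self.n_f1_initial, self.n_f1_additional, self.n_f5_screen) < 2:
            raise ValueError("screen sizes must be >= 2")
        if self.inbreeding_rounds < 0:
            raise ValueError("inbreeding rounds must be >= 0")
        if min(self.pool_size_f1, self.pool_size_f5, self.unselected_pool_size) < 1:
            raise ValueError("pool sizes must be >= 1")
        if self.mean_depth <= 0 or not 0 <= self.error_rate < 0.5:
            raise ValueError("invalid sequencing parameters")
        if self.bandwidth <= 0 or self.overlap <= 0 or not 0 < self.alpha < 1:
            raise ValueError("invalid mapping/validation parameters")
        if self.min_pools < 1:
            raise ValueError("min_pools must be >= 1")

    def trait_model(self, snp_map: SnpMap) -> TraitModel:
        if self.trait in ("default", None):
            return default_trait_model(snp_map)
        if isinstance(self.trait, TraitModel):
            return self.trait
        if isinstance(self.trait, Mapping):
            spec = dict(self.trait)
            masks = {}
            for locus, m in (spec.pop("masks", {}) or {}).items():
                masks[int(locus)] = EpistasisMask(suppressors=tuple(m["suppressors"]),
                                                  rule=m.get("rule", "any"))
            return TraitModel(
                causal_loci=tuple(spec.pop("causal_loci", ())),
                effects=tuple(spec.pop("effects", ())),
                masks=masks,
                background_loci=tuple(spec.pop("background_loci", ())),
                background_effects=tuple(spec.pop("background_effects", ())),
                **spec,
            )
        raise ValueError(f"cannot interpret trait specification: {self.trait!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.trait, TraitModel):
            t = dataclasses.asdict(self.trait)
            t["masks"] = {str(k): {"suppressors": list(v.suppressors), "rule": v.rule}
                          for k, v in self.trait.masks.items()}
            d["trait"] = t
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        hmm_raw = raw.pop("hmm", None)
        hmm = HmmParams(**{**hmm_raw, "priors": tuple(hmm_raw.get("priors", (0.98, 0.01, 0.01)))}) \
            if hmm_raw else HmmParams()
        return cls(hmm=hmm, **raw)


@dataclass
class ExperimentBundle:
    """All stage outputs of one experiment run plus a provenance manifest."""

    config: ExperimentConfig
    snp_map: SnpMap
    trait_model: TraitModel
    phenotypes: pd.DataFrame                 # all screened segregants, with screen round
    selected: dict[str, pd.DataFrame]        # passers per screen round
    pool_members: dict[str, list[SegregantGenome]]
    pools: dict[str, Pool]
    counts: dict[str, PoolCounts]
    tracks: dict[str, VariantFrequencyTrack]
    smoothed: dict[str, SmoothedTrack]
    regions: dict[str, list[QtlRegion]]
    validated_regions: list[QtlRegion]
    scored_markers: list[int]
    marker_scores: pd.DataFrame | None
    allele_groups: list | None
    binned: BinnedFrequency | None
    potency: list[int] | None
    manifest: dict


def _retest_and_pool(phenotypes: pd.DataFrame, population: Sequence[SegregantGenome],
                     trait_model, size: int, glycerol_max: float, ethanol_min: float,
                     seed: int) -> tuple[list[SegregantGenome], pd.DataFrame]:
    """Cut-off screen, triplicate-mean retest of the passers, re-applied
    cut-offs, and retention of the ``size`` lowest-glycerol confirmed
    segregants.  Returns the pool members and their retest phenotypes (the
    values reported for selected segregants are replicate means)."""
    from .sim_cross import assign_phenotypes

    passers = select_superior(phenotypes, glycerol_max, ethanol_min)
    chosen = set(passers["strain"])
    candidates = [s for s in population if s.strain_id in chosen]
    if not candidates:
        return [], phenotypes.iloc[0:0]
    retest = assign_phenotypes(candidates, trait_model, seed, replicates=3)
    confirmed = select_superior(retest, glycerol_max, ethanol_min)
    confirmed = confirmed.sort_values("glycerol_rel", kind="stable").head(size)
    kept = set(confirmed["strain"])
    members = [s for s in candidates if s.strain_id in kept]
    return members, confirmed.reset_index(drop=True)


@dataclass
class ScreenResult:
    """Outcome of the phenotypic screening stages, before sequencing."""

    phenotypes: pd.DataFrame                  # all screened, with screen round
    selected: dict[str, pd.DataFrame]         # cut-off passers per round
    pool_members: dict[str, list[SegregantGenome]]
    retest: pd.DataFrame                      # triplicate-mean yields of pool members
    populations: dict[str, list[SegregantGenome]]


def simulate_screen(config: ExperimentConfig, snp_map: SnpMap,
                    trait_model: TraitModel, seed: int) -> ScreenResult:
    """Screen F1 and inbred segregant batches and assemble the pools.

    Simulates the initial and additional F1 screens, the inbreeding rounds
    and the advanced-generation screen, applies the yield cut-offs, and
    keeps the configured number of lowest-glycerol passers per pool plus a
    random unselected control pool.
    """
    seeds = [int(c.generate_state(1)[0] % (2 ** 31))
             for c in np.random.SeedSequence(seed).spawn(11)]
    (s_f1a, s_ph_a, s_f1b, s_ph_b, s_inbr, s_ph_f5, s_uns,
     s_rt_a, s_rt_b, s_rt_f5, _spare) = seeds

    f1_initial = simulate_f1_population(snp_map, config.n_f1_initial, s_f1a, "F1a")
    pheno_a = assign_phenotypes(f1_initial, trait_model, s_ph_a)
    pheno_a["screen"] = "F1-initial"

    f1_additional = simulate_f1_population(snp_map, config.n_f1_additional, s_f1b, "F1b")
    pheno_b = assign_phenotypes(f1_additional, trait_model, s_ph_b)
    pheno_b["screen"] = "F1-additional"

    rng_inbreed = np.random.default_rng(s_inbr)
    f5_pop = inbreed(f1_initial + f1_additional, config.inbreeding_rounds, snp_map, rng_inbreed)
    f5_idx = rng_inbreed.choice(len(f5_pop), size=min(config.n_f5_screen, len(f5_pop)),
                                replace=False)
    f5_screened = [f5_pop[i] for i in sorted(f5_idx)]
    pheno_f5 = assign_phenotypes(f5_screened, trait_model, s_ph_f5)
    pheno_f5["screen"] = "F5"

    selected = {
        "F1-initial": select_superior(pheno_a, config.glycerol_max, config.ethanol_min),
        "F1-additional": select_superior(pheno_b, config.glycerol_max, config.ethanol_min),
        "F5": select_superior(pheno_f5, config.glycerol_max, config.ethanol_min),
    }
    members_a, retest_a = _retest_and_pool(pheno_a, f1_initial, trait_model,
                                           config.pool_size_f1, config.glycerol_max,
                                           config.ethanol_min, s_rt_a)
    members_b, retest_b = _retest_and_pool(pheno_b, f1_additional, trait_model,
                                           config.pool_size_f1, config.glycerol_max,
                                           config.ethanol_min, s_rt_b)
    members_f5, retest_f5 = _retest_and_pool(pheno_f5, f5_screened, trait_model,
                                             config.pool_size_f5, config.glycerol_max,
                                             config.ethanol_min, s_rt_f5)
    pool_members = {
        "selected_f1_a": members_a,
        "selected_f1_b": members_b,
        "selected_f5": members_f5,
    }
    rng_uns = np.random.default_rng(s_uns)
    uns_idx = rng_uns.choice(len(f1_initial), size=min(config.unselected_pool_size,
                                                       len(f1_initial)), replace=False)
    pool_members["unselected"] = [f1_initial[i] for i in sorted(uns_idx)]
    return ScreenResult(
        phenotypes=pd.concat([pheno_a, pheno_b, pheno_f5], ignore_index=True),
        selected=selected,
        pool_members=pool_members,
        retest=pd.concat([retest_a, retest_b, retest_f5], ignore_index=True),
        populations={"F1-initial": f1_initial, "F1-additional": f1_additional,
                     "F5": f5_screened},
    )


def _peak_marker(region: QtlRegion, snp_map: SnpMap) -> int:
    sl = snp_map.chromosome_slices()[region.chrom]
    pos = snp_map.pos[sl]
    mid = (region.start + region.end) / 2
    return sl.start + int(np.argmin(np.abs(pos - mid)))


def run_experiment(config: ExperimentConfig, output_dir: str | None = None) -> ExperimentBundle:
    """Run the full pipeline; optionally write all outputs to a directory."""
    stage_seeds = {name: int(child.generate_state(1)[0] % (2 ** 31))
                   for name, child in zip(["map", "screen", "sequencing"],
                                          np.random.SeedSequence(config.seed).spawn(3))}

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %-22s %6.2fs", name, time.perf_counter() - t0)
        return result

    snp_map = stage("simulate_map", simulate_parental_genomes,
                    config.n_chromosomes, config.markers_per_chromosome,
                    config.chrom_length, config.map_length, stage_seeds["map"])
    trait_model = stage("trait_model", config.trait_model, snp_map)
    screen = stage("screen", simulate_screen, config, snp_map, trait_model,
                   stage_seeds["screen"])
    phenotypes = screen.phenotypes
    selected = screen.selected
    pool_members = screen.pool_members

    for name in ("selected_f1_a", "selected_f1_b", "selected_f5"):
        if len(pool_members[name]) == 0:
            raise RuntimeError(f"stage 'pooling' failed: screen produced no passers for {name}")

    pools, counts, tracks, smoothed, regions = {}, {}, {}, {}, {}
    seq_ss = np.random.SeedSequence(stage_seeds["sequencing"])
    for child, (name, members) in zip(seq_ss.spawn(len(pool_members)), pool_members.items()):
        pool = build_pool(members, pool_id=name, selected=(name != "unselected"))
        cnt = stage(f"sequence[{name}]", sample_read_counts, pool, snp_map,
                    config.mean_depth, config.error_rate, np.random.default_rng(child))
        track = variant_frequency(cnt)
        pools[name], counts[name], tracks[name] = pool, cnt, track
        smoothed[name] = stage(f"smooth[{name}]", smooth_track, track, config.bandwidth)
        post = stage(f"hmm[{name}]", hmm_posteriors, cnt, config.hmm)
        regions[name] = stage(f"regions[{name}]", call_regions, post, cnt, config.hmm)

    validated = stage("concordance", concordance_filter,
                      [regions["selected_f1_a"], regions["selected_f1_b"], regions["selected_f5"]],
                      regions["unselected"], config.min_pools, config.overlap)

    # per-marker validation in individual segregants, at candidate peaks
    candidate_regions = validated or [r for name in
                                      ("selected_f1_a", "selected_f1_b", "selected_f5")
                                      for r in regions[name]]
    scored_markers = sorted({_peak_marker(r, snp_map) for r in candidate_regions})
    members_a = pool_members["selected_f1_a"]
    members_b = pool_members["selected_f1_b"]
    members_f5 = pool_members["selected_f5"]
    all70 = members_a + members_b + members_f5
    marker_scores = None
    groups = None
    if scored_markers and all70:
        genotypes = genotype_frame(all70, scored_markers)
        groups = {
            f"F1-sequenced-{len(members_a)}": [s.strain_id for s in members_a],
            f"F1-additional-{len(members_b)}": [s.strain_id for s in members_b],
            f"F1-all-{len(members_a) + len(members_b)}":
                [s.strain_id for s in members_a + members_b],
            f"F5-{len(members_f5)}": [s.strain_id for s in members_f5],
            f"all-{len(all70)}": [s.strain_id for s in all70],
        }
        marker_scores = stage("marker_scores", evaluate_groups, genotypes,
                              scored_markers, groups, config.alpha)

    # allele-combination analysis over all selected segregants
    allele_groups = binned = potency = None
    superior_peaks = sorted({_peak_marker(r, snp_map) for r in candidate_regions
                             if r.direction == "superior"})
    if superior_peaks and all70:
        geno70 = genotype_frame(all70, superior_peaks)
        ids70 = {s.strain_id for s in all70}
        pheno70 = screen.retest[screen.retest["strain"].isin(ids70)]
        allele_groups = stage("allele_groups", group_by_combination, geno70, pheno70,
                              superior_peaks)
        binned = stage("binned_frequency", binned_allele_frequency, geno70, pheno70,
                       superior_peaks)
        try:
            potency = potency_order(binned)
        except ValueError:
            potency = None   # lowest bin unoccupied in this run

    manifest = {
        "package": "bsamap",
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "n_markers": snp_map.n_markers,
        "n_screened": {k: int((phenotypes["screen"] == k).sum())
                       for k in ("F1-initial", "F1-additional", "F5")},
        "n_selected": {k: int(len(v)) for k, v in selected.items()},
        "pool_sizes": {k: len(v) for k, v in pool_members.items()},
        "n_candidate_regions": {k: len(v) for k, v in regions.items()},
        "n_validated_regions": len(validated),
        "scored_markers": scored_markers,
        "hmm_substitute_note": ("linked regions called by bsamap's documented 3-state "
                                "binomial-emission HMM"),
    }

    bundle = ExperimentBundle(
        config=config, snp_map=snp_map, trait_model=trait_model, phenotypes=phenotypes,
        selected=selected, pool_members=pool_members, pools=pools, counts=counts,
        tracks=tracks, smoothed=smoothed, regions=regions, validated_regions=validated,
        scored_markers=scored_markers, marker_scores=marker_scores,
        allele_groups=allele_groups, binned=binned, potency=potency, manifest=manifest,
    )
    if output_dir is not None:
        _write_bundle(bundle, output_dir)
    return bundle


def _write_bundle(bundle: ExperimentBundle, output_dir: str) -> None:
    os.makedirs(output_dir, exist_ok=True)
    bio.write_snp_map(bundle.snp_map, os.path.join(output_dir, "snp_map.tsv"))
    bio.write_phenotypes(bundle.phenotypes, os.path.join(output_dir, "phenotypes.tsv"))
    for name, df in bundle.selected.items():
        bio.write_phenotypes(df, os.path.join(output_dir, f"selected_{name}.tsv"))
    for name, cnt in bundle.counts.items():
        bio.write_counts_tsv(cnt, os.path.join(output_dir, f"counts_{name}.tsv"))
        bio.write_smoothed_tsv(bundle.smoothed[name],
                               os.path.join(output_dir, f"smoothed_{name}.tsv"))
        bio.write_regions_tsv(bundle.regions[name],
                              os.path.join(output_dir, f"regions_{name}.tsv"))
    bio.write_regions_tsv(bundle.validated_regions,
                          os.path.join(output_dir, "validated_regions.tsv"))
    bio.write_regions_bed(bundle.validated_regions,
                          os.path.join(output_dir, "validated_regions.bed"))
    if bundle.marker_scores is not None:
        bio.write_marker_scores(bundle.marker_scores,
                                os.path.join(output_dir, "marker_scores.tsv"))
    if bundle.allele_groups is not None:
        pd.DataFrame([{
            "combination": "".join(g.combination), "n": g.n,
            "glycerol_mean": g.glycerol_mean, "glycerol_sd": g.glycerol_sd,
            "ethanol_mean": g.ethanol_mean, "ethanol_sd": g.ethanol_sd,
        } for g in bundle.allele_groups]).to_csv(
            os.path.join(output_dir, "allele_groups.tsv"), sep="\t", index=False)
    with open(os.path.join(output_dir, "manifest.json"), "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=str)
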
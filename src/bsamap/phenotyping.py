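"""Fermentation yields, normalisation to the superior reference strain and
phenotypic selection of superior segregants.

Absolute yields are grams of product per gram of glucose consumed,
``Y = c_product_final / (c_glucose_initial - c_glucose_final)``; relative
yields express a strain's absolute yield as a percentage of the reference
strain run in the same fermentation batch (the reference is 100 % by
construction).  The screening cut-offs are strict inequalities: a superior
segregant has glycerol yield < 120 % and ethanol yield > 99 % of the
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FermentationResult",
    "YieldRecord",
    "absolute_yield",
    "relative_yield",
    "yields_from_fermentations",
    "select_superior",
    "phenotype_correlation",
    "screen_rare_segregant",
]

PRODUCTS = ("glycerol", "ethanol")


@dataclass(frozen=True)
class FermentationResult:
    """End-point measurements of one fermentation."""

    strain: str
    c_glucose_initial: float
    c_glucose_final: float
    glycerol_final: float
    ethanol_final: float
    batch: str = "batch1"

    def __post_init__(self):
        if self.c_glucose_final < 0 or self.glycerol_final < 0 or self.ethanol_final < 0:
            raise ValueError("concentrations must be >= 0")
        if self.c_glucose_initial <= self.c_glucose_final:
            raise ValueError(
                f"no glucose consumed by {self.strain}: initial {self.c_glucose_initial} "
                f"<= final {self.c_glucose_final} (failed fermentation)")


@dataclass(frozen=True)
class YieldRecord:
    """Absolute (g/g) and relative (% of reference) yields of one strain."""

    strain: str
    glycerol_abs: float
    ethanol_abs: float
    glycerol_rel: float
    ethanol_rel: float
    generation: str = ""
    batch: str = "batch1"


def absolute_yield(result: FermentationResult, product: str) -> float:
    """Product yield in g per g glucose consumed."""
    if product not in PRODUCTS:
        raise ValueError(f"unknown product {product!r}; expected one of {PRODUCTS}")
    consumed = result.c_glucose_initial - result.c_glucose_final
    if consumed <= 0:
        raise ValueError(f"no glucose consumed by {result.strain}")
    final = result.glycerol_final if product == "glycerol" else result.ethanol_final
    return final / consumed


def relative_yield(segregant_yield: float, reference_yield: float) -> float:
    """Yield as a percentage of the reference strain (reference = 100)."""
    if reference_yield <= 0:
        raise ValueError("reference yield must be positive")
    return 100.0 * segregant_yield / reference_yield


def yields_from_fermentations(fermentations: pd.DataFrame, reference: str,
                              batch_column: str = "batch") -> pd.DataFrame:
    """Per-strain yields from a fermentation table.

    ``fermentations`` needs columns ``strain, c_glucose_initial,
    c_glucose_final, glycerol_final, ethanol_final`` and optionally a batch
    column (defaulting to a single batch); replicate rows of a strain are
    averaged (arithmetic mean of replicate yields).  Relative yields are
    computed against the reference strain's mean yields *within the same
    batch*, which absorbs between-batch variance.
    """
    df = fermentations.copy()
    if batch_column not in df.columns:
        df[batch_column] = "batch1"
    required = {"strain", "c_glucose_initial", "c_glucose_final", "glycerol_final", "ethanol_final"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fermentation table lacks columns: {sorted(missing)}")

    def _yields(row):
        res = FermentationResult(
            strain=row["strain"],
            c_glucose_initial=row["c_glucose_initial"],
            c_glucose_final=row["c_glucose_final"],
            glycerol_final=row["glycerol_final"],
            ethanol_final=row["ethanol_final"],
            batch=row[batch_column],
        )
        return pd.Series({
            "glycerol_abs": absolute_yield(res, "glycerol"),
            "ethanol_abs": absolute_yield(res, "ethanol"),
        })

    df[["glycerol_abs", "ethanol_abs"]] = df.apply(_yields, axis=1)
    per_strain = (df.groupby([batch_column, "strain"], sort=False)[["glycerol_abs", "ethanol_abs"]]
                    .mean().reset_index())
    out = []
    for batch, grp in per_strain.groupby(batch_column, sort=False):
        ref = grp[grp["strain"] == reference]
        if ref.empty:
            raise ValueError(f"reference strain {reference!r} missing from batch {batch!r}")
        ref_g = float(ref["glycerol_abs"].iloc[0])
        ref_e = float(ref["ethanol_abs"].iloc[0])
        grp = grp.copy()
        grp["glycerol_rel"] = [relative_yield(y, ref_g) for y in grp["glycerol_abs"]]
        grp["ethanol_rel"] = [relative_yield(y, ref_e) for y in grp["ethanol_abs"]]
        out.append(grp)
    result = pd.concat(out, ignore_index=True)
    return result[["strain", batch_column, "glycerol_abs", "ethanol_abs",
                   "glycerol_rel", "ethanol_rel"]].rename(columns={batch_column: "batch"})


def select_superior(records: pd.DataFrame, glycerol_max: float = 120.0,
                    ethanol_min: float = 99.0) -> pd.DataFrame:
    """Superior segregants: glycerol % strictly below ``glycerol_max`` AND
    ethanol % strictly above ``ethanol_min``.

    Records with a missing yield are rejected with a warning rather than
    silently dropped; row order is preserved.
    """
    if records.empty:
        return records.copy()
    for col in ("glycerol_rel", "ethanol_rel"):
        if col not in records.columns:
            raise ValueError(f"records lack column {col!r}")
    incomplete = records["glycerol_rel"].isna() | records["ethanol_rel"].isna()
    if incomplete.any():
        bad = records.loc[incomplete, "strain"].tolist() if "strain" in records.columns \
            else records.index[incomplete].tolist()
        warnings.warn(f"rejecting {int(incomplete.sum())} record(s) with missing yields: {bad}",
                      stacklevel=2)
    keep = (~incomplete) & (records["glycerol_rel"] < glycerol_max) \
        & (records["ethanol_rel"] > ethanol_min)
    return records.loc[keep].copy()


def phenotype_correlation(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between relative glycerol and
    ethanol yields; an inverse correlation gives r < 0."""
    g = np.asarray(records["glycerol_rel"], dtype=float)
    e = np.asarray(records["ethanol_rel"], dtype=float)
    if len(g) < 3:
        raise ValueError("correlation needs at least 3 records")
    if np.std(g) == 0 or np.std(e) == 0:
        raise ValueError("correlation undefined: zero variance in a yield")
    r, p = stats.pearsonr(g, e)
    return float(r), float(p)


def screen_rare_segregant(selected_records: pd.DataFrame, genotypes: pd.DataFrame,
                          major_locus: int) -> pd.DataFrame:
    """Superior-phenotype segregants that *lack* the superior allele at the
    major locus — the rare recombinants that allow minor loci to be
    re-segregated in a backcross.
    """
    if major_locus not in genotypes.columns:
        raise ValueError(f"locus {major_locus} not in the genotype table")
    strains = selected_records["strain"]
    missing = [s for s in strains if s not in genotypes.index]
    if missing:
        raise ValueError(f"no genotype for strains: {missing}")
    calls = genotypes.loc[strains, major_locus]
    keep = (calls != "S").to_numpy()
    return selected_records.loc[keep].copy()
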
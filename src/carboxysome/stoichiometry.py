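"""QconCAT absolute-quantification arithmetic for the intact carboxysome.

Peptide light/heavy area ratios against a spiked, isotope-labelled
standard give per-protein molar amounts; anchoring to the cryoET-derived
Rubisco content (RbcL, 639 complexes x 8 = 5112 monomers) converts these
to copies per carboxysome; oligomer specifications then yield functional
units, per-protein mass and the total particle molecular weight.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR = "RbcL"
#: 639 Rubisco L8S8 complexes x 8 RbcL monomers each
DEFAULT_ANCHOR_MONOMERS = 5112.0
#: peptides of one protein disagreeing by more than this are flagged
PEPTIDE_DISAGREEMENT_FOLD = 4.0
#: label of Q-peptides shared by both CcmM isoforms (total CcmM)
CCMM_SHARED = "CcmM35/58"


def reference_composition() -> pd.DataFrame:
    """The reference carboxysome composition table (13 proteins).

    Columns: category, protein, structure, monomers_per_unit,
    monomer_mw_kda, monomer_copies, monomer_copies_sd.
    """
    with resources.files(__package__).joinpath(
            "data/reference_composition.csv").open() as fh:
        return pd.read_csv(fh)


def oligomer_specs(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Oligomer spec (protein, monomers_per_unit, monomer_mw_kda)."""
    table = reference_composition() if table is None else table
    return table[["protein", "monomers_per_unit", "monomer_mw_kda"]].copy()


def protein_amounts(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-protein, per-replicate molar amounts (pmol).

    Each peptide row yields ``(light_area / heavy_area) * spike_pmol``;
    a protein's amount in a replicate is the mean over its peptides.
    Rows with non-positive heavy area are rejected with a warning; a
    protein whose every row is rejected is an error. Peptides of one
    protein disagreeing by more than 4-fold are flagged but kept.
    """
    required = {"protein", "peptide", "replicate", "light_area",
                "heavy_area", "spike_pmol"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: "
                         f"{sorted(missing)}")
    proteins = measurements["protein"].unique()
    bad = measurements["heavy_area"] <= 0
    if bad.any():
        for idx in measurements.index[bad]:
            row = measurements.loc[idx]
            logger.warning("rejecting row %s (%s/%s/%s): heavy_area <= 0",
                           idx, row["protein"], row["peptide"],
                           row["replicate"])
        measurements = measurements[~bad]
    lost = set(proteins) - set(measurements["protein"].unique())
    if lost:
        raise ValueError(
            f"all measurements rejected for protein(s): {sorted(lost)}")

    df = measurements.copy()
    df["pmol"] = (df["light_area"].clip(lower=0) / df["heavy_area"]
                  * df["spike_pmol"])

    per_pep = (df.groupby(["protein", "peptide"])["pmol"].mean())
    for protein, grp in per_pep.groupby(level="protein"):
        lo, hi = grp.min(), grp.max()
        if lo > 0 and hi / lo > PEPTIDE_DISAGREEMENT_FOLD:
            logger.warning("peptides of %s disagree %.1f-fold: %s",
                           protein, hi / lo, dict(grp.droplevel(0)))

    amounts = (df.groupby(["protein", "replicate"])["pmol"].mean()
               .unstack("replicate"))
    amounts.columns.name = None
    return amounts


def copies_per_carboxysome(amounts: pd.DataFrame,
                           anchor: str = DEFAULT_ANCHOR,
                           anchor_monomers: float = DEFAULT_ANCHOR_MONOMERS,
                           ) -> pd.DataFrame:
    """Monomer copies per carboxysome via anchor normalization.

    ``copies_i(rep) = amount_i(rep) / amount_anchor(rep) * anchor_monomers``.
    Returns per-replicate copies plus ``monomer_copies`` (mean) and
    ``monomer_copies_sd`` (SD over replicates); the anchor's mean is
    exactly ``anchor_monomers`` with SD 0.
    """
    if anchor not in amounts.index:
        raise ValueError(f"anchor protein {anchor!r} not quantified")
    ref = amounts.loc[anchor]
    if not (ref > 0).all():
        raise ValueError(
            f"anchor protein {anchor!r} must have a positive amount "
            "in every replicate")
    copies = amounts.div(ref, axis=1) * anchor_monomers
    out = copies.copy()
    out["monomer_copies"] = copies.mean(axis=1)
    out["monomer_copies_sd"] = copies.std(axis=1, ddof=1).fillna(0.0)
    out.loc[anchor, "monomer_copies"] = anchor_monomers
    out.loc[anchor, "monomer_copies_sd"] = 0.0
    return out


def resolve_ccmm(copies: pd.DataFrame, shared: str = CCMM_SHARED,
                 long_isoform: str = "CcmM58",
                 short_isoform: str = "CcmM35") -> pd.DataFrame:
    """Split total-CcmM quantification into its isoforms.

    Q-peptides from the region shared by CcmM35 and CcmM58 measure total
    CcmM; when such a row is present the short isoform is obtained by
    subtraction (floored at zero) and the shared row is dropped.
    """
    if shared not in copies.index:
        return copies
    if long_isoform not in copies.index:
        raise ValueError(
            f"{shared!r} present but {long_isoform!r} not quantified")
    out = copies.copy()
    diff = (out.loc[shared] - out.loc[long_isoform]).clip(lower=0.0)
    out.loc[short_isoform] = diff
    out = out.drop(index=shared)
    rep_cols = [c for c in out.columns
                if c not in ("monomer_copies", "monomer_copies_sd")]
    out.loc[short_isoform, "monomer_copies"] = \
        out.loc[short_isoform, rep_cols].mean()
    sd = out.loc[short_isoform, rep_cols].std(ddof=1)
    out.loc[short_isoform, "monomer_copies_sd"] = 0.0 if pd.isna(sd) else sd
    return out


def to_functional_units(monomer_copies: float,
                        monomers_per_unit: int) -> int:
    """Functional oligomer count: nearest integer, exact halves DOWN.

    11853 CcmK2 monomers / 6 = 1975.5 -> 1975 hexamers; 7 RbcX / 2 = 3.5
    -> 3 dimers; 29 CcmL / 5 = 5.8 -> 6 pentamers. Values are rounded to
    6 decimals first so floating-point dust cannot flip an exact half.
    """
    if monomer_copies < 0:
        raise ValueError("monomer_copies must be >= 0")
    if monomers_per_unit < 1:
        raise ValueError("monomers_per_unit must be >= 1")
    x = round(monomer_copies / monomers_per_unit, 6)
    return int(np.ceil(x - 0.5))


def mass_summary(copies: pd.DataFrame, specs: pd.DataFrame) -> pd.DataFrame:
    """Per-protein mass (MDa), mass fractions (%) and totals.

    ``copies`` needs a ``monomer_copies`` column indexed by protein;
    ``specs`` maps protein -> monomers_per_unit, monomer_mw_kda. A
    quantified protein without a spec is an error.
    """
    specs = specs.set_index("protein") if "protein" in specs.columns \
        else specs
    missing = [p for p in copies.index if p not in specs.index]
    if missing:
        raise ValueError(f"no oligomer spec for: {missing}")
    out = copies.copy()
    out["monomer_mw_kda"] = specs.loc[out.index, "monomer_mw_kda"]
    out["monomers_per_unit"] = specs.loc[out.index, "monomers_per_unit"]
    out["protein_mass_MDa"] = (out["monomer_copies"]
                               * out["monomer_mw_kda"] / 1000.0)
    total = out["protein_mass_MDa"].sum()
    out["mass_fraction_pct"] = (
        out["protein_mass_MDa"] / total * 100.0 if total > 0 else np.nan)
    out.attrs["total_mass_MDa"] = float(total)
    return out


def build_table1_report(measurements: pd.DataFrame,
                        specs: pd.DataFrame | None = None,
                        anchor: str = DEFAULT_ANCHOR,
                        anchor_monomers: float = DEFAULT_ANCHOR_MONOMERS,
                        ) -> pd.DataFrame:
    """Full stoichiometry table from a peptide measurement table.

    One row per protein: monomer mean +/- SD, functional-unit count
    (+/- SD), mass fraction; the total particle mass (MDa) is stored in
    ``.attrs["total_mass_MDa"]``.
    """
    specs = oligomer_specs() if specs is None else specs
    amounts = protein_amounts(measurements)
    copies = copies_per_carboxysome(amounts, anchor, anchor_monomers)
    copies = resolve_ccmm(copies)
    summary = mass_summary(
        copies[["monomer_copies", "monomer_copies_sd"]], specs)
    summary["unit_copies"] = [
        to_functional_units(c, int(u)) for c, u in
        zip(summary["monomer_copies"], summary["monomers_per_unit"])]
    summary["unit_copies_sd"] = (summary["monomer_copies_sd"]
                                 / summary["monomers_per_unit"])
    report = summary[["monomer_mw_kda", "mass_fraction_pct",
                      "monomer_copies", "monomer_copies_sd",
                      "unit_copies", "unit_copies_sd",
                      "monomers_per_unit", "protein_mass_MDa"]].copy()
    report = report.sort_values("protein_mass_MDa", ascending=False)
    report.attrs["total_mass_MDa"] = summary.attrs["total_mass_MDa"]
    report.attrs["anchor"] = anchor
    report.attrs["anchor_monomers"] = float(anchor_monomers)
    return report
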
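"""Reduction of peptide evidence to normalized protein abundances.

Steps, in order: technical-injection averaging, fraction-presence peptide
filtering, per-sample total-ion normalization, and median-scaling /
median-averaging aggregation to one abundance per protein per sample.
Missing values are never imputed; they propagate as absent cells.
"""
from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ProteinQuantMatrix(NamedTuple):
    """Protein x sample normalized abundances plus per-cell peptide counts."""

    abundance: pd.DataFrame      # index protein_id, columns sample_id, NaN = missing
    peptide_counts: pd.DataFrame  # same shape, int counts of contributing peptides


class EmptyEvidenceError(ValueError):
    pass


def _check_design(evidence: pd.DataFrame, design: pd.DataFrame) -> None:
    extra = set(evidence["sample_id"]) - set(design["sample_id"])
    if extra:
        raise ValueError(f"evidence contains samples absent from design: {sorted(extra)[:5]}")
    if design["sample_id"].duplicated().any():
        raise ValueError("design sample_id values must be unique")


def average_injections(evidence: pd.DataFrame, design: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-average technical injections into one biological-replicate sample.

    Returns the collapsed evidence and the collapsed design. A no-op when the
    design has no injection column or only single injections.
    """
    if "injection" not in design.columns or design.groupby(
        ["genotype", "fraction", "replicate"]
    ).size().max() <= 1:
        return evidence, design
    _check_design(evidence, design)
    key_cols = ["genotype", "fraction", "replicate"]
    collapsed = design.drop_duplicates(key_cols).copy()
    collapsed["sample_id"] = (
        collapsed["genotype"] + "_" + collapsed["fraction"] + "_r" + collapsed["replicate"].astype(str)
    )
    collapsed = collapsed[["sample_id"] + key_cols]
    mapping = design.merge(collapsed, on=key_cols, suffixes=("", "_new"))
    sid_map = dict(zip(mapping["sample_id"], mapping["sample_id_new"]))
    ev = evidence.copy()
    ev["sample_id"] = ev["sample_id"].map(sid_map)
    ev = (
        ev.groupby(["peptide_id", "protein_id", "sample_id"], as_index=False, sort=False)["intensity"]
        .mean()
    )
    return ev, collapsed.reset_index(drop=True)


def filter_peptides(
    evidence: pd.DataFrame,
    design: pd.DataFrame,
    min_presence: float = 0.70,
    *,
    per_genotype: bool = False,
    require_all_fractions: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the fraction-presence rule to peptides.

    A peptide is retained iff it is quantified in at least ``min_presence`` of
    the samples of at least one fraction (or of every fraction when
    ``require_all_fractions``). With ``per_genotype`` the rule is evaluated
    within each genotype x fraction group instead of pooling genotypes.

    Returns (retained evidence, audit table of removed peptides).
    """
    if evidence.empty:
        audit = pd.DataFrame(columns=["peptide_id", "reason"])
        return evidence.copy(), audit
    _check_design(evidence, design)

    group_cols = ["genotype", "fraction"] if per_genotype else ["fraction"]
    group_sizes = design.groupby(group_cols).size()

    quantified = evidence[evidence["intensity"].notna() & (evidence["intensity"] > 0)]
    merged = quantified.merge(design[["sample_id"] + group_cols], on="sample_id")
    presence = (
        merged.drop_duplicates(["peptide_id", "sample_id"])
        .groupby(["peptide_id"] + group_cols)
        .size()
    )
    frac_presence = presence / group_sizes.reindex(
        presence.index.droplevel("peptide_id")
    ).to_numpy()
    ok = frac_presence >= min_presence
    if require_all_fractions:
        n_groups = len(group_sizes)
        n_ok = ok.groupby(level="peptide_id").sum()
        keep_ids = set(n_ok.index[n_ok == n_groups])
    else:
        keep_ids = set(ok.index.get_level_values("peptide_id")[ok.to_numpy()])

    all_ids = evidence["peptide_id"].unique()
    removed = [p for p in all_ids if p not in keep_ids]
    audit = pd.DataFrame(
        {
            "peptide_id": removed,
            "reason": [
                f"presence < {min_presence:.0%} in "
                + ("some fraction" if require_all_fractions else "every fraction")
            ]
            * len(removed),
        }
    )
    if removed:
        logger.info("filter_peptides removed %d / %d peptides", len(removed), len(all_ids))
    kept = evidence[evidence["peptide_id"].isin(keep_ids)].copy()
    return kept, audit


def normalize_total_ion(evidence: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Express each peptide intensity as a fraction of its sample's total.

    Samples whose intensities are all missing are excluded and reported.
    """
    if evidence.empty:
        raise EmptyEvidenceError("cannot normalize an empty evidence table")
    ev = evidence.copy()
    totals = ev.groupby("sample_id")["intensity"].sum(min_count=1)
    bad = sorted(totals.index[~(totals > 0)].tolist())
    if bad:
        logger.warning("excluding samples with no quantified peptides: %s", bad)
        ev = ev[~ev["sample_id"].isin(bad)]
        totals = totals.drop(bad)
    ev["intensity"] = ev["intensity"] / ev["sample_id"].map(totals)
    return ev, bad


def aggregate_protein(evidence: pd.DataFrame, design: pd.DataFrame) -> ProteinQuantMatrix:
    """Median-scale peptide profiles, then median-average them per protein.

    Each peptide's profile is divided by the median of its quantified values
    across samples; a protein's abundance in a sample is the median of its
    peptides' scaled values there, multiplied by the protein-level median of
    the peptide scales so the result stays in fraction-of-total units.
    """
    _check_design(evidence, design)
    pivot = evidence.pivot_table(
        index=["protein_id", "peptide_id"],
        columns="sample_id",
        values="intensity",
        aggfunc="mean",
    )
    pivot = pivot.reindex(columns=design["sample_id"].to_numpy())
    pep_median = pivot.median(axis=1, skipna=True)
    scaled = pivot.div(pep_median, axis=0)

    protein_scale = pep_median.groupby(level="protein_id").median()
    protein_profiles = scaled.groupby(level="protein_id").median()
    abundance = protein_profiles.mul(protein_scale, axis=0)
    counts = scaled.notna().groupby(level="protein_id").sum().astype(int)
    abundance.columns.name = None
    counts.columns.name = None
    return ProteinQuantMatrix(abundance=abundance, peptide_counts=counts)


def quantify(
    evidence: pd.DataFrame,
    design: pd.DataFrame,
    min_presence: float = 0.70,
    *,
    per_genotype: bool = False,
    require_all_fractions: bool = False,
) -> tuple[ProteinQuantMatrix, pd.DataFrame, pd.DataFrame]:
    """Full evidence -> ProteinQuantMatrix chain.

    Returns (matrix, collapsed design, peptide audit log).
    """
    ev, design = average_injections(evidence, design)
    kept, audit = filter_peptides(
        ev, design, min_presence,
        per_genotype=per_genotype, require_all_fractions=require_all_fractions,
    )
    if kept.empty:
        empty = pd.DataFrame()
        return ProteinQuantMatrix(empty, empty), design, audit
    normed, _ = normalize_total_ion(kept)
    matrix = aggregate_protein(normed, design)
    return matrix, design, audit
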
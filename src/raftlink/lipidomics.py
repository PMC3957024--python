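"""Lipid table normalization, transformation, differential abundance and
targeted peak annotation.

Positive- and negative-mode tables are combined before normalization. The
normalization denominator per sample is the summed intensity of a low-variation
reference set: non-TAG lipids whose CV across all samples is strictly below
the median CV of all lipids (TAG never enters the denominator but is itself
normalized). Downstream, values are z-scaled per lipid, shifted to positive
values and log2 transformed; differential abundance uses Welch t-tests at the
species and class level. Peak annotation matches RT-corrected peaks against a
targeted library at ppm / RT tolerances.
"""
from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import NORMALIZATION_EXCLUDED_CLASSES

logger = logging.getLogger(__name__)

#: metadata columns of a lipid table; all other columns are samples
META_COLUMNS = ("lipid_id", "class", "acyl_carbons", "double_bonds", "hydroxylation", "mode")


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def merge_modes(pos: pd.DataFrame, neg: pd.DataFrame) -> pd.DataFrame:
    """Combine mode-specific tables; species present in both modes stay as
    distinct rows with mode-suffixed ids."""
    if pos.empty:
        return neg.copy()
    if neg.empty:
        return pos.copy()
    shared = set(pos["lipid_id"]) & set(neg["lipid_id"])
    for lid in shared:
        meta_p = pos.loc[pos["lipid_id"] == lid, ["class"]].iloc[0]
        meta_n = neg.loc[neg["lipid_id"] == lid, ["class"]].iloc[0]
        if meta_p["class"] != meta_n["class"]:
            raise ValueError(f"conflicting class metadata for shared lipid {lid!r}")
    pos = pos.copy()
    neg = neg.copy()
    pos.loc[pos["lipid_id"].isin(shared), "lipid_id"] += "[+]"
    neg.loc[neg["lipid_id"].isin(shared), "lipid_id"] += "[-]"
    merged = pd.concat([pos, neg], ignore_index=True)
    return merged


class NormalizationResult(NamedTuple):
    table: pd.DataFrame
    reference_ids: list[str]
    fallback_used: bool


def normalize_lipids(table: pd.DataFrame, *, variation: str = "cv") -> NormalizationResult:
    """Express every lipid as a fraction of a per-sample reference-set total.

    Reference set: non-TAG lipids with variation strictly below the median
    variation of all lipids (variation = CV by default, switchable to SD).
    Variation is measured on provisional fraction-of-total values (denominator
    = all non-TAG lipids) so that selection — and hence the whole operation —
    is invariant to per-sample intensity scaling. An empty reference set falls
    back to all non-TAG lipids with a warning.
    """
    cols = sample_columns(table)
    if len(table) < 2:
        raise ValueError("need at least 2 lipids to normalize")
    X = table[cols].to_numpy(dtype=float)
    non_tag = ~table["class"].isin(NORMALIZATION_EXCLUDED_CLASSES).to_numpy()
    if not non_tag.any():
        raise ValueError("no non-TAG lipids available for normalization")
    provisional_denom = np.nansum(X[non_tag], axis=0)
    if np.any(provisional_denom <= 0):
        raise ValueError("non-positive total intensity in some sample")
    P = X / provisional_denom
    sd = np.nanstd(P, axis=1, ddof=1)
    if variation == "cv":
        with np.errstate(invalid="ignore", divide="ignore"):
            var = sd / np.nanmean(P, axis=1)
    elif variation == "sd":
        var = sd
    else:
        raise ValueError(f"unknown variation measure {variation!r}")
    median_var = np.nanmedian(var)
    ref = non_tag & (var < median_var)
    fallback = False
    if not ref.any():
        logger.warning("empty low-variation reference set; falling back to all non-TAG lipids")
        ref = non_tag
        fallback = True
    if not ref.any():
        raise ValueError("no non-TAG lipids available for normalization")
    denom = np.nansum(X[ref], axis=0)
    if np.any(denom <= 0):
        raise ValueError("non-positive normalization denominator in some sample")
    out = table.copy()
    out[cols] = X / denom
    return NormalizationResult(out, table.loc[ref, "lipid_id"].tolist(), fallback)


class TransformResult(NamedTuple):
    table: pd.DataFrame
    shift: float
    degenerate_ids: list[str]


def transform_lipids(table: pd.DataFrame) -> TransformResult:
    """Per-lipid z-scores, shifted positive by ``|global min| + 1``, log2'd.

    Lipids with zero variance get an all-zero z row and are flagged.
    """
    cols = sample_columns(table)
    X = table[cols].to_numpy(dtype=float)
    mean = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
    degenerate = (sd == 0).ravel() | ~np.isfinite(sd).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[degenerate] = 0.0
    shift = float(abs(np.nanmin(Z)) + 1.0)
    out = table.copy()
    out[cols] = np.log2(Z + shift)
    degenerate_ids = table.loc[degenerate, "lipid_id"].tolist()
    if degenerate_ids:
        logger.warning("zero-variance lipids z-scored to 0: %s", degenerate_ids)
    return TransformResult(out, shift, degenerate_ids)


class DifferentialResult(NamedTuple):
    species: pd.DataFrame
    classes: pd.DataFrame


def _genotype_columns(design: pd.DataFrame, genotype: str, cols: list[str]) -> list[str]:
    sel = design[design["genotype"] == genotype]["sample_id"]
    return [c for c in sel if c in cols]


def differential_lipids(
    normalized: pd.DataFrame,
    transformed: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    *,
    wildtype: str | None = None,
    mutant: str | None = None,
) -> DifferentialResult:
    """Welch t-tests mutant vs wildtype per lipid species and per class.

    P-values come from the transformed values; log2 fold changes from the
    normalized (pre-z) values. Class-level tests run on per-sample class sums
    of normalized values. No multiple-testing correction is applied to the
    significance flag; a Benjamini-Hochberg column is emitted for reference.
    """
    cols = sample_columns(normalized)
    genotypes = list(dict.fromkeys(design["genotype"]))
    if wildtype is None:
        wildtype = genotypes[0]
    if mutant is None:
        others = [g for g in genotypes if g != wildtype]
        if len(others) != 1:
            raise ValueError(f"specify mutant explicitly; design has {others}")
        mutant = others[0]
    wt_cols = _genotype_columns(design, wildtype, cols)
    mut_cols = _genotype_columns(design, mutant, cols)
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("need >=2 replicates per genotype")

    def _test(norm_df: pd.DataFrame, trans_df: pd.DataFrame, id_col: str) -> pd.DataFrame:
        wt_t = trans_df[wt_cols].to_numpy(dtype=float)
        mut_t = trans_df[mut_cols].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(mut_t, wt_t, axis=1, equal_var=False, nan_policy="omit")
            pvals = np.asarray(res.pvalue, dtype=float)
            wt_mean = np.nanmean(norm_df[wt_cols].to_numpy(dtype=float), axis=1)
            mut_mean = np.nanmean(norm_df[mut_cols].to_numpy(dtype=float), axis=1)
            log2_fc = np.log2(mut_mean / wt_mean)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        finite = np.isfinite(pvals)
        bh = np.full(len(pvals), np.nan)
        if finite.any():
            bh[finite] = stats.false_discovery_control(pvals[finite], method="bh")
        return pd.DataFrame(
            {
                id_col: norm_df[id_col].to_numpy(),
                "log2_fc": log2_fc,
                "p_value": pvals,
                "p_bh": bh,
                "significant": pvals < alpha,
                "fold_change_flag": np.abs(log2_fc) > 1.0,
            }
        )

    species = _test(normalized, transformed, "lipid_id")
    species.insert(1, "class", normalized["class"].to_numpy())

    class_sums = normalized.groupby("class")[cols].sum().reset_index()
    # class-level test runs directly on the per-sample class sums
    classes = _test(class_sums.rename(columns={"class": "class_id"}),
                    class_sums.rename(columns={"class": "class_id"}), "class_id")
    return DifferentialResult(species, classes)


# ---------------------------------------------------------------------------
# targeted peak annotation
# ---------------------------------------------------------------------------

def rt_correct(peaks: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Map observed retention times onto the library RT scale.

    Fits a piecewise-linear observed->library mapping through the marker
    pairs; outside the marker range the boundary segments are extended
    linearly. With fewer than 2 markers the identity mapping is used.
    """
    out = peaks.copy()
    if len(markers) < 2:
        logger.warning("fewer than 2 markers; retention times left uncorrected")
        return out
    m = markers.sort_values("observed_rt")
    obs = m["observed_rt"].to_numpy(dtype=float)
    lib = m["library_rt"].to_numpy(dtype=float)
    if np.any(np.diff(obs) <= 0):
        keep = np.concatenate([[True], np.diff(obs) > 0])
        obs, lib = obs[keep], lib[keep]
        if obs.size < 2:
            logger.warning("degenerate marker set; retention times left uncorrected")
            return out
    rt = peaks["rt"].to_numpy(dtype=float)
    corrected = np.interp(rt, obs, lib)
    # linear extension of the boundary segments instead of np.interp's clamp
    left = rt < obs[0]
    right = rt > obs[-1]
    slope_l = (lib[1] - lib[0]) / (obs[1] - obs[0])
    slope_r = (lib[-1] - lib[-2]) / (obs[-1] - obs[-2])
    corrected[left] = lib[0] + slope_l * (rt[left] - obs[0])
    corrected[right] = lib[-1] + slope_r * (rt[right] - obs[-1])
    out["rt"] = corrected
    return out


class MatchResult(NamedTuple):
    matches: pd.DataFrame
    unmatched_peaks: pd.DataFrame
    unmatched_library: pd.DataFrame


def match_library(
    peaks: pd.DataFrame,
    library: pd.DataFrame,
    ppm_tol: float = 5.0,
    rt_tol: float = 0.5,
) -> MatchResult:
    """Annotate peaks against a targeted library.

    A peak matches an entry iff |dm/z|/m/z <= ppm_tol * 1e-6 and
    |dRT| <= rt_tol. Among multiple candidates the nearest by ppm wins, ties
    broken by dRT.
    """
    if peaks.empty or library.empty:
        return MatchResult(
            pd.DataFrame(columns=["peak_id", "name", "ppm_error", "rt_error"]),
            peaks.copy(), library.copy(),
        )
    pmz = peaks["mz"].to_numpy(dtype=float)[:, None]
    prt = peaks["rt"].to_numpy(dtype=float)[:, None]
    lmz = library["mz"].to_numpy(dtype=float)[None, :]
    lrt = library["rt"].to_numpy(dtype=float)[None, :]
    ppm = np.abs(pmz - lmz) / lmz * 1e6
    drt = np.abs(prt - lrt)
    ok = (ppm <= ppm_tol) & (drt <= rt_tol)

    rows = []
    matched_lib = set()
    for i in range(len(peaks)):
        cand = np.flatnonzero(ok[i])
        if cand.size == 0:
            continue
        order = sorted(cand, key=lambda j: (ppm[i, j], drt[i, j]))
        j = order[0]
        matched_lib.add(j)
        rows.append(
            (peaks.iloc[i]["peak_id"] if "peak_id" in peaks.columns else i,
             library.iloc[j]["name"], float(ppm[i, j]), float(drt[i, j]))
        )
    matches = pd.DataFrame(rows, columns=["peak_id", "name", "ppm_error", "rt_error"])
    matched_peak_ids = set(matches["peak_id"])
    if "peak_id" in peaks.columns:
        unmatched_peaks = peaks[~peaks["peak_id"].isin(matched_peak_ids)].copy()
    else:
        unmatched_peaks = peaks[~peaks.index.isin(matched_peak_ids)].copy()
    unmatched_library = library[~library.index.isin(matched_lib)].copy()
    return MatchResult(matches, unmatched_peaks, unmatched_library)
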
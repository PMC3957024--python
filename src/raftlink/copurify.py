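"""Flagging of co-purifying proteins via the SP/IM reference fractions.

A protein is called co-purifying when its highest mean abundance lies in SP
or IM, or when a one-sided Welch t-test finds SP or IM significantly higher
than the best membrane fraction (alpha default 0.01, deliberately without a
multiple-testing correction so the filter stays stringent). Significant
partitioning-shift results for such proteins are moved to an excluded list
rather than dropped.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import FRACTIONS, MEMBRANE_FRACTIONS, REFERENCE_FRACTIONS

logger = logging.getLogger(__name__)


def _fraction_values(abundance, design, fraction, genotype=None):
    sel = design[design["fraction"] == fraction]
    if genotype is not None:
        sel = sel[sel["genotype"] == genotype]
    cols = [c for c in sel["sample_id"] if c in abundance.columns]
    return abundance[cols].to_numpy(dtype=float)


def _welch_greater(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided Welch p-value for mean(a) > mean(b); NaN when untestable."""
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0 if a.mean() > b.mean() else 1.0
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.pvalue)


def flag_copurifying(
    matrix,
    design: pd.DataFrame,
    alpha: float = 0.01,
    *,
    genotype: str | None = None,
) -> pd.DataFrame:
    """Per-protein co-purification calls.

    Pools genotypes by default; pass ``genotype`` to restrict the comparison.
    Proteins with fewer than 2 replicates in a tested fraction are marked
    untestable on the t-test route but still get the highest-mean call.
    """
    abundance = getattr(matrix, "abundance", matrix)
    missing = [f for f in FRACTIONS if design[design["fraction"] == f].empty]
    if missing:
        raise ValueError(f"design lacks fractions {missing}")

    values = {f: _fraction_values(abundance, design, f, genotype) for f in FRACTIONS}
    with np.errstate(invalid="ignore"):
        means = {f: np.nanmean(values[f], axis=1) for f in FRACTIONS}
    mean_mat = np.column_stack([means[f] for f in FRACTIONS])
    top_idx = np.nanargmax(np.where(np.isnan(mean_mat), -np.inf, mean_mat), axis=1)

    rows = []
    for i, pid in enumerate(abundance.index):
        top = FRACTIONS[top_idx[i]]
        # best membrane fraction by mean abundance
        mem = max(MEMBRANE_FRACTIONS, key=lambda f: (means[f][i] if np.isfinite(means[f][i]) else -np.inf))
        mem_vals = values[mem][i]
        p_sp = _welch_greater(values["SP"][i], mem_vals)
        p_im = _welch_greater(values["IM"][i], mem_vals)
        untestable = np.isnan(p_sp) and np.isnan(p_im)
        by_top = top in REFERENCE_FRACTIONS
        by_test = (not np.isnan(p_sp) and p_sp < alpha) or (not np.isnan(p_im) and p_im < alpha)
        cop = bool(by_top or by_test)
        if by_top and by_test:
            reason = "highest mean in reference fraction and significant excess"
        elif by_top:
            reason = f"highest mean abundance in {top}"
        elif by_test:
            reason = "SP/IM significantly above best membrane fraction"
        elif untestable:
            reason = "untestable (insufficient replicates); retained"
        else:
            reason = ""
        rows.append((pid, top, p_sp, p_im, cop, untestable, reason))
        if untestable:
            logger.warning("co-purification t-tests untestable for %s; protein retained", pid)
    return pd.DataFrame(
        rows,
        columns=["protein_id", "top_fraction", "p_vs_SP", "p_vs_IM",
                 "copurifying", "untestable", "reason"],
    )


def filter_results(
    results: pd.DataFrame, calls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split partitioning-shift results into retained and excluded tables.

    Excluded = significant proteins flagged co-purifying; they are kept as a
    table (for reporting) rather than silently dropped.
    """
    orphans = set(results["protein_id"]) - set(calls["protein_id"])
    if orphans:
        raise ValueError(
            f"{len(orphans)} proteins missing from co-purification calls, "
            f"e.g. {sorted(orphans)[:5]}"
        )
    merged = results.merge(
        calls[["protein_id", "copurifying", "top_fraction"]], on="protein_id", how="left"
    )
    exclude = merged["significant"] & merged["copurifying"]
    excluded = merged[exclude].reset_index(drop=True)
    retained = merged[~exclude].reset_index(drop=True)
    for key, value in results.attrs.items():
        retained.attrs[key] = value
    return retained, excluded
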
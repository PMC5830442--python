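"""Meta-analytic marker discovery for replicated cell types.

Per dataset, each gene is tested for enrichment in the target type with a
one-sided Wilcoxon rank-sum test against all other cells of that dataset.
Per-dataset p-values are combined across datasets with Fisher's method
(-2 sum(ln p) ~ chi-square on 2k df) and adjusted across genes with
Benjamini-Hochberg. Markers are genes passing the FDR cut that also show a
log2 fold change above the cut in every contributing dataset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MergedExperiment

__all__ = [
    "wilcoxon_one_sided",
    "fisher_combine",
    "bh_adjust",
    "log2_fold_change",
    "run_meta_de",
    "select_markers",
]

#: pseudocount added to group means before taking the fold-change ratio
FC_PSEUDOCOUNT = 1.0

_TINY = np.finfo(float).tiny


def wilcoxon_one_sided(in_group, out_group) -> float:
    """One-sided Wilcoxon rank-sum p-value, alternative "in_group greater".

    Exact enumeration when the pooled sample has at most 20 tie-free
    observations; tie-corrected normal approximation with continuity
    correction otherwise.
    """
    a = np.asarray(in_group, dtype=float)
    b = np.asarray(out_group, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = pooled.size <= 20 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        a, b, alternative="greater", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's method: returns (chi_square, df, meta_p).

    chi_square = -2 sum(ln p) on 2k degrees of freedom. Zero p-values are
    clamped to the smallest positive float with a warning, keeping the
    statistic finite.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float",
                      stacklevel=2)
        p = np.maximum(p, _TINY)
    chi_square = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi_square, df, float(stats.chi2.sf(chi_square, df))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(
    in_values: np.ndarray, out_values: np.ndarray, pseudocount: float = FC_PSEUDOCOUNT
) -> np.ndarray:
    """log2((mean_in + eps) / (mean_out + eps)) per gene (rows)."""
    mean_in = np.asarray(in_values, dtype=float).mean(axis=-1)
    mean_out = np.asarray(out_values, dtype=float).mean(axis=-1)
    return np.log2((mean_in + pseudocount) / (mean_out + pseudocount))


def _dataset_pvalues(X_in: np.ndarray, X_out: np.ndarray) -> np.ndarray:
    """Per-gene one-sided Wilcoxon p-values for one dataset (vectorized)."""
    n = X_in.shape[1] + X_out.shape[1]
    if n > 20:
        res = stats.mannwhitneyu(
            X_in, X_out, alternative="greater", method="asymptotic", axis=1
        )
        return np.asarray(res.pvalue, dtype=float)
    return np.array(
        [wilcoxon_one_sided(X_in[g], X_out[g]) for g in range(X_in.shape[0])]
    )


def run_meta_de(
    merged: MergedExperiment,
    target_type: str,
    pseudocount: float = FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Meta-analytic differential expression of one cell type.

    Only datasets containing the target type contribute; within each, the
    target's cells are compared with all other labeled cells of the same
    dataset. Returns one row per gene with per-dataset p-values and log2
    fold changes (columns ``p_<study>`` / ``log2fc_<study>``), the Fisher
    chi-square, its meta p-value and the BH-adjusted FDR (one family: all
    genes of this target type).
    """
    ann = merged.annotations
    labeled = ann["cell_type"].notna() & (ann["cell_type"] != "")
    contributing = sorted(
        ann.loc[labeled & (ann["cell_type"] == target_type), "study_id"].unique()
    )
    if not contributing:
        raise ValueError(f"no study labels cells as {target_type!r}")
    genes = merged.gene_universe
    out = pd.DataFrame(index=genes)
    per_study_p = []
    for study in contributing:
        in_mask = (
            (ann["study_id"] == study) & (ann["cell_type"] == target_type)
        ).to_numpy()
        out_mask = (
            (ann["study_id"] == study)
            & labeled.to_numpy()
            & (ann["cell_type"] != target_type)
        ).to_numpy()
        if out_mask.sum() == 0:
            raise ValueError(
                f"study {study!r} has no out-group cells for {target_type!r}"
            )
        X_in = merged.data.loc[:, in_mask].to_numpy()
        X_out = merged.data.loc[:, out_mask].to_numpy()
        p = _dataset_pvalues(X_in, X_out)
        out[f"p_{study}"] = p
        out[f"log2fc_{study}"] = log2_fold_change(X_in, X_out, pseudocount)
        per_study_p.append(np.maximum(p, _TINY))
    P = np.column_stack(per_study_p)
    chi_square = -2.0 * np.log(P).sum(axis=1)
    df = 2 * P.shape[1]
    out["chi_square"] = chi_square
    out["df"] = df
    out["meta_p"] = stats.chi2.sf(chi_square, df)
    out["fdr"] = bh_adjust(out["meta_p"].to_numpy())
    return out


def select_markers(
    de: pd.DataFrame, fdr_max: float = 0.001, min_log2fc: float = 2.0
) -> pd.DataFrame:
    """Genes with FDR < fdr_max and log2FC > min_log2fc in every dataset.

    Rows are ranked by the minimum per-dataset fold change, descending, so
    the most consistently enriched genes come first.
    """
    fc_cols = [c for c in de.columns if c.startswith("log2fc_")]
    if not fc_cols:
        raise ValueError("no per-dataset log2fc columns found")
    min_fc = de[fc_cols].min(axis=1)
    passed = de[(de["fdr"] < fdr_max) & (min_fc > min_log2fc)].copy()
    passed["min_log2fc"] = min_fc[passed.index]
    return passed.sort_values("min_log2fc", ascending=False)
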
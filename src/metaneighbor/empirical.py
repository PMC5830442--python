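"""Empirical model of cell-type rarity and transcriptional subtlety.

The model stress-tests cross-dataset classification by constructing data in
which the minority class is both rarer and more similar to the majority
class than in the source data. Rarity is set by subsampling: incidence r of
the n analyzed cells per dataset are positives. Subtlety s replaces the
same randomly chosen fraction of every positive's transcriptome with the
values of a held-out negative cell (one donor per positive, sampled without
replacement and strictly disjoint from the analyzed cells), so each
modified positive is the discrete combination of two real cells differing
from the negative class in only 1 - s of its genes. At each (r, s) the full
cross-dataset voting procedure scores the positives, repeated over seeded
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionStudy, merge_on_gene_universe
from .gene_sets import select_hvg
from .voting import run_metaneighbor

__all__ = [
    "EmpiricalModelConfig",
    "EmpiricalModelResult",
    "subsample_incidence",
    "inject_subtlety",
    "run_empirical_model",
]

POSITIVE, NEGATIVE = "positive", "negative"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class EmpiricalModelConfig:
    """Grid and replication settings for the rarity/subtlety sweep.

    r_values: incidences in (0, 1]; s_values: subtleties in [0, 1];
    n_cells: analyzed cells per dataset; gene_set: explicit gene list used
    for scoring, or "hvg_varying" to re-select HVGs (majority rule) from the
    subsampled data of each replicate.
    """

    r_values: list[float]
    s_values: list[float]
    n_cells: int = 100
    n_reps: int = 100
    gene_set: object = "hvg_varying"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in self.r_values:
            if not 0 < r <= 1:
                raise ValueError("incidence r must lie in (0, 1]")
            if _round_half_up(r * self.n_cells) < 1:
                raise ValueError(
                    f"r={r} with n_cells={self.n_cells} yields no positives"
                )
        for s in self.s_values:
            if not 0 <= s <= 1:
                raise ValueError("subtlety s must lie in [0, 1]")


@dataclass
class EmpiricalModelResult:
    """Long-format replicate scores plus a (r, s) summary."""

    results: pd.DataFrame  # columns: r, s, rep, auroc

    def summary(self) -> pd.DataFrame:
        g = self.results.groupby(["r", "s"])["auroc"]
        return g.agg(mean_auroc="mean", sd_auroc="std").reset_index()


def subsample_incidence(
    positives: list[str],
    negatives: list[str],
    r: float,
    n: int,
    seed: int | np.random.Generator,
) -> tuple[list[str], list[str], list[str]]:
    """Sample an analysis set at incidence r plus paired donor negatives.

    Returns (selected positives, selected negatives, held-out negatives);
    round(r*n) positives (half-up) and n - round(r*n) negatives are drawn
    uniformly without replacement, and one additional negative per positive
    is partitioned off as a donor, disjoint from the analyzed cells.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_pos = _round_half_up(r * n)
    n_neg = n - n_pos
    if n_pos < 1:
        raise ValueError(f"r={r}, n={n}: no positive cells would be sampled")
    if len(positives) < n_pos:
        raise ValueError(
            f"need {n_pos} positives, pool has {len(positives)}"
        )
    if len(negatives) < n_neg + n_pos:
        raise ValueError(
            f"need {n_neg} negatives plus {n_pos} held-out donors, "
            f"pool has {len(negatives)}"
        )
    sel_pos = [positives[i] for i in rng.choice(len(positives), n_pos, replace=False)]
    neg_draw = rng.choice(len(negatives), n_neg + n_pos, replace=False)
    sel_neg = [negatives[i] for i in neg_draw[:n_neg]]
    held_out = [negatives[i] for i in neg_draw[n_neg:]]
    return sel_pos, sel_neg, held_out


def inject_subtlety(
    positive_values: np.ndarray,
    donor_values: np.ndarray,
    s: float,
    seed: int | np.random.Generator,
    swap_rows: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace a shared fraction s of every positive's genes with donor values.

    ``positive_values`` and ``donor_values`` are genes x cells arrays with
    columns paired (positive i's donor is column i). One gene subset of size
    round(s * n_genes) is drawn (or taken from ``swap_rows`` when the mask
    is shared more widely, e.g. across datasets within a replicate) and
    applied identically to all positives. Returns the modified matrix and
    the swap mask.
    """
    if positive_values.shape != donor_values.shape:
        raise ValueError("positives and donors must be paired 1:1")
    if not 0 <= s <= 1:
        raise ValueError("subtlety s must lie in [0, 1]")
    n_genes = positive_values.shape[0]
    if swap_rows is None:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        k = _round_half_up(s * n_genes)
        swap_rows = np.sort(rng.choice(n_genes, size=k, replace=False))
    modified = positive_values.copy()
    modified[swap_rows, :] = donor_values[swap_rows, :]
    return modified, swap_rows


def _one_replicate(
    studies: list[ExpressionStudy],
    pools: dict[str, tuple[list[str], list[str]]],
    r: float,
    s: float,
    config: EmpiricalModelConfig,
    rng: np.random.Generator,
) -> float:
    n_genes = studies[0].n_genes
    k = _round_half_up(s * n_genes)
    swap_rows = np.sort(rng.choice(n_genes, size=k, replace=False))
    sub_studies, meta_rows = [], []
    for study in studies:
        pos_pool, neg_pool = pools[study.study_id]
        sel_pos, sel_neg, held_out = subsample_incidence(
            pos_pool, neg_pool, r, config.n_cells, rng
        )
        assert not set(held_out) & (set(sel_pos) | set(sel_neg))
        donors = [held_out[i] for i in rng.permutation(len(held_out))]
        pos_vals, _ = inject_subtlety(
            study.data[sel_pos].to_numpy(),
            study.data[donors].to_numpy(),
            s,
            rng,
            swap_rows=swap_rows,
        )
        data = pd.concat(
            [
                pd.DataFrame(pos_vals, index=study.gene_ids, columns=sel_pos),
                study.data[sel_neg],
            ],
            axis=1,
        )
        sub_studies.append(ExpressionStudy(study.study_id, data))
        meta_rows.extend(
            (c, study.study_id, POSITIVE) for c in sel_pos
        )
        meta_rows.extend(
            (c, study.study_id, NEGATIVE) for c in sel_neg
        )
    metadata = pd.DataFrame(meta_rows, columns=["cell_id", "study_id", "cell_type"])
    merged = merge_on_gene_universe(sub_studies, metadata=metadata)
    if isinstance(config.gene_set, str) and config.gene_set == "hvg_varying":
        genes = select_hvg(sub_studies, combine="majority")
    else:
        genes = list(config.gene_set)
    reports = run_metaneighbor(merged, [("model", genes)], cell_types=[POSITIVE])
    return float(reports[0].mean_aurocs[POSITIVE])


def run_empirical_model(
    studies: list[ExpressionStudy],
    metadata: pd.DataFrame,
    positive_type: str,
    config: EmpiricalModelConfig,
) -> EmpiricalModelResult:
    """Sweep the (incidence, subtlety) grid with seeded replicates.

    ``metadata`` labels each study's cells; cells of ``positive_type`` form
    the positive pool, all other labeled cells the negative pool. Within a
    replicate the swapped gene subset is shared across datasets; every
    replicate draws its own subsample, donor pairing and gene subset from a
    counter-derived seed so it is reproducible in isolation.
    """
    if len(studies) < 2:
        raise ValueError("the model needs >=2 datasets for cross-validation")
    pools = {}
    for study in studies:
        m = metadata[metadata["study_id"] == study.study_id]
        pos = m.loc[m["cell_type"] == positive_type, "cell_id"].tolist()
        neg = m.loc[
            m["cell_type"].notna() & (m["cell_type"] != positive_type), "cell_id"
        ].tolist()
        if not pos:
            raise ValueError(
                f"study {study.study_id!r} has no {positive_type!r} cells"
            )
        pools[study.study_id] = (pos, neg)

    rows = []
    for ri, r in enumerate(config.r_values):
        for si, s in enumerate(config.s_values):
            for rep in range(config.n_reps):
                # counter-derived seed: each replicate reproducible alone
                rng = np.random.default_rng([config.seed, ri, si, rep])
                auroc = _one_replicate(studies, pools, r, s, config, rng)
                rows.append((r, s, rep, auroc))
    return EmpiricalModelResult(
        results=pd.DataFrame(rows, columns=["r", "s", "rep", "auroc"])
    )
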
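"""Neighbor voting with analytic AUROC under leave-one-dataset-out CV.

Every cell is a neighbor of every other cell to a degree given by the
standardized similarity network. For a candidate cell type, each cell is
scored by the weighted fraction of its neighbors (including itself) that
carry the type label, normalized by node degree so that hub cells are not
preferentially favored. Cross-dataset validation hides one study's labels
at a time; held-out cells are scored using training labels from the other
studies only and ranked within their own study, and performance is the
probability that a held-out cell of the type outranks a held-out cell not
of the type (AUROC), computed analytically from rank sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import MergedExperiment
from .network import MAX_CELLS_DEFAULT, CellNetwork, build_network

__all__ = [
    "FoldScore",
    "AUROCReport",
    "node_degree",
    "neighbor_vote",
    "analytic_auroc",
    "run_metaneighbor",
    "reports_to_long",
    "reports_to_wide",
]


@dataclass
class FoldScore:
    """AUROC of one cell type in one held-out study (NaN = undefined)."""

    test_study: str
    cell_type: str
    auroc: float


@dataclass
class AUROCReport:
    """Per gene set: mean AUROC per cell type plus the per-fold scores."""

    gene_set_name: str
    mean_aurocs: pd.Series
    folds: list[FoldScore] = field(default_factory=list)

    def fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.cell_type, f.test_study, f.auroc) for f in self.folds],
            columns=["cell_type", "test_study", "auroc"],
        )


def node_degree(network: CellNetwork | np.ndarray) -> np.ndarray:
    """Sum of each cell's edge weights, self-edge included."""
    weights = network.weights if isinstance(network, CellNetwork) else network
    return weights.sum(axis=1)


def neighbor_vote(
    network: CellNetwork | np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Degree-normalized label votes: (W @ labels) / degree.

    ``labels`` is a {0,1} vector (columns of a matrix are also accepted);
    the result lies in [0, 1] per cell.
    """
    weights = network.weights if isinstance(network, CellNetwork) else network
    labels = np.asarray(labels, dtype=float)
    if labels.shape[0] != weights.shape[0]:
        raise ValueError("label vector length does not match network size")
    degree = node_degree(weights)
    if labels.ndim == 1:
        return (weights @ labels) / degree
    return (weights @ labels) / degree[:, None]


def analytic_auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Rank-sum AUROC: P(random positive outranks a random negative).

    With scores ranked ascending (average ranks for ties, highest score =
    rank n), returns ``sum(Ranks_pos) / (N * N_neg) - (N + 1) / (2 * N_neg)``
    where N is the positive and N_neg the negative count. NaN when either
    class is empty — with no negatives (or no positives) the quantity is
    undefined, not zero.
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives)
    if positives.dtype != bool:
        mask = np.zeros(len(scores), dtype=bool)
        if positives.size:
            mask[positives.astype(int)] = True
        positives = mask
    n_pos = int(positives.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float(
        ranks[positives].sum() / (n_pos * n_neg) - (n_pos + 1) / (2 * n_neg)
    )


def _label_matrix(
    annotations: pd.DataFrame, cell_types: list[str], train_mask: np.ndarray
) -> np.ndarray:
    ct = annotations["cell_type"].to_numpy(dtype=object)
    L = np.zeros((len(ct), len(cell_types)))
    for k, t in enumerate(cell_types):
        L[:, k] = (ct == t) & train_mask
    return L


def run_metaneighbor(
    merged: MergedExperiment,
    gene_sets,
    cell_types: list[str] | None = None,
    max_cells: int = MAX_CELLS_DEFAULT,
) -> list[AUROCReport]:
    """Score cell-type replicability for every gene set.

    For each gene set one network is built over all cells; each study in
    turn is the test set with its labels hidden (set to 0 in the voting
    vector, so training positives are pooled from the remaining studies).
    Held-out cells are ranked within the test study only, and the per-type
    AUROC of each fold is averaged, skipping folds where the test study has
    no positives or no negatives, or where no training study labels the
    type. Iteration order is deterministic: sorted studies, sorted cell
    types, gene sets in input order.
    """
    studies = merged.studies
    if len(studies) < 2:
        raise ValueError("cross-dataset validation requires >=2 studies")
    ct_series = merged.annotations["cell_type"]
    labeled = ct_series.notna() & (ct_series != "")
    if cell_types is None:
        cell_types = sorted(ct_series[labeled].unique())
    for t in cell_types:
        if not (ct_series[labeled] == t).any():
            raise ValueError(f"cell type {t!r} is not labeled in any study")

    study_arr = merged.annotations["study_id"].to_numpy()
    ct_arr = ct_series.to_numpy(dtype=object)
    reports: list[AUROCReport] = []
    for name, genes in _iter_gene_sets(gene_sets):
        try:
            network = build_network(merged, genes, max_cells=max_cells)
        except ValueError as exc:
            if "need at least 2" in str(exc):
                warnings.warn(f"skipping gene set {name!r}: {exc}", stacklevel=2)
                continue
            raise
        W = network.weights
        degree = node_degree(W)
        folds: list[FoldScore] = []
        for test_study in studies:
            test_mask = study_arr == test_study
            train_mask = ~test_mask
            L = _label_matrix(merged.annotations, cell_types, train_mask)
            votes = (W @ L) / degree[:, None]
            for k, t in enumerate(cell_types):
                if L[:, k].sum() == 0:  # type absent from all training studies
                    auroc = float("nan")
                else:
                    test_scores = votes[test_mask, k]
                    test_pos = (ct_arr[test_mask] == t)
                    auroc = analytic_auroc(test_scores, test_pos)
                folds.append(FoldScore(test_study, t, auroc))
        fold_df = pd.DataFrame(
            [(f.cell_type, f.auroc) for f in folds], columns=["cell_type", "auroc"]
        )
        means = fold_df.groupby("cell_type")["auroc"].mean().reindex(cell_types)
        reports.append(AUROCReport(name, means, folds))
    return reports


def _iter_gene_sets(gene_sets):
    """Accept a GeneSetCollection, a mapping, or a bare (name, genes) list."""
    if hasattr(gene_sets, "items"):
        return list(gene_sets.items())
    return list(gene_sets)


def reports_to_long(reports: list[AUROCReport]) -> pd.DataFrame:
    """Long format: one row per (gene_set, cell_type, test_study)."""
    rows = [
        (r.gene_set_name, f.cell_type, f.test_study, f.auroc)
        for r in reports
        for f in r.folds
    ]
    return pd.DataFrame(rows, columns=["gene_set", "cell_type", "test_study", "auroc"])


def reports_to_wide(reports: list[AUROCReport]) -> pd.DataFrame:
    """Wide format: gene sets x cell types, mean AUROC across folds."""
    return pd.DataFrame(
        {r.gene_set_name: r.mean_aurocs for r in reports}
    ).T.rename_axis("gene_set")
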
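"""Cell-cell similarity networks.

A network is built per gene set: Spearman correlation between every pair of
cells across the genes in the set, then joint rank-standardization of the
whole matrix so all weights lie in (0, 1]. Rank correlation makes the
network invariant to any rank-preserving normalization of the expression
values; rank standardization makes weight distributions uniform across gene
sets and bounds the influence of outlier similarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import MergedExperiment

__all__ = [
    "CellNetwork",
    "spearman_similarity",
    "rank_standardize",
    "build_network",
    "write_network",
    "read_network",
    "MAX_CELLS_DEFAULT",
]

#: refuse to build dense O(cells^2) networks above this many cells
MAX_CELLS_DEFAULT = 50_000


@dataclass
class CellNetwork:
    """Cells x cells symmetric weights, all entries in (0, 1]."""

    cell_ids: pd.Index
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match cell ids")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def _usable_genes(merged: MergedExperiment, gene_set) -> list[str]:
    members = set(gene_set)
    return [g for g in merged.gene_universe if g in members]


def spearman_similarity(merged: MergedExperiment, gene_set) -> np.ndarray:
    """Spearman correlation between all cell pairs over a gene set.

    Each cell's profile over the (universe-intersected) gene set is ranked
    with average ranks for ties, then Pearson correlation of the rank
    vectors is taken. A cell with zero variance across the set has no
    defined correlation; its off-diagonal entries are set to 0 with a
    warning so the network stays total and finite.
    """
    genes = _usable_genes(merged, gene_set)
    if len(genes) < 2:
        raise ValueError(
            f"gene set has {len(genes)} gene(s) in the universe; "
            "need at least 2"
        )
    if merged.n_cells < 2:
        raise ValueError("need at least 2 cells")
    X = merged.data.loc[genes].to_numpy(dtype=float)
    R = rankdata(X, axis=0)  # rank each cell's profile across genes
    constant = R.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} cell(s) have zero variance across the "
            "gene set; their correlations are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(R, rowvar=False)
    C = np.where(np.isfinite(C), C, 0.0)
    C = (C + C.T) / 2.0  # enforce exact symmetry before ranking
    # collapse float noise so genuinely tied similarities (e.g. duplicate
    # cells, correlation exactly 1) rank as ties, not by rounding error
    C = np.round(C, 12)
    np.fill_diagonal(C, 1.0)
    return C


def rank_standardize(raw: np.ndarray) -> np.ndarray:
    """Replace every entry by rank / max(rank), jointly over the matrix.

    Average ranks are used for ties, so a symmetric input stays symmetric
    and the output is a monotone transform of the input with maximum exactly
    1. Self-similarities (the all-1 diagonal) take the top rank.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("network entries must be finite")
    ranks = rankdata(raw, axis=None)
    return (ranks / ranks.max()).reshape(raw.shape)


def build_network(
    merged: MergedExperiment,
    gene_set,
    max_cells: int = MAX_CELLS_DEFAULT,
) -> CellNetwork:
    """Spearman similarity followed by joint rank standardization.

    The result is dense O(cells^2); inputs above ``max_cells`` cells are
    refused rather than silently thrashing memory.
    """
    if merged.n_cells > max_cells:
        raise ValueError(
            f"{merged.n_cells} cells exceeds the configured ceiling of "
            f"{max_cells}; raise max_cells explicitly if this is intended"
        )
    weights = rank_standardize(spearman_similarity(merged, gene_set))
    return CellNetwork(cell_ids=merged.data.columns, weights=weights)


def write_network(network: CellNetwork, path: str | Path) -> None:
    pd.DataFrame(
        network.weights, index=network.cell_ids, columns=network.cell_ids
    ).to_csv(path, sep="\t")


def read_network(path: str | Path) -> CellNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.index.astype(str).equals(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column cell ids differ")
    return CellNetwork(cell_ids=df.columns, weights=df.to_numpy(dtype=float))
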
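"""Synthetic multi-study single-cell expression with planted structure.

The generator emulates the cross-laboratory setting the framework targets:
several studies profile the same cell types, each type carries its own
marker genes (multiplicatively up-shifted means), each study applies its own
per-gene multiplicative batch distortion, and measurements are overdispersed
counts (gamma-Poisson) thinned by independent dropout. Ground-truth marker
assignments are returned so tests never re-derive them.

This is not a read-level scRNA-seq simulator: there is no UMI model, no
library-size variation beyond what the count noise induces, and no
gene-gene correlation structure beyond the planted type means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionStudy

__all__ = [
    "SyntheticConfig",
    "generate",
    "generate_disjoint_types",
    "shuffle_labels",
    "merge_generated",
]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    effect_size is the log2 mean shift of a type's marker genes (markers are
    ``2**effect_size``-fold up); batch_sd is the standard deviation of the
    per-study per-gene log-normal distortion factor (natural-log scale);
    dispersion is the gamma shape of the gamma-Poisson count noise (smaller
    = more overdispersed). cells_per_type_per_study may be a single int or
    one int per type, which is how rare types (1-24% incidence) are set up.
    """

    n_studies: int = 3
    n_types: int = 2
    cells_per_type_per_study: int | list[int] = 50
    n_genes: int = 500
    n_marker_genes_per_type: int = 50
    effect_size: float = 2.0
    batch_sd: float = 0.5
    dropout_rate: float = 0.3
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.cells_per_type(0)
        if self.n_studies < 1 or self.n_types < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if isinstance(self.cells_per_type_per_study, list):
            if len(self.cells_per_type_per_study) != self.n_types:
                raise ValueError("need one cell count per type")
        if counts < 1:
            raise ValueError("cells_per_type_per_study must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_marker_genes_per_type * self.n_types > self.n_genes:
            raise ValueError("marker genes exceed the gene universe")

    def cells_per_type(self, k: int) -> int:
        if isinstance(self.cells_per_type_per_study, list):
            return int(self.cells_per_type_per_study[k])
        return int(self.cells_per_type_per_study)


def generate(
    config: SyntheticConfig,
) -> tuple[list[ExpressionStudy], pd.DataFrame, dict[str, list[str]]]:
    """Generate studies, cell metadata and the ground-truth marker map.

    Baseline gene means are log-normal (heavy-tailed, as real transcript
    abundances are); type ``type_k`` has its markers multiplied by
    ``2**effect_size``; study ``study_s`` multiplies every gene by
    ``exp(N(0, batch_sd))``; counts are gamma-Poisson with the configured
    dispersion and are zeroed independently with probability dropout_rate.
    Byte-identical under the same seed.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{j + 1:04d}" for j in range(config.n_genes)]
    base_mean = rng.lognormal(mean=1.0, sigma=1.0, size=config.n_genes)

    marker_idx = rng.choice(
        config.n_genes,
        size=config.n_marker_genes_per_type * config.n_types,
        replace=False,
    )
    type_names = [f"type_{k + 1}" for k in range(config.n_types)]
    marker_map = {
        t: sorted(
            gene_ids[j]
            for j in marker_idx[
                k * config.n_marker_genes_per_type : (k + 1)
                * config.n_marker_genes_per_type
            ]
        )
        for k, t in enumerate(type_names)
    }
    type_mult = np.ones((config.n_types, config.n_genes))
    for k, t in enumerate(type_names):
        cols = [gene_ids.index(g) for g in marker_map[t]]
        type_mult[k, cols] = 2.0 ** config.effect_size

    studies: list[ExpressionStudy] = []
    meta_rows = []
    for s in range(config.n_studies):
        study_id = f"study_{s + 1}"
        batch = np.exp(rng.normal(0.0, config.batch_sd, size=config.n_genes))
        blocks, cells = [], []
        for k, t in enumerate(type_names):
            n_cells = config.cells_per_type(k)
            mu = base_mean * batch * type_mult[k]  # (n_genes,)
            lam = rng.gamma(
                shape=config.dispersion,
                scale=np.tile(mu[:, None], (1, n_cells)) / config.dispersion,
            )
            counts = rng.poisson(lam).astype(float)
            if config.dropout_rate > 0:
                keep = rng.random(counts.shape) >= config.dropout_rate
                counts *= keep
            blocks.append(counts)
            start = len(cells)
            new = [f"{study_id}_c{start + i + 1:04d}" for i in range(n_cells)]
            cells.extend(new)
            meta_rows.extend((c, study_id, t) for c in new)
        data = pd.DataFrame(
            np.hstack(blocks), index=gene_ids, columns=cells
        )
        studies.append(ExpressionStudy(study_id=study_id, data=data))
    metadata = pd.DataFrame(meta_rows, columns=["cell_id", "study_id", "cell_type"])
    return studies, metadata, marker_map


def generate_disjoint_types(
    n_studies: int = 3,
    cells_per_type: int = 30,
    genes_per_type: int = 100,
    mean_level: float = 10.0,
    dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[list[ExpressionStudy], pd.DataFrame, dict[str, list[str]]]:
    """Two types with disjointly supported expression, identical across studies.

    ``type_A`` expresses only the first ``genes_per_type`` genes and
    ``type_B`` only the next block; everything off-support is exactly zero.
    The extreme case for which cross-dataset classification is perfect.
    """
    rng = np.random.default_rng(seed)
    n_genes = 2 * genes_per_type
    gene_ids = [f"g{j + 1:04d}" for j in range(n_genes)]
    support = {
        "type_A": np.arange(genes_per_type),
        "type_B": np.arange(genes_per_type, n_genes),
    }
    studies, meta_rows = [], []
    for s in range(n_studies):
        study_id = f"study_{s + 1}"
        blocks, cells = [], []
        for t, rows in support.items():
            lam = rng.gamma(
                shape=dispersion,
                scale=mean_level / dispersion,
                size=(len(rows), cells_per_type),
            )
            counts = np.zeros((n_genes, cells_per_type))
            counts[rows] = rng.poisson(lam)
            blocks.append(counts)
            start = len(cells)
            new = [f"{study_id}_c{start + i + 1:03d}" for i in range(cells_per_type)]
            cells.extend(new)
            meta_rows.extend((c, study_id, t) for c in new)
        data = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=cells)
        studies.append(ExpressionStudy(study_id=study_id, data=data))
    metadata = pd.DataFrame(meta_rows, columns=["cell_id", "study_id", "cell_type"])
    marker_map = {t: [gene_ids[j] for j in rows] for t, rows in support.items()}
    return studies, metadata, marker_map


def shuffle_labels(metadata: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Permute cell_type within each study; per-study label counts unchanged.

    The null harness: after shuffling, labels are independent of expression
    while every marginal frequency is preserved.
    """
    rng = np.random.default_rng(seed)
    out = metadata.copy()
    for study in sorted(out["study_id"].unique()):
        idx = out.index[out["study_id"] == study]
        out.loc[idx, "cell_type"] = (
            out.loc[idx, "cell_type"].to_numpy()[rng.permutation(len(idx))]
        )
    return out


def merge_generated(studies, metadata):
    """Convenience: merge generated studies with their metadata."""
    from .io import merge_on_gene_universe

    return merge_on_gene_universe(studies, metadata=metadata)
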
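"""Reading, merging and quality control of expression studies.

Dense matrices are genes-as-rows delimited text (first column = gene id,
header row = cell ids). Sparse matrices are MatrixMarket coordinate files
with sidecar row/column name files (one name per line). Expression values
must be finite and non-negative; units are arbitrary as long as they are
rank-preserving (counts, TPM, RPKM, log2 of any of these), because every
downstream computation works on ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionStudy",
    "MergedExperiment",
    "load_study",
    "write_study",
    "read_metadata",
    "write_metadata",
    "collapse_duplicate_genes",
    "merge_on_gene_universe",
    "filter_low_coverage_cells",
]

#: separator used to namespace cell ids with their study of origin
STUDY_SEP = "|"


@dataclass
class ExpressionStudy:
    """One study's genes x cells expression matrix.

    ``data`` is a genes x cells :class:`pandas.DataFrame`; gene ids may be
    duplicated until :func:`collapse_duplicate_genes` is applied, cell ids
    must be unique within the study.
    """

    study_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError(
                f"study {self.study_id!r}: expression contains non-finite values"
            )
        if values.size and values.min() < 0:
            gene, cell = np.unravel_index(int(np.argmin(values)), values.shape)
            raise ValueError(
                f"study {self.study_id!r}: negative expression value "
                f"{values[gene, cell]} at gene {self.data.index[gene]!r}, "
                f"cell {self.data.columns[cell]!r}"
            )
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(
                f"study {self.study_id!r}: duplicate cell id {dup!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]


@dataclass
class MergedExperiment:
    """Multi-study expression on a shared gene universe.

    ``data``: genes x cells DataFrame whose columns are namespaced
    ``"study|cell"`` ids. ``annotations``: one row per column, indexed by the
    namespaced id, with columns ``study_id``, ``cell_id`` and ``cell_type``
    (NaN/None = unlabeled).
    """

    data: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.columns.equals(self.annotations.index):
            raise ValueError("annotation rows must match matrix columns 1:1")

    @property
    def gene_universe(self) -> pd.Index:
        return self.data.index

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    @property
    def studies(self) -> list[str]:
        return sorted(self.annotations["study_id"].unique())

    def labeled_mask(self) -> np.ndarray:
        ct = self.annotations["cell_type"]
        return (ct.notna() & (ct != "")).to_numpy()

    def subset_cells(self, keep: np.ndarray) -> "MergedExperiment":
        return MergedExperiment(
            self.data.loc[:, keep], self.annotations.loc[keep]
        )


def _read_names(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def load_study(
    expression_path: str | Path,
    format: str = "dense",
    study_id: str | None = None,
    *,
    gene_names_path: str | Path | None = None,
    cell_names_path: str | Path | None = None,
) -> ExpressionStudy:
    """Read one study's expression matrix from disk.

    ``format="dense"``: delimited text, comma separator for ``.csv``
    otherwise tab. ``format="matrix_market"``: coordinate file plus sidecar
    name files (defaults: ``<path>.rows`` for genes, ``<path>.cols`` for
    cells).
    """
    path = Path(expression_path)
    if study_id is None:
        study_id = path.stem
    if format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pandas raises several parser classes
            raise ValueError(f"cannot parse {path}: {exc}") from exc
        non_numeric = df.columns[
            [not np.issubdtype(dt, np.number) for dt in df.dtypes]
        ]
        if len(non_numeric):
            raise ValueError(
                f"cannot parse {path}: non-numeric entries in column "
                f"{non_numeric[0]!r}"
            )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "matrix_market":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ValueError(f"cannot parse {path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_names(
            Path(gene_names_path) if gene_names_path else path.with_suffix(
                path.suffix + ".rows"
            )
        )
        cells = _read_names(
            Path(cell_names_path) if cell_names_path else path.with_suffix(
                path.suffix + ".cols"
            )
        )
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"{path}: matrix shape {mat.shape} does not match "
                f"{len(genes)} gene / {len(cells)} cell names"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionStudy(study_id=study_id, data=df)


def write_study(
    study: ExpressionStudy, path: str | Path, format: str = "dense"
) -> None:
    """Write a study in a format :func:`load_study` reads back."""
    path = Path(path)
    if format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        study.data.to_csv(path, sep=sep)
    elif format == "matrix_market":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(study.values))
        path.with_suffix(path.suffix + ".rows").write_text(
            "".join(f"{g}\n" for g in study.gene_ids)
        )
        path.with_suffix(path.suffix + ".cols").write_text(
            "".join(f"{c}\n" for c in study.cell_ids)
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a cell metadata table (TSV: cell_id, study_id, cell_type)."""
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"cell_id", "study_id", "cell_type"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    meta.loc[meta["cell_type"] == "", "cell_type"] = pd.NA
    if meta.duplicated(["study_id", "cell_id"]).any():
        dup = meta[meta.duplicated(["study_id", "cell_id"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate metadata row for study {dup['study_id']!r}, "
            f"cell {dup['cell_id']!r}"
        )
    return meta


def write_metadata(annotations: pd.DataFrame, path: str | Path) -> None:
    out = annotations[["cell_id", "study_id", "cell_type"]].copy()
    out["cell_type"] = out["cell_type"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def collapse_duplicate_genes(study: ExpressionStudy) -> ExpressionStudy:
    """Average rows that share a gene id.

    Rows with the same id are replaced by their elementwise arithmetic mean;
    row order follows first occurrence. Idempotent.
    """
    if not study.gene_ids.duplicated().any():
        return study
    collapsed = study.data.groupby(level=0, sort=False).mean()
    return ExpressionStudy(study_id=study.study_id, data=collapsed)


def merge_on_gene_universe(
    studies: list[ExpressionStudy],
    gene_universe: list[str] | pd.Index | None = None,
    metadata: pd.DataFrame | None = None,
) -> MergedExperiment:
    """Stack studies column-wise on a shared gene universe.

    Genes absent from a study are zero-filled for that study's cells; all
    cells are retained. Cell ids are namespaced ``"study|cell"`` so they are
    globally unique. ``gene_universe`` defaults to the union of study genes
    in order of first appearance. ``metadata`` (cell_id/study_id/cell_type)
    labels the cells; cells without a metadata row stay unlabeled.
    """
    if not studies:
        raise ValueError("at least one study is required")
    seen_ids = set()
    for s in studies:
        if s.study_id in seen_ids:
            raise ValueError(f"duplicate study id {s.study_id!r}")
        seen_ids.add(s.study_id)
        if s.gene_ids.duplicated().any():
            raise ValueError(
                f"study {s.study_id!r} has duplicate gene ids; apply "
                "collapse_duplicate_genes first"
            )
    if gene_universe is None:
        universe: list[str] = []
        known: set[str] = set()
        for s in studies:
            for g in s.gene_ids:
                if g not in known:
                    known.add(g)
                    universe.append(g)
        gene_universe = universe
    gene_universe = pd.Index(gene_universe)
    if len(gene_universe) == 0:
        raise ValueError("gene universe is empty")
    if gene_universe.duplicated().any():
        raise ValueError("gene universe contains duplicate ids")

    blocks = []
    ann_rows = []
    for s in studies:
        block = s.data.reindex(index=gene_universe, fill_value=0.0)
        block.columns = [f"{s.study_id}{STUDY_SEP}{c}" for c in s.cell_ids]
        blocks.append(block)
        for c in s.cell_ids:
            ann_rows.append((f"{s.study_id}{STUDY_SEP}{c}", str(c), s.study_id))
    data = pd.concat(blocks, axis=1)
    if data.columns.duplicated().any():
        dup = data.columns[data.columns.duplicated()][0]
        raise ValueError(f"duplicate namespaced cell id {dup!r}")
    annotations = pd.DataFrame(
        ann_rows, columns=["key", "cell_id", "study_id"]
    ).set_index("key")
    annotations.index.name = None
    annotations["cell_type"] = pd.NA

    if metadata is not None:
        labeled = metadata[metadata["cell_type"].notna()]
        keys = labeled["study_id"] + STUDY_SEP + labeled["cell_id"]
        known_keys = keys.isin(annotations.index)
        annotations.loc[
            keys[known_keys], "cell_type"
        ] = labeled.loc[known_keys, "cell_type"].to_numpy()
    return MergedExperiment(data=data, annotations=annotations)


def filter_low_coverage_cells(
    merged: MergedExperiment, min_genes: int = 1000
) -> MergedExperiment:
    """Drop cells expressing fewer than ``min_genes`` genes at level > 0.

    The count is taken on the raw stored values ("expressed" means strictly
    positive); a cell with exactly ``min_genes`` expressed genes is kept.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be non-negative")
    n_expressed = (merged.data.to_numpy() > 0).sum(axis=0)
    keep = n_expressed >= min_genes
    if not keep.any():
        survivors = merged.annotations.groupby("study_id").size() * 0
        raise ValueError(
            f"no cell expresses >= {min_genes} genes; per-study survivor "
            f"counts: {survivors.to_dict()}"
        )
    return merged.subset_cells(keep)
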
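"""Gene-set collections and selection heuristics.

Four sources of gene sets are supported: GMT files (e.g. GO slim exports)
with the 20-1000 size filter, size-matched random sets, coefficient-of-
variation centile sets, and the highly-variable-gene (HVG) heuristic that
picks the most variable genes within expression-level bins and combines
per-study lists by intersection or majority rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionStudy

__all__ = [
    "GeneSetCollection",
    "parse_gmt",
    "write_gmt",
    "filter_by_size",
    "random_sets_matched",
    "cv_centile_sets",
    "select_hvg",
]


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets with a provenance tag.

    ``sets`` maps set name -> list of unique gene ids (insertion order kept
    for reproducible output); ``descriptions`` carries the GMT description
    column or heuristic metadata.
    """

    sets: dict[str, list[str]]
    provenance: str = "user"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()

    def __iter__(self):
        return iter(self.sets.items())


def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-delimited GMT file (name, description, genes...).

    Duplicate genes within a line are dropped, keeping first occurrence.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, >=1 gene)"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(g for g in genes if g))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, provenance="user", descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, collection.provenance)
            fh.write("\t".join([name, desc, *genes]) + "\n")


def filter_by_size(
    sets: GeneSetCollection,
    universe,
    min_size: int = 20,
    max_size: int = 1000,
) -> GeneSetCollection:
    """Intersect each set with the gene universe, keep sets of usable size.

    A set is retained iff ``min_size <= |set & universe| <= max_size``
    (bounds inclusive); the retained set is the intersection itself. The
    operation is idempotent.
    """
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    members = set(universe)
    kept: dict[str, list[str]] = {}
    for name, genes in sets.items():
        usable = [g for g in genes if g in members]
        if min_size <= len(usable) <= max_size:
            kept[name] = usable
    return GeneSetCollection(
        sets=kept,
        provenance=sets.provenance,
        descriptions={n: sets.descriptions.get(n, "") for n in kept},
    )


def random_sets_matched(
    template_sizes: list[int],
    universe,
    n_sets: int,
    seed: int,
) -> GeneSetCollection:
    """Random gene sets with sizes drawn from a template distribution.

    Genes are drawn uniformly without replacement within each set;
    reproducible under ``seed``.
    """
    universe = list(universe)
    if not template_sizes:
        raise ValueError("template_sizes is empty")
    if max(template_sizes) > len(universe):
        raise ValueError(
            f"template size {max(template_sizes)} exceeds universe size "
            f"{len(universe)}"
        )
    rng = np.random.default_rng(seed)
    sizes = rng.choice(np.asarray(template_sizes), size=n_sets, replace=True)
    width = len(str(max(n_sets, 1)))
    sets = {
        f"random_{i + 1:0{width}d}": [
            universe[j] for j in rng.choice(len(universe), size=int(k), replace=False)
        ]
        for i, k in enumerate(sizes)
    }
    return GeneSetCollection(sets=sets, provenance="random")


def _per_gene_cv(study: ExpressionStudy) -> pd.Series:
    values = study.values
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(len(mean))
    cv = pd.Series(np.divide(sd, mean, out=np.zeros_like(sd), where=mean > 0),
                   index=study.gene_ids)
    return cv[mean > 0]


def cv_centile_sets(
    studies: list[ExpressionStudy], n_bins: int = 100
) -> GeneSetCollection:
    """Bin shared genes into equal-size bins of average CV rank.

    Per study, the coefficient of variation (sd/mean) of every gene with
    nonzero mean is ranked; ranks are averaged across studies over the genes
    shared by all studies, and the averaged ranks are partitioned into
    ``n_bins`` equal-count bins ordered from lowest to highest CV. The top
    bin is flagged in its description: in practice the most extremely
    variable genes are dominated by technical noise and carry little
    cell-type signal.
    """
    if not studies:
        raise ValueError("at least one study is required")
    cvs = [_per_gene_cv(s) for s in studies]
    shared = cvs[0].index
    for cv in cvs[1:]:
        shared = shared.intersection(cv.index)
    shared = sorted(shared)
    if len(shared) < n_bins:
        raise ValueError(
            f"only {len(shared)} shared genes with nonzero mean; "
            f"need at least n_bins={n_bins}"
        )
    rank_sum = np.zeros(len(shared))
    for cv in cvs:
        rank_sum += rankdata(cv.loc[shared].to_numpy())
    avg_rank = rank_sum / len(cvs)
    # order genes by averaged rank, lexicographic gene id breaking ties
    order = sorted(range(len(shared)), key=lambda i: (avg_rank[i], shared[i]))
    chunks = np.array_split(np.asarray(order), n_bins)
    width = len(str(n_bins))
    sets, descriptions = {}, {}
    for b, chunk in enumerate(chunks):
        name = f"cv_centile_{b + 1:0{width}d}"
        sets[name] = [shared[i] for i in chunk]
        descriptions[name] = (
            f"CV bin {b + 1}/{n_bins} (low to high)"
            + ("; top bin: typically uninformative" if b == n_bins - 1 else "")
        )
    return GeneSetCollection(sets=sets, provenance="cv_centile",
                             descriptions=descriptions)


def _hvg_one_study(
    study: ExpressionStudy, n_expr_bins: int, top_fraction: float
) -> set[str]:
    values = study.values
    genes = list(study.gene_ids)
    mean = values.mean(axis=1)
    var = values.var(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros_like(mean)
    # equal-count expression bins, ties at bin edges broken by gene id
    order = sorted(range(len(genes)), key=lambda i: (mean[i], genes[i]))
    bins = np.array_split(np.asarray(order), n_expr_bins)
    selected: set[str] = set()
    for expr_bin in bins[:-1]:  # exclude the most highly expressed bin
        if len(expr_bin) == 0:
            continue
        k = math.ceil(top_fraction * len(expr_bin))
        top = sorted(expr_bin, key=lambda i: (-var[i], genes[i]))[:k]
        selected.update(genes[i] for i in top)
    return selected


def select_hvg(
    studies: list[ExpressionStudy],
    combine: str = "intersect",
    n_expr_bins: int = 10,
    top_fraction: float = 0.25,
) -> list[str]:
    """Highly variable genes, combined across studies.

    Per study, genes are split into ``n_expr_bins`` equal-count bins by mean
    expression; within every bin except the most highly expressed one the
    ``top_fraction`` most variable genes (by variance; ceil, so small bins
    contribute at least one gene) form the study's HVG list. Lists are
    combined by intersection (default) or by majority rule (gene kept when
    present in strictly more than half of the studies).
    """
    if not studies:
        raise ValueError("at least one study is required")
    if combine not in ("intersect", "majority"):
        raise ValueError(f"unknown combine rule {combine!r}")
    lists = [_hvg_one_study(s, n_expr_bins, top_fraction) for s in studies]
    if combine == "intersect":
        combined = set.intersection(*lists)
    else:
        counts: dict[str, int] = {}
        for lst in lists:
            for g in lst:
                counts[g] = counts.get(g, 0) + 1
        combined = {g for g, c in counts.items() if c > len(studies) / 2}
    if not combined:
        raise ValueError(
            "combined HVG set is empty; consider combine='majority' "
            "(intersection grows stringent with many studies)"
        )
    return sorted(combined)
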
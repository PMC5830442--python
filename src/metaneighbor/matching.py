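"""Matching cell subtypes across studies with different label vocabularies.

Each study-qualified subtype is alternately the training positive and the
test positive: voting scores trained on subtype A are evaluated as an AUROC
for subtype B against all other cells of B's study, and the (A->B, B->A)
mean fills a square subtype x subtype matrix. Reciprocal best hits across
studies, optionally together with pairs scoring at or above a threshold
(0.95 by default), define candidate edges whose connected components are
reported as putatively replicated types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import STUDY_SEP, MergedExperiment
from .network import MAX_CELLS_DEFAULT, build_network
from .voting import analytic_auroc, node_degree

__all__ = [
    "PairwiseAUROCMatrix",
    "ReplicateGroup",
    "pairwise_auroc",
    "reciprocal_best_hits",
    "identify_replicates",
    "merged_labels",
]


def _qualify(study: str, subtype: str) -> str:
    return f"{study}{STUDY_SEP}{subtype}"


@dataclass
class PairwiseAUROCMatrix:
    """Square subtype x subtype score matrix (study-qualified ids).

    ``scores`` is symmetric by construction (each entry is the mean of the
    two train/test directions) with diagonal 1. ``subtype_study`` maps each
    subtype id to its study; within-study off-diagonal entries come from
    within-study cross-validation and are flagged by ``within_study_mask``.
    """

    scores: pd.DataFrame
    subtype_study: pd.Series

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.scores.columns):
            raise ValueError("score matrix must be square with matching ids")

    @property
    def subtypes(self) -> pd.Index:
        return self.scores.index

    def within_study_mask(self) -> pd.DataFrame:
        studies = self.subtype_study.loc[self.subtypes].to_numpy()
        same = studies[:, None] == studies[None, :]
        return pd.DataFrame(same, index=self.subtypes, columns=self.subtypes)


@dataclass
class ReplicateGroup:
    """A putatively replicated type: >=2 subtypes spanning >=2 studies."""

    label: str
    members: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def studies(self) -> set[str]:
        return {m.split(STUDY_SEP, 1)[0] for m in self.members}


def _direction_auroc(
    W: np.ndarray,
    degree: np.ndarray,
    train_labels: np.ndarray,
    test_mask: np.ndarray,
    test_pos: np.ndarray,
) -> float:
    votes = (W @ train_labels) / degree
    return analytic_auroc(votes[test_mask], test_pos[test_mask])


def pairwise_auroc(
    merged: MergedExperiment,
    gene_set,
    n_folds: int = 2,
    seed: int = 0,
    max_cells: int = MAX_CELLS_DEFAULT,
) -> PairwiseAUROCMatrix:
    """All-vs-all train/test AUROCs between study-qualified subtypes.

    Cross-study entry (A, B): train on all of A's cells, score the cells of
    B's study and compute the AUROC of B's cells against the rest of that
    study; the entry is the mean of the A->B and B->A directions.
    Within-study entries are filled by ``n_folds``-fold cross-validation
    inside the study (training on A's cells outside the held-out fold,
    scoring the fold), averaged over folds and directions; the fold split is
    a seeded permutation so results are reproducible. Diagonal is defined
    as 1.
    """
    ann = merged.annotations
    labeled = ann["cell_type"].notna() & (ann["cell_type"] != "")
    if not labeled.all():
        merged = merged.subset_cells(labeled.to_numpy())
        ann = merged.annotations
    study_arr = ann["study_id"].to_numpy()
    ct_arr = ann["cell_type"].to_numpy(dtype=object)
    subtype_study = {}
    for s, t in sorted(set(zip(study_arr, ct_arr))):
        subtype_study[_qualify(s, t)] = s
    subtypes = pd.Index(sorted(subtype_study))
    studies = sorted(set(study_arr))
    if len(studies) < 2:
        raise ValueError("subtype matching requires >=2 studies")
    for q in subtypes:
        s, t = q.split(STUDY_SEP, 1)
        if ((study_arr == s) & (ct_arr == t)).sum() == 0:
            raise ValueError(f"subtype {q!r} has no cells")

    network = build_network(merged, gene_set, max_cells=max_cells)
    W = network.weights
    degree = node_degree(W)
    n = len(ct_arr)

    member = {
        q: (study_arr == q.split(STUDY_SEP, 1)[0])
        & (ct_arr == q.split(STUDY_SEP, 1)[1])
        for q in subtypes
    }
    study_mask = {s: study_arr == s for s in studies}

    # seeded within-study fold assignment, stratified by subtype so every
    # fold sees every subtype when counts allow
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n, dtype=int)
    for q in subtypes:
        idx = np.flatnonzero(member[q])
        perm = idx[rng.permutation(len(idx))]
        fold_of[perm] = np.arange(len(perm)) % n_folds

    # one-directional scores: train subtype -> test subtype
    direct = pd.DataFrame(np.nan, index=subtypes, columns=subtypes)
    for a in subtypes:
        sa = subtype_study[a]
        votes_full = (W @ member[a].astype(float)) / degree
        for b in subtypes:
            sb = subtype_study[b]
            if sa != sb:
                tm = study_mask[sb]
                direct.loc[a, b] = analytic_auroc(votes_full[tm], member[b][tm])
            else:
                vals = []
                for f in range(n_folds):
                    held = study_mask[sa] & (fold_of == f)
                    train = member[a] & ~held
                    if train.sum() == 0 or held.sum() == 0:
                        continue
                    votes = (W @ train.astype(float)) / degree
                    vals.append(analytic_auroc(votes[held], member[b][held]))
                direct.loc[a, b] = float(np.nanmean(vals)) if vals else np.nan
    with np.errstate(invalid="ignore"):
        scores = (direct.to_numpy() + direct.to_numpy().T) / 2.0
    np.fill_diagonal(scores, 1.0)
    return PairwiseAUROCMatrix(
        scores=pd.DataFrame(scores, index=subtypes, columns=subtypes),
        subtype_study=pd.Series(subtype_study),
    )


def reciprocal_best_hits(matrix: PairwiseAUROCMatrix) -> pd.DataFrame:
    """Cross-study subtype pairs that are each other's best match.

    For subtype A and every other study S, B is a best hit when it attains
    the maximum of A's scores over S's subtypes; (A, B) is reported when the
    relation holds in both directions. Co-maximal ties are all reported and
    flagged. Output columns: subtype_a, subtype_b, score, tie.
    """
    S = matrix.scores
    studies = matrix.subtype_study
    if len(set(studies)) < 2:
        raise ValueError("reciprocal best hits require >=2 studies")

    def best_in_study(a: str, target_study: str) -> set[str]:
        cols = studies.index[studies == target_study]
        row = S.loc[a, cols].astype(float)
        if row.isna().all():
            return set()
        m = row.max()
        return set(row.index[row == m])

    rows = []
    seen = set()
    for a in S.index:
        for target in sorted(set(studies) - {studies[a]}):
            bests = best_in_study(a, target)
            for b in bests:
                if a not in best_in_study(b, studies[a]):
                    continue
                key = tuple(sorted((a, b)))
                if key in seen:
                    continue
                seen.add(key)
                tie = len(bests) > 1 or len(best_in_study(b, studies[a])) > 1
                rows.append((key[0], key[1], float(S.loc[a, b]), tie))
    return pd.DataFrame(rows, columns=["subtype_a", "subtype_b", "score", "tie"])


def identify_replicates(
    matrix: PairwiseAUROCMatrix,
    threshold: float = 0.95,
    mode: str = "union",
) -> list[ReplicateGroup]:
    """Group subtypes into putatively replicated types.

    Candidate edges are cross-study reciprocal best hits together with
    (``mode="union"``, the default) every cross-study pair scoring
    ``>= threshold``; ``mode="strict"`` instead requires an RBH pair to also
    meet the threshold. Groups are the connected components of the candidate
    edge graph with singletons discarded; because every edge is cross-study,
    each group spans >=2 studies. Lowering the threshold can only add edges,
    so group membership is monotone in it.
    """
    if threshold < 0.5:
        raise ValueError("threshold must be >= 0.5")
    if mode not in ("union", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    S = matrix.scores
    rbh = reciprocal_best_hits(matrix)
    edges: dict[tuple[str, str], float] = {}
    for _, row in rbh.iterrows():
        pair = (row["subtype_a"], row["subtype_b"])
        if mode == "union" or row["score"] >= threshold:
            edges[pair] = row["score"]
    if mode == "union":
        cross = ~matrix.within_study_mask().to_numpy()
        vals = S.to_numpy()
        ii, jj = np.where(cross & (vals >= threshold))
        for i, j in zip(ii, jj):
            if i < j:
                pair = tuple(sorted((S.index[i], S.index[j])))
                edges.setdefault(pair, float(vals[i, j]))

    graph = nx.Graph()
    graph.add_nodes_from(S.index)
    for (a, b), score in edges.items():
        graph.add_edge(a, b, score=score)
    groups = []
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        comp_edges = [
            (a, b, float(d["score"]))
            for a, b, d in graph.edges(comp, data=True)
        ]
        groups.append(
            ReplicateGroup(
                label="+".join(members), members=members, edges=comp_edges
            )
        )
    return groups


def merged_labels(
    groups: list[ReplicateGroup], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Relabel cells of replicated subtypes with their group label.

    ``annotations`` must carry study_id and cell_type columns (the merged
    experiment's table); cells outside any group keep their original label.
    The result is suitable as input to run_metaneighbor or the meta-analytic
    marker discovery.
    """
    seen: dict[str, str] = {}
    for g in groups:
        for m in g.members:
            if m in seen:
                raise ValueError(
                    f"subtype {m!r} appears in more than one group"
                )
            seen[m] = g.label
    out = annotations.copy()
    qualified = (
        out["study_id"].astype(str) + STUDY_SEP + out["cell_type"].astype(str)
    )
    mapped = qualified.map(seen)
    out.loc[mapped.notna(), "cell_type"] = mapped[mapped.notna()]
    return out
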
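import numpy as np
import pandas as pd
import pytest

from metaneighbor.gene_sets import select_hvg
from metaneighbor.io import merge_on_gene_universe
from metaneighbor.matching import (
    PairwiseAUROCMatrix,
    ReplicateGroup,
    identify_replicates,
    merged_labels,
    pairwise_auroc,
    reciprocal_best_hits,
)
from metaneighbor.synthetic import SyntheticConfig, generate
from metaneighbor.voting import run_metaneighbor


def matrix_from(scores: pd.DataFrame) -> PairwiseAUROCMatrix:
    study = pd.Series({q: q.split("|", 1)[0] for q in scores.index})
    return PairwiseAUROCMatrix(scores=scores, subtype_study=study)


def cross_matrix(block, studies=("A", "B"), names=("1", "2")):
    """Symmetric 2-study matrix with the given cross-study block."""
    ids = [f"{s}|t{n}" for s in studies for n in names]
    S = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            S.loc[f"A|t{a}", f"B|t{b}"] = block[i][j]
            S.loc[f"B|t{b}", f"A|t{a}"] = block[i][j]
    S.values[np.eye(len(ids), dtype=bool)] = 1.0
    return matrix_from(S)


class TestRBH:
    def test_two_by_two_block(self):
        matrix = cross_matrix([[0.96, 0.60], [0.55, 0.80]])
        rbh = reciprocal_best_hits(matrix)
        pairs = set(zip(rbh["subtype_a"], rbh["subtype_b"]))
        assert pairs == {("A|t1", "B|t1"), ("A|t2", "B|t2")}
        assert not rbh["tie"].any()

    def test_unreciprocated_best_is_dropped(self):
        # A|t1's best is B|t1, but B|t1 prefers A|t2
        matrix = cross_matrix([[0.90, 0.60], [0.95, 0.95]])
        rbh = reciprocal_best_hits(matrix)
        pairs = set(zip(rbh["subtype_a"], rbh["subtype_b"]))
        assert ("A|t1", "B|t1") not in pairs
        assert ("A|t2", "B|t1") in pairs or ("A|t2", "B|t2") in pairs

    def test_all_equal_scores_flag_ties(self):
        matrix = cross_matrix([[0.7, 0.7], [0.7, 0.7]])
        rbh = reciprocal_best_hits(matrix)
        assert len(rbh) == 4
        assert rbh["tie"].all()

    def test_invariant_to_permutation(self):
        matrix = cross_matrix([[0.96, 0.60], [0.55, 0.80]])
        perm = list(matrix.scores.index[::-1])
        permuted = matrix_from(matrix.scores.loc[perm, perm])
        a = reciprocal_best_hits(matrix).sort_values("subtype_a", ignore_index=True)
        b = reciprocal_best_hits(permuted).sort_values("subtype_a", ignore_index=True)
        pd.testing.assert_frame_equal(a, b)


class TestIdentifyReplicates:
    def test_chained_edges_form_one_group(self):
        ids = ["A|x", "B|y", "C|z"]
        S = pd.DataFrame(
            [[1.0, 0.96, 0.5], [0.96, 1.0, 0.97], [0.5, 0.97, 1.0]],
            index=ids, columns=ids,
        )
        groups = identify_replicates(matrix_from(S), threshold=0.95)
        assert len(groups) == 1
        assert groups[0].members == ids
        assert groups[0].studies() == {"A", "B", "C"}

    def test_vacuous_threshold_keeps_only_rbh(self):
        matrix = cross_matrix([[0.96, 0.60], [0.55, 0.80]])
        groups = identify_replicates(matrix, threshold=1.01)
        assert {tuple(g.members) for g in groups} == {
            ("A|t1", "B|t1"), ("A|t2", "B|t2"),
        }

    def test_monotone_in_threshold(self):
        matrix = cross_matrix([[0.96, 0.955], [0.55, 0.80]])
        strict_members = {
            m for g in identify_replicates(matrix, threshold=0.99) for m in g.members
        }
        loose_members = {
            m for g in identify_replicates(matrix, threshold=0.95) for m in g.members
        }
        assert strict_members <= loose_members

    def test_perfect_correspondence_synthetic(self):
        config = SyntheticConfig(seed=13, n_studies=2, effect_size=3.0)
        studies, metadata, markers = generate(config)
        merged = merge_on_gene_universe(studies, metadata=metadata)
        gene_set = markers["type_1"] + markers["type_2"]
        matrix = pairwise_auroc(merged, gene_set, seed=0)
        cross = matrix.scores.loc[
            ["study_1|type_1", "study_1|type_2"],
            ["study_2|type_1", "study_2|type_2"],
        ].to_numpy()
        assert cross[0, 0] > 0.95 and cross[1, 1] > 0.95
        assert cross[0, 1] < 0.5 and cross[1, 0] < 0.5
        groups = identify_replicates(matrix)
        assert {tuple(g.members) for g in groups} == {
            ("study_1|type_1", "study_2|type_1"),
            ("study_1|type_2", "study_2|type_2"),
        }

    def test_within_study_entries_filled_by_cv(self, strong_signal):
        _, _, markers, merged = strong_signal
        matrix = pairwise_auroc(merged, markers["type_1"] + markers["type_2"])
        within = matrix.within_study_mask().to_numpy()
        assert np.isfinite(matrix.scores.to_numpy()[within]).all()
        # same-type diagonal is 1 by definition
        assert (np.diag(matrix.scores.to_numpy()) == 1.0).all()


class TestMergedLabels:
    def test_group_members_share_label(self, strong_signal):
        _, _, _, merged = strong_signal
        group = ReplicateGroup(
            "combined", ["study_1|type_1", "study_2|type_1", "study_3|type_1"]
        )
        out = merged_labels([group], merged.annotations)
        relabeled = out["cell_type"] == "combined"
        assert relabeled.sum() == (merged.annotations["cell_type"] == "type_1").sum()
        assert (out.loc[~relabeled, "cell_type"] == "type_2").all()

    def test_empty_groups_identity(self, strong_signal):
        _, _, _, merged = strong_signal
        out = merged_labels([], merged.annotations)
        pd.testing.assert_frame_equal(out, merged.annotations)

    def test_overlapping_groups_rejected(self, strong_signal):
        _, _, _, merged = strong_signal
        groups = [
            ReplicateGroup("g1", ["study_1|type_1", "study_2|type_1"]),
            ReplicateGroup("g2", ["study_2|type_1", "study_3|type_1"]),
        ]
        with pytest.raises(ValueError, match="more than one group"):
            merged_labels(groups, merged.annotations)

    def test_relabeled_experiment_scores_one_auroc_per_group(self, strong_signal):
        _, _, markers, merged = strong_signal
        groups = [
            ReplicateGroup("combined_1",
                           [f"study_{s}|type_1" for s in (1, 2, 3)]),
            ReplicateGroup("combined_2",
                           [f"study_{s}|type_2" for s in (1, 2, 3)]),
        ]
        relabeled = merged_labels(groups, merged.annotations)
        remerged = type(merged)(data=merged.data, annotations=relabeled)
        reports = run_metaneighbor(
            remerged, [("m", markers["type_1"] + markers["type_2"])]
        )
        assert list(reports[0].mean_aurocs.index) == ["combined_1", "combined_2"]
        assert reports[0].mean_aurocs.min() > 0.99


def test_planted_correspondence_recovered_with_hvg(strong_signal):
    studies, _, _, merged = strong_signal
    gene_set = select_hvg(studies, combine="majority")
    groups = identify_replicates(pairwise_auroc(merged, gene_set, seed=1))
    expected = {
        tuple(f"study_{s}|type_{k}" for s in (1, 2, 3)) for k in (1, 2)
    }
    assert {tuple(g.members) for g in groups} == expected
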
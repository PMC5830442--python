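import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaneighbor.io import merge_on_gene_universe
from metaneighbor.synthetic import SyntheticConfig, generate
from metaneighbor.voting import (
    analytic_auroc,
    neighbor_vote,
    node_degree,
    reports_to_long,
    run_metaneighbor,
)


def brute_force_auroc(scores, positives):
    """Oracle: fraction of (positive, negative) pairs where the positive
    outranks the negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[positives]
    neg = scores[~np.asarray(positives)]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestNodeDegree:
    def test_row_sum(self):
        W = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.5], [0.2, 0.5, 1.0]])
        np.testing.assert_allclose(node_degree(W), [2.0, 2.3, 1.7])

    def test_constant_network(self):
        W = np.full((4, 4), 0.25)
        np.testing.assert_allclose(node_degree(W), [1.0] * 4)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        W = rng.random((4, 4))
        W = (W + W.T) / 2
        expected = [sum(W[i, j] for j in range(4)) for i in range(4)]
        np.testing.assert_allclose(node_degree(W), expected)


class TestNeighborVote:
    def test_hand_computed_score(self):
        # cell 0's weights (self first) 0.5,0.9,0.7,0.3,0.1; neighbors 1 and 2
        # labeled -> (0.9+0.7)/2.5 = 0.64
        row = np.array([0.5, 0.9, 0.7, 0.3, 0.1])
        W = np.vstack([row, np.tile(row, (4, 1))])  # only row 0 matters
        labels = np.array([0, 1, 1, 0, 0], dtype=float)
        assert neighbor_vote(W, labels)[0] == pytest.approx(0.64)

    @pytest.mark.parametrize("fill,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_saturated_labels(self, fill, expected):
        rng = np.random.default_rng(1)
        W = rng.random((6, 6))
        W = (W + W.T) / 2
        scores = neighbor_vote(W, np.full(6, fill))
        np.testing.assert_allclose(scores, expected)


class TestAnalyticAUROC:
    @pytest.mark.parametrize(
        "scores,pos,expected",
        [
            ([0.1, 0.2, 0.3, 0.4], [2, 3], 1.0),  # positives ranked 3,4
            ([0.1, 0.2, 0.3, 0.4], [0, 1], 0.0),  # positives ranked 1,2
            ([0.1, 0.2, 0.3, 0.4], [1, 3], 0.75),  # positives ranked 2,4
        ],
    )
    def test_rank_examples(self, scores, pos, expected):
        assert analytic_auroc(np.array(scores), pos) == pytest.approx(expected)

    def test_undefined_without_both_classes(self):
        assert np.isnan(analytic_auroc(np.array([1.0, 2.0]), [0, 1]))
        assert np.isnan(analytic_auroc(np.array([1.0, 2.0]), []))

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = rng.integers(3, 50)
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            pos = np.zeros(n, dtype=bool)
            pos[rng.choice(n, rng.integers(1, n), replace=False)] = True
            if pos.all():
                pos[0] = False
            assert analytic_auroc(scores, pos) == pytest.approx(
                brute_force_auroc(scores, pos), abs=1e-12
            )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False, width=16), min_size=4,
                 max_size=20),
        st.integers(1, 10),
    )
    def test_complement_symmetry(self, scores, k):
        scores = np.array(scores)
        pos = np.zeros(len(scores), dtype=bool)
        pos[: min(k, len(scores) - 1)] = True
        assert analytic_auroc(scores, pos) + analytic_auroc(scores, ~pos) == (
            pytest.approx(1.0)
        )


class TestRunMetaneighbor:
    def test_requires_two_studies(self, strong_signal):
        studies, metadata, _, _ = strong_signal
        single = merge_on_gene_universe(studies[:1], metadata=metadata)
        with pytest.raises(ValueError, match=">=2 studies"):
            run_metaneighbor(single, [("x", ["g0001", "g0002"])])

    def test_perfect_separation_on_strong_signal(self, strong_signal):
        _, _, markers, merged = strong_signal
        genes = markers["type_1"] + markers["type_2"]
        reports = run_metaneighbor(merged, [("markers", genes)])
        assert reports[0].mean_aurocs.min() > 0.99

    def test_fold_missing_when_no_negatives(self, strong_signal):
        studies, metadata, markers, _ = strong_signal
        # study_3 keeps only type_1 cells -> no negatives in that fold
        meta = metadata[
            (metadata["study_id"] != "study_3") | (metadata["cell_type"] == "type_1")
        ]
        keep_cells = set(meta["study_id"] + "|" + meta["cell_id"])
        merged = merge_on_gene_universe(studies, metadata=meta)
        merged = merged.subset_cells(
            merged.annotations.index.isin(keep_cells).astype(bool)
        )
        reports = run_metaneighbor(
            merged, [("m", markers["type_1"])], cell_types=["type_1"]
        )
        folds = reports[0].fold_frame()
        fold3 = folds[folds["test_study"] == "study_3"]
        assert fold3["auroc"].isna().all()
        assert not np.isnan(reports[0].mean_aurocs["type_1"])

    def test_hidden_labels_do_not_leak(self, strong_signal):
        # the held-out fold's voting scores must be reproducible from
        # training-study labels alone: recompute the study_1 fold with
        # neighbor_vote fed only study_2/study_3 labels and match the
        # pipeline's reported AUROC exactly
        from metaneighbor.network import build_network

        _, _, markers, merged = strong_signal
        genes = markers["type_1"]
        report = run_metaneighbor(merged, [("m", genes)], ["type_1"])[0]
        fold = report.fold_frame().query("test_study == 'study_1'")
        network = build_network(merged, genes)
        ann = merged.annotations
        train_labels = (
            (ann["cell_type"] == "type_1") & (ann["study_id"] != "study_1")
        ).to_numpy(dtype=float)
        votes = neighbor_vote(network, train_labels)
        test_mask = (ann["study_id"] == "study_1").to_numpy()
        expected = analytic_auroc(
            votes[test_mask], (ann["cell_type"] == "type_1").to_numpy()[test_mask]
        )
        assert fold["auroc"].iloc[0] == expected

    def test_rank_invariance_bit_identical(self, strong_signal):
        studies, metadata, markers, merged = strong_signal
        genes = [("m", markers["type_1"] + markers["type_2"])]
        transformed = merged.subset_cells(np.ones(merged.n_cells, dtype=bool))
        transformed.data = np.log2(merged.data + 1)
        a = reports_to_long(run_metaneighbor(merged, genes))
        b = reports_to_long(run_metaneighbor(transformed, genes))
        pd.testing.assert_frame_equal(a, b)

    def test_null_labels_score_near_chance(self):
        from metaneighbor.gene_sets import random_sets_matched
        from metaneighbor.synthetic import shuffle_labels

        config = SyntheticConfig(seed=21, n_genes=300, cells_per_type_per_study=30)
        studies, metadata, _ = generate(config)
        merged = merge_on_gene_universe(
            studies, metadata=shuffle_labels(metadata, seed=22)
        )
        sets = random_sets_matched([100] * 20, merged.gene_universe, 20, seed=23)
        reports = run_metaneighbor(merged, sets)
        grand = np.nanmean(
            np.concatenate([r.mean_aurocs.to_numpy() for r in reports])
        )
        assert 0.4 < grand < 0.6
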
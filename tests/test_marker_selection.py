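from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from leukomet import (
    CentroidModel,
    classify,
    fit_centroids,
    select_markers,
    shrink,
    simulate_reference,
    SimulationConfig,
)

from .conftest import make_matrix
from .oracles import naive_classify, naive_nsc, naive_shrink

SQRT2 = np.sqrt(2.0)


def two_class_model() -> CentroidModel:
    """1 gene; class A samples [0, 2], class B samples [4, 6]."""
    m = make_matrix(
        [[0.0, 2.0, 4.0, 6.0]],
        sample_ids=["a1", "a2", "b1", "b2"],
        labels={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )
    return fit_centroids(m)


class TestFitCentroids:
    def test_hand_worked_two_class_example(self):
        model = two_class_model()
        assert model.classes == ["A", "B"]
        np.testing.assert_allclose(model.class_centroids, [[1.0, 5.0]])
        np.testing.assert_allclose(model.overall_centroid, [3.0])
        np.testing.assert_allclose(model.pooled_sd, [SQRT2])
        assert model.s0 == pytest.approx(SQRT2)
        np.testing.assert_allclose(model.m_k, [0.5, 0.5])
        np.testing.assert_allclose(model.d_stats, [[-SQRT2, SQRT2]], atol=1e-12)

    def test_constant_gene_has_zero_d_when_s0_positive(self):
        m = make_matrix(
            [[0.0, 2.0, 4.0, 6.0], [1.0, 1.0, 1.0, 1.0]],
            labels=dict(zip(["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"])),
        )
        model = fit_centroids(m)
        np.testing.assert_array_equal(model.d_stats[1], [0.0, 0.0])

    def test_centroids_consistent_with_overall_mean(self, fitted_reference):
        model = fitted_reference.model
        weighted = (model.class_centroids * model.class_sizes).sum(axis=1)
        np.testing.assert_allclose(
            weighted / model.class_sizes.sum(), model.overall_centroid, atol=1e-8
        )

    def test_matches_loop_oracle_on_six_class_reference(self):
        sim = simulate_reference(SimulationConfig(n_genes=200, markers_per_class=30), seed=3)
        model = fit_centroids(sim.matrix)
        labels = [sim.labels[s] for s in sim.matrix.sample_ids]
        oracle = naive_nsc(sim.matrix.values, labels)
        assert model.classes == oracle["classes"]
        np.testing.assert_allclose(model.d_stats, oracle["d"], atol=1e-10)
        np.testing.assert_allclose(model.pooled_sd, oracle["s"], atol=1e-10)
        assert model.s0 == pytest.approx(oracle["s0"], abs=1e-10)

    def test_small_class_and_unlabeled_sample_rejected(self):
        m = make_matrix(
            np.zeros((2, 3)),
            labels={"s1": "A", "s2": "A", "s3": "B"},
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_centroids(m)
        with pytest.raises(ValueError, match="unlabeled"):
            fit_centroids(make_matrix(np.zeros((2, 3))), {"s1": "A", "s2": "A"})

    @given(st.floats(-50, 50))
    def test_constant_shift_of_one_gene_leaves_d_unchanged(self, c):
        base = two_class_model()
        shifted = fit_centroids(
            make_matrix(
                [[0.0 + c, 2.0 + c, 4.0 + c, 6.0 + c]],
                sample_ids=["a1", "a2", "b1", "b2"],
                labels={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            )
        )
        np.testing.assert_allclose(shifted.d_stats, base.d_stats, atol=1e-10)


class TestShrink:
    def test_zero_delta_is_identity(self):
        model = two_class_model()
        out = shrink(model, 0.0)
        np.testing.assert_array_equal(out.d_stats, model.d_stats)
        np.testing.assert_array_equal(out.class_centroids, model.class_centroids)

    def test_soft_threshold_subtracts_delta(self):
        out = shrink(two_class_model(), 1.0)
        np.testing.assert_allclose(out.d_stats, [[-(SQRT2 - 1), SQRT2 - 1]], atol=1e-12)

    def test_full_shrinkage_collapses_centroids_to_overall(self):
        model = two_class_model()
        out = shrink(model, float(np.abs(model.d_stats).max()))
        np.testing.assert_array_equal(out.d_stats, [[0.0, 0.0]])
        np.testing.assert_allclose(
            out.class_centroids, np.tile(model.overall_centroid[:, None], (1, 2))
        )

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            shrink(two_class_model(), -0.1)

    def test_matches_loop_oracle(self):
        sim = simulate_reference(SimulationConfig(n_genes=100, markers_per_class=12), seed=5)
        model = fit_centroids(sim.matrix)
        labels = [sim.labels[s] for s in sim.matrix.sample_ids]
        oracle = naive_nsc(sim.matrix.values, labels)
        d_shr, cents = naive_shrink(oracle, 0.8)
        out = shrink(model, 0.8)
        np.testing.assert_allclose(out.d_stats, d_shr, atol=1e-10)
        np.testing.assert_allclose(out.class_centroids, cents, atol=1e-10)

    @given(st.floats(0, 3), st.floats(0, 3))
    def test_shrinkage_magnitude_monotone_in_delta(self, d1, d2):
        model = fit_centroids(
            simulate_reference(SimulationConfig(n_genes=40, markers_per_class=5), seed=9).matrix
        )
        lo, hi = sorted([d1, d2])
        assert (
            np.abs(shrink(model, hi).d_stats) <= np.abs(shrink(model, lo).d_stats) + 1e-12
        ).all()


class TestSelectMarkers:
    def test_default_reference_yields_disjoint_panels_of_k(self, fitted_reference):
        panel = fitted_reference.panel
        assert all(len(genes) == 25 for genes in panel.panels.values())
        assert len(set(panel.all_genes)) == 150

    def test_k_one_picks_argmax_of_signed_d(self):
        sim = simulate_reference(SimulationConfig(n_genes=60, markers_per_class=8), seed=2)
        model = fit_centroids(sim.matrix)
        panel = select_markers(model, k=1)
        for j, cls in enumerate(model.classes):
            order = np.argsort(-model.d_stats[:, j], kind="stable")
            # the class's top gene may have been claimed by an earlier class
            claimed = {panel.panels[c][0] for c in model.classes[:j]}
            expected = next(
                model.gene_ids[i] for i in order if model.gene_ids[i] not in claimed
            )
            assert panel.panels[cls] == [expected]

    def test_exact_d_ties_rank_lexicographically(self):
        # two genes with identical values hence identical d for every class
        m = make_matrix(
            [[0.0, 2.0, 4.0, 6.0], [0.0, 2.0, 4.0, 6.0], [1.0, 0.0, 1.0, 0.0]],
            gene_ids=["gB", "gA", "gC"],
            labels=dict(zip(["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"])),
        )
        panel = select_markers(fit_centroids(m), k=1)
        assert panel.panels["B"] == ["gA"]

    def test_insufficient_genes_error_states_deficit(self):
        model = two_class_model()
        with pytest.raises(ValueError, match="need 4 genes"):
            select_markers(model, k=2)

    def test_abs_ranking_can_pick_down_regulated_genes(self):
        m = make_matrix(
            [[10.0, 12.0, 0.0, 1.0], [6.0, 4.0, 2.0, 0.0], [0.1, 0.0, 0.1, 0.0]],
            gene_ids=["upA", "down", "flat"],
            labels=dict(zip(["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"])),
        )
        # class A claims "upA" in both modes; B's best by |d| is the
        # down-regulated gene, by signed d the flat one
        model = fit_centroids(m)
        assert select_markers(model, k=1, rank="abs").panels["B"] == ["down"]
        assert select_markers(model, k=1, rank="signed").panels["B"] == ["flat"]


class TestClassify:
    def test_sample_at_class_centroid_wins(self, fitted_reference):
        model = fitted_reference.model
        for j, cls in enumerate(model.classes):
            label, _ = classify(model, model.class_centroids[:, j])
            assert label == cls

    def test_full_shrinkage_ties_resolve_to_first_class(self):
        model = two_class_model()
        collapsed = shrink(model, float(np.abs(model.d_stats).max()) + 1.0)
        label, scores = classify(collapsed, [10.0])
        assert label == "A"
        assert scores[0] == pytest.approx(scores[1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="model expects"):
            classify(two_class_model(), [1.0, 2.0])

    def test_training_set_predictions_match_loop_oracle(self):
        sim = simulate_reference(SimulationConfig(n_genes=150, markers_per_class=20), seed=13)
        model = fit_centroids(sim.matrix)
        for j, sid in enumerate(sim.matrix.sample_ids):
            x = sim.matrix.values[:, j]
            label, scores = classify(model, x)
            k, oracle_scores = naive_classify(
                x, model.class_centroids, model.pooled_sd, model.s0, model.priors
            )
            assert label == model.classes[k]
            np.testing.assert_allclose(scores, oracle_scores, rtol=1e-10)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path, fitted_reference):
        model = fitted_reference.model
        path = tmp_path / "model.json"
        model.to_json(path)
        back = CentroidModel.from_json(path)
        assert back.classes == model.classes
        np.testing.assert_array_equal(back.d_stats, model.d_stats)
        np.testing.assert_array_equal(back.class_centroids, model.class_centroids)
        assert back.s0 == model.s0
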
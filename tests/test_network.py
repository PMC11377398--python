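"""Sparse-net structure, forward pass, gradients, training and gene ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from genesieve.association import TopologyMap
from genesieve.network import (
    SparseGeneNetParams,
    TrainConfig,
    build_model,
    forward,
    gene_importances,
    loss_and_gradients,
    top_gene_list,
    train,
)
from genesieve.pipeline import compute_auc, stratified_split
from genesieve.synthetic import contiguous_topology


def zero_params(topo):
    p = build_model(topo, TrainConfig(), seed=0)
    p.variant_weights[:] = 0
    p.gene_output_weights[:] = 0
    return p


class TestStructure:
    @pytest.mark.parametrize(
        "n_v,n_g,expected",
        [(1, 1, 4), (5, 2, 10), (18_970, 9_160, 37_291)],
    )
    def test_parameter_count_formula(self, n_v, n_g, expected):
        topo = contiguous_topology(n_v, n_g)
        params = build_model(topo, TrainConfig(), seed=0)
        assert params.n_parameters == expected == n_v + 2 * n_g + 1

    def test_parameter_count_on_random_topologies(self, rng):
        for _ in range(100):
            n_g = int(rng.integers(1, 20))
            n_v = int(rng.integers(n_g, 80))
            topo = contiguous_topology(n_v, n_g, permute=True,
                                       seed=int(rng.integers(2**31)))
            params = build_model(topo, TrainConfig(), seed=1)
            assert params.n_parameters == n_v + 2 * n_g + 1

    def test_empty_topology_rejected(self):
        with pytest.raises(ValueError):
            TopologyMap(pd.DataFrame(columns=list(TopologyMap.COLUMNS)))


class TestForward:
    def test_all_zero_parameters_score_half(self):
        topo = contiguous_topology(6, 3)
        p = zero_params(topo)
        scores = forward(p, np.ones((4, 6)))
        assert np.allclose(scores, 0.5)

    def test_closed_form_single_path(self):
        # one variant, one gene, all weights 1, x = 2 -> sigmoid(2)
        topo = contiguous_topology(1, 1)
        p = zero_params(topo)
        p.variant_weights[:] = 1.0
        p.gene_output_weights[:] = 1.0
        score = forward(p, np.array([[2.0]]))
        assert score[0] == pytest.approx(expit(2.0), rel=1e-12)

    def test_scores_strictly_inside_unit_interval(self, rng):
        topo = contiguous_topology(8, 4)
        p = build_model(topo, TrainConfig(init_scale=5.0), seed=2)
        s = forward(p, rng.integers(0, 3, size=(50, 8)).astype(float))
        assert (s > 0).all() and (s < 1).all()

    def test_genes_with_zero_output_weight_are_inert(self, rng):
        topo = contiguous_topology(10, 5)
        p = build_model(topo, TrainConfig(), seed=3)
        p.gene_output_weights[2] = 0.0
        X = rng.integers(0, 3, size=(20, 10)).astype(float)
        base = forward(p, X)
        X2 = X.copy()
        X2[:, topo.gene_index == 2] += 1.0  # perturb only gene 2's variants
        assert np.allclose(forward(p, X2), base)

    def test_monotone_in_variant_on_positive_path(self):
        topo = contiguous_topology(3, 1)
        p = zero_params(topo)
        p.variant_weights[:] = 0.5
        p.gene_output_weights[:] = 1.0
        X = np.zeros((3, 3))
        X[:, 0] = [0, 1, 2]
        s = forward(p, X)
        assert s[0] < s[1] < s[2]

    def test_dimension_mismatch_fails(self):
        topo = contiguous_topology(4, 2)
        p = build_model(topo, TrainConfig(), seed=0)
        with pytest.raises(ValueError):
            forward(p, np.zeros((2, 5)))


class TestGradients:
    @pytest.mark.parametrize("activation", ["linear", "tanh"])
    def test_finite_difference_agreement(self, activation, rng):
        topo = contiguous_topology(10, 4)
        p = build_model(topo, TrainConfig(init_scale=0.3), seed=5)
        p.gene_biases[:] = rng.normal(0, 0.3, 4)
        X = rng.integers(0, 3, size=(12, 10)).astype(float)
        y = rng.integers(0, 2, size=12).astype(float)
        loss, grads = loss_and_gradients(p, X, y, activation)
        eps = 1e-6

        def numeric(attr, idx=None):
            q = p.copy()
            if attr == "output_bias":
                q.output_bias += eps
            else:
                getattr(q, attr)[idx] += eps
            lp, _ = loss_and_gradients(q, X, y, activation)
            return (lp - loss) / eps

        for v in range(10):
            assert numeric("variant_weights", v) == pytest.approx(
                grads["w"][v], rel=1e-4, abs=1e-7)
        for g in range(4):
            assert numeric("gene_biases", g) == pytest.approx(
                grads["b"][g], rel=1e-4, abs=1e-7)
            assert numeric("gene_output_weights", g) == pytest.approx(
                grads["u"][g], rel=1e-4, abs=1e-7)
        assert numeric("output_bias") == pytest.approx(grads["c"], rel=1e-4, abs=1e-7)

    def test_gradient_sparsity_silenced_gene(self, rng):
        # zero output weight on gene g kills the gradient of g's variants
        topo = contiguous_topology(10, 5)
        p = build_model(topo, TrainConfig(), seed=6)
        p.gene_output_weights[3] = 0.0
        X = rng.integers(0, 3, size=(15, 10)).astype(float)
        y = rng.integers(0, 2, size=15).astype(float)
        _, grads = loss_and_gradients(p, X, y)
        on_gene3 = topo.gene_index == 3
        assert np.allclose(grads["w"][on_gene3], 0.0)
        assert not np.allclose(grads["w"][~on_gene3], 0.0)


class TestTraining:
    def _separable(self):
        # 20 samples, 4 variants: variant 0 perfectly tags the class
        y = np.array([0] * 10 + [1] * 10, float)
        X = np.zeros((20, 4))
        X[y == 1, 0] = 2.0
        X[:, 1:] = np.tile([[1, 0, 1]], (20, 1))
        return X, y

    def test_separable_toy_reaches_perfect_accuracy(self):
        X, y = self._separable()
        topo = contiguous_topology(4, 2)
        cfg = TrainConfig(max_epochs=200, learning_rate=0.05, batch_size=8, seed=1)
        params, hist = train(build_model(topo, cfg), X, y, cfg)
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert (((forward(params, X) >= 0.5) == y.astype(bool)).all())

    def test_same_seed_bit_identical_history(self):
        X, y = self._separable()
        topo = contiguous_topology(4, 2)
        cfg = TrainConfig(max_epochs=20, seed=7)
        _, h1 = train(build_model(topo, cfg), X, y, cfg)
        _, h2 = train(build_model(topo, cfg), X, y, cfg)
        assert h1["train_loss"] == h2["train_loss"]

    def test_single_class_rejected(self):
        topo = contiguous_topology(4, 2)
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            train(build_model(topo, cfg), np.zeros((5, 4)), np.ones(5), cfg)

    def test_early_stopping_halts_and_restores_best(self, small_cohort, rng):
        X = small_cohort.genotypes.values.astype(float)
        y = small_cohort.truth.observed_label.astype(float)
        tr, va, _ = stratified_split(y, seed=0)
        cfg = TrainConfig(max_epochs=200, early_stopping=True, patience=5, seed=2)
        params, hist = train(build_model(small_cohort.topology, cfg),
                             X[tr], y[tr], cfg, validation=(X[va], y[va]))
        assert len(hist["val_loss"]) < 200
        best = min(hist["val_loss"])
        from genesieve.network import _bce
        assert _bce(forward(params, X[va]), y[va]) == pytest.approx(best, abs=1e-9)

    def test_label_permutation_gives_chance_level_auc(self, small_cohort, rng):
        X = small_cohort.genotypes.values.astype(float)
        y = rng.permutation(small_cohort.truth.observed_label).astype(float)
        tr, _, te = stratified_split(y, seed=1)
        cfg = TrainConfig(max_epochs=30, seed=3)
        params, _ = train(build_model(small_cohort.topology, cfg), X[tr], y[tr], cfg)
        auc = compute_auc(forward(params, X[te]), y[te])
        assert 0.40 <= auc <= 0.60


class TestGeneImportances:
    def _params(self, topo, weights):
        p = build_model(topo, TrainConfig(), seed=0)
        p.gene_output_weights = np.asarray(weights, float)
        return p

    def test_single_model_means_equal_its_weights(self):
        topo = contiguous_topology(6, 3)
        p = self._params(topo, [0.5, -1.0, 2.0])
        imp = gene_importances([p], k=2)
        by_gene = imp.set_index("gene_id")["mean_weight"]
        assert by_gene[topo.gene_ids[2]] == 2.0
        assert imp.iloc[0]["gene_id"] == topo.gene_ids[2]

    def test_opposite_models_cancel_unless_magnitude(self):
        topo = contiguous_topology(6, 3)
        a = self._params(topo, [1.0, -2.0, 0.5])
        b = self._params(topo, [-1.0, 2.0, -0.5])
        assert (gene_importances([a, b], k=1)["mean_weight"] == 0).all()
        mag = gene_importances([a, b], k=1, magnitude=True)
        assert mag.iloc[0]["mean_weight"] == 2.0

    def test_mismatched_topologies_rejected(self):
        a = build_model(contiguous_topology(6, 3), TrainConfig(), seed=0)
        b = build_model(contiguous_topology(6, 2), TrainConfig(), seed=0)
        with pytest.raises(ValueError):
            gene_importances([a, b])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            gene_importances([])

    def test_top_gene_list_matches_rank_order(self):
        topo = contiguous_topology(6, 3)
        p = self._params(topo, [3.0, 1.0, 2.0])
        imp = gene_importances([p], k=3)
        top = top_gene_list(imp, k=2)
        assert top == [topo.gene_ids[0], topo.gene_ids[2]]
        with pytest.raises(ValueError):
            top_gene_list(imp, k=4)

    def test_ties_break_by_gene_id(self):
        topo = contiguous_topology(4, 2)
        p = self._params(topo, [1.0, 1.0])
        imp = gene_importances([p], k=1)
        assert imp.iloc[0]["gene_id"] == sorted(topo.gene_ids)[0]
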
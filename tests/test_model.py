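"""The GCN scorer: initialization, the convolution operator, gradients,
invariances, the multi-task loss, fold assignment, and the target sampler."""

import math

import numpy as np
import pytest

from atomscreen.complexes import FEATURE_DIM, Atom3D, ComplexPose, build_complex_graph
from atomscreen.model import (
    GCNPotencyRegressor,
    ComplexGCNScorer,
    BlockSpec,
    GNNConfig,
    TrainingConfig,
    _backward_batch,
    _collate,
    _forward_batch,
    _loss_and_dlogits,
    assign_folds,
    forward,
    graph_conv_block,
    init_model,
    multitask_loss,
    prepare_graph,
    sample_training_targets,
)


def _random_pose(rng, n_ligand=8, n_receptor=12, spread=4.0):
    types = ["C.3", "C.ar", "N.3", "O.3", "O.2", "S.3"]
    lig = [
        Atom3D("C", rng.uniform(-spread / 2, spread / 2, 3), "ligand", types[rng.integers(len(types))])
        for _ in range(n_ligand)
    ]
    rec = [
        Atom3D("C", rng.uniform(-spread, spread, 3), "receptor", types[rng.integers(len(types))])
        for _ in range(n_receptor)
    ]
    return ComplexPose(ligand_atoms=lig, receptor_atoms=rec, pose_id="toy")


class TestInit:
    def test_same_seed_bit_identical(self):
        cfg = GNNConfig()
        a, b = init_model(cfg, 42), init_model(cfg, 42)
        assert np.array_equal(a["W_head"], b["W_head"])
        for pa, pb in zip(a["blocks"], b["blocks"]):
            for key in pa:
                assert np.array_equal(pa[key], pb[key])

    def test_block_output_widths_follow_spec(self):
        params = init_model(GNNConfig(), 0)
        widths = [p["W_self"].shape for p in params["blocks"]]
        assert widths == [
            (FEATURE_DIM, 64), (64, 64), (64, 128), (128, 128), (128, 128),
        ]
        assert params["W_head"].shape == (128, 3)

    def test_four_block_config_rejected(self):
        with pytest.raises(ValueError, match="five"):
            GNNConfig(blocks=tuple(GNNConfig().blocks[:4]))

    def test_last_block_must_be_ligand_only(self):
        blocks = list(GNNConfig().blocks)
        blocks[-1] = BlockSpec(7.0, 128, "all")
        with pytest.raises(ValueError, match="ligand-only"):
            GNNConfig(blocks=tuple(blocks))


class TestConvBlock:
    def _params(self, f_in, f_out, n_rbf=15):
        return {
            "W_self": np.zeros((f_in, f_out)),
            "W_nbr": np.zeros((f_in, f_out)),
            "b": np.zeros(f_out),
            "w_g": np.zeros(n_rbf),
            "b_g": np.zeros(1),
        }

    def test_zero_weights_zero_output(self):
        h = np.ones((4, 5))
        edges = {"src": np.array([0, 1]), "dst": np.array([1, 0]), "dist": np.array([2.0, 2.0])}
        out = graph_conv_block(h, edges, self._params(5, 3))
        assert np.all(out == 0.0)

    def test_isolated_node_sees_only_self_term(self):
        p = self._params(2, 2)
        p["W_self"] = np.array([[1.0, 0.5], [0.0, 2.0]])
        p["b"] = np.array([0.1, -0.2])
        h = np.array([[1.0, 2.0]])
        edges = {"src": np.array([], int), "dst": np.array([], int), "dist": np.array([])}
        out = graph_conv_block(h, edges, p)
        assert np.allclose(out, np.maximum(h @ p["W_self"] + p["b"], 0.0))

    def test_four_node_toy_matches_hand_loop(self):
        """Gated message sum recomputed with explicit per-node loops."""
        rng = np.random.default_rng(0)
        n, f_in, f_out, n_rbf = 4, 3, 2, 5
        p = {
            "W_self": rng.normal(size=(f_in, f_out)),
            "W_nbr": rng.normal(size=(f_in, f_out)),
            "b": rng.normal(size=f_out),
            "w_g": rng.normal(size=n_rbf),
            "b_g": rng.normal(size=1),
        }
        h = rng.normal(size=(n, f_in))
        src = np.array([0, 1, 1, 2, 3, 2])
        dst = np.array([1, 0, 2, 1, 2, 3])
        dist = rng.uniform(1.0, 4.0, size=6)
        centers = np.linspace(0.5, 2.5, n_rbf)
        width = 0.5
        edges = {"src": src, "dst": dst, "dist": dist}
        out = graph_conv_block(h, edges, p, rbf_centers=centers, rbf_width=width)
        for v in range(n):
            acc = h[v] @ p["W_self"] + p["b"]
            for e in range(len(src)):
                if dst[e] == v:
                    phi = np.exp(-((dist[e] - centers) ** 2) / (2 * width**2))
                    gate = phi @ p["w_g"] + p["b_g"][0]
                    acc = acc + gate * (h[src[e]] @ p["W_nbr"])
            assert np.allclose(out[v], np.maximum(acc, 0.0), atol=1e-12)

    def test_ligand_only_scope_zeroes_receptor_rows(self):
        p = self._params(2, 2)
        p["W_self"] = np.eye(2)
        p["b"] = np.array([1.0, 1.0])
        h = np.ones((3, 2))
        edges = {"src": np.array([], int), "dst": np.array([], int), "dist": np.array([])}
        mask = np.array([True, False, True])
        out = graph_conv_block(h, edges, p, scope="ligand-only", ligand_mask=mask)
        assert np.all(out[1] == 0.0) and np.all(out[0] > 0.0)


class TestForward:
    def test_bias_only_head(self):
        rng = np.random.default_rng(1)
        pose = _random_pose(rng)
        graph = build_complex_graph(pose)
        params = init_model(GNNConfig(), 0)
        params["W_head"][:] = 0.0
        params["b_head"][:] = [0.3, -0.7, 2.5]
        p_act, p_pose, dock = forward(params, graph)
        sigmoid = lambda z: 1.0 / (1.0 + math.exp(-z))
        assert p_act == pytest.approx(sigmoid(0.3), abs=1e-9)
        assert p_pose == pytest.approx(sigmoid(-0.7), abs=1e-9)
        assert dock == pytest.approx(2.5, abs=1e-9)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(2)
        pose = _random_pose(rng)
        params = init_model(GNNConfig(), 3)
        out1 = forward(params, build_complex_graph(pose))
        theta = 1.1
        rot = np.array(
            [[1, 0, 0], [0, np.cos(theta), -np.sin(theta)], [0, np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([5.0, -3.0, 2.0])
        moved = ComplexPose(
            ligand_atoms=[
                Atom3D(a.element, rot @ a.coords + shift, a.role, a.sybyl_type)
                for a in pose.ligand_atoms
            ],
            receptor_atoms=[
                Atom3D(a.element, rot @ a.coords + shift, a.role, a.sybyl_type)
                for a in pose.receptor_atoms
            ],
        )
        out2 = forward(params, build_complex_graph(moved))
        assert np.allclose(out1, out2, atol=1e-6)

    def test_atom_permutation_invariance(self):
        rng = np.random.default_rng(4)
        pose = _random_pose(rng)
        params = init_model(GNNConfig(), 5)
        out1 = forward(params, build_complex_graph(pose))
        lig = [pose.ligand_atoms[i] for i in rng.permutation(len(pose.ligand_atoms))]
        rec = [pose.receptor_atoms[i] for i in rng.permutation(len(pose.receptor_atoms))]
        out2 = forward(params, build_complex_graph(ComplexPose(ligand_atoms=lig, receptor_atoms=rec)))
        assert np.allclose(out1, out2, atol=1e-6)

    def test_missing_cutoff_edge_set_raises(self):
        rng = np.random.default_rng(6)
        graph = build_complex_graph(_random_pose(rng), cutoffs=(5.0,))
        with pytest.raises(ValueError, match="7.0"):
            forward(init_model(GNNConfig(), 0), graph)


class TestMultitaskLoss:
    def test_perfect_predictions_near_zero(self):
        preds = np.array([[1.0, 0.0, 2.0]])
        labels = np.array([[1.0, 0.0, 2.0]])
        assert multitask_loss(preds, labels) == pytest.approx(0.0, abs=1e-5)

    def test_coin_flip_probability_is_ln2(self):
        preds = np.array([[0.5, np.nan, np.nan]])
        labels = np.array([[1.0, np.nan, np.nan]])
        assert multitask_loss(preds, labels) == pytest.approx(math.log(2), abs=1e-9)

    def test_masked_dock_task_ignored(self):
        labels = np.array([[1.0, 1.0, np.nan]])
        a = multitask_loss(np.array([[0.8, 0.9, 5.0]]), labels)
        b = multitask_loss(np.array([[0.8, 0.9, -100.0]]), labels)
        assert a == pytest.approx(b)

    def test_all_masked_raises(self):
        with pytest.raises(ValueError, match="masked"):
            multitask_loss(np.array([[0.5, 0.5, 0.0]]), np.full((1, 3), np.nan))

    def test_weights_scale_terms(self):
        preds = np.array([[0.5, np.nan, np.nan]])
        labels = np.array([[1.0, np.nan, np.nan]])
        assert multitask_loss(preds, labels, weights=(2, 1, 1)) == pytest.approx(2 * math.log(2))


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        """Spot-check the hand-derived backward pass against central differences."""
        rng = np.random.default_rng(8)
        cfg = GNNConfig()
        graphs = [build_complex_graph(_random_pose(rng, 4, 5)) for _ in range(2)]
        batch = _collate([prepare_graph(g, cfg) for g in graphs])
        y = np.array([[1.0, 0.0, -3.0], [np.nan, 1.0, 2.0]])
        params = init_model(cfg, 9)

        def loss_of(p):
            logits, _ = _forward_batch(p, batch, cfg, 3)
            loss, _ = _loss_and_dlogits(logits, y, (1.0, 1.0, 1.0))
            return loss

        logits, fwd = _forward_batch(params, batch, cfg, 3)
        _, dlogits = _loss_and_dlogits(logits, y, (1.0, 1.0, 1.0))
        grads = _backward_batch(params, batch, cfg, fwd, dlogits)

        h = 1e-6
        checked = 0
        targets = [
            ("W_head", grads["W_head"], params["W_head"]),
            ("b_head", grads["b_head"], params["b_head"]),
        ]
        for bi in (0, 2, 4):
            for key in ("W_self", "W_nbr", "b", "w_g", "b_g"):
                targets.append((f"block{bi}.{key}", grads["blocks"][bi][key], params["blocks"][bi][key]))
        for name, g_analytic, arr in targets:
            flat = arr.reshape(-1)
            gflat = g_analytic.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp = loss_of(params)
                flat[idx] = orig - h
                lm = loss_of(params)
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert gflat[idx] == pytest.approx(fd, abs=1e-4, rel=1e-3), name
                checked += 1
        assert checked >= 30


class TestFolds:
    def test_identical_sequences_share_fold(self):
        seq = "MKVLAWQRST" * 6
        rng = np.random.default_rng(0)
        others = [
            ("x%d" % i, "".join("ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(0, 20, 60)))
            for i in range(6)
        ]
        folds = assign_folds([("a", seq), ("b", seq)] + others, k=6)
        assert folds["a"] == folds["b"]

    def test_equal_actives_balanced_packing(self):
        rng = np.random.default_rng(1)
        targets = [
            ("t%02d" % i, "".join("ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(0, 20, 80)))
            for i in range(12)
        ]
        folds = assign_folds(targets, k=6, active_counts={t: 10 for t, _ in targets})
        sizes = np.bincount(list(folds.values()), minlength=6)
        assert list(sizes) == [2] * 6

    def test_too_few_clusters_suggests_smaller_k(self):
        seq = "MKVLAWQRST" * 6
        with pytest.raises(ValueError, match="smaller k"):
            assign_folds([("a", seq), ("b", seq), ("c", seq[:-1] + "G")], k=6)


class TestSampler:
    def test_probabilities_proportional_to_actives(self):
        draws = sample_training_targets(["a", "b"], [3, 1], 8000, seed=0)
        frac_a = draws.count("a") / len(draws)
        assert frac_a == pytest.approx(0.75, abs=0.02)

    def test_zero_count_target_never_drawn(self):
        draws = sample_training_targets(["a", "b"], [5, 0], 1000, seed=1)
        assert "b" not in draws

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            sample_training_targets(["a"], [0], 10)

    def test_deterministic_given_seed(self):
        a = sample_training_targets(["x", "y", "z"], [1, 2, 3], 100, seed=7)
        b = sample_training_targets(["x", "y", "z"], [1, 2, 3], 100, seed=7)
        assert a == b


class TestTraining:
    def test_seeded_fit_reproducible(self, small_dataset):
        ds = small_dataset
        runs = []
        for _ in range(2):
            m = ComplexGCNScorer(epochs=1, random_state=5)
            m.fit(ds["graphs"], ds["y"], groups=ds["groups"])
            runs.append(m)
        assert runs[0].training_log_ == runs[1].training_log_
        assert np.array_equal(runs[0].params_["W_head"], runs[1].params_["W_head"])
        for a, b in zip(runs[0].params_["blocks"], runs[1].params_["blocks"]):
            assert np.array_equal(a["W_self"], b["W_self"])

    def test_loss_decreases_over_training(self, small_dataset):
        ds = small_dataset
        m = ComplexGCNScorer(epochs=4, random_state=2)
        m.fit(ds["graphs"], ds["y"], groups=ds["groups"])
        assert m.training_log_[-1] <= m.training_log_[0] * 1.05

    def test_predictions_deterministic_and_bounded(self, small_dataset):
        ds = small_dataset
        m = ComplexGCNScorer(epochs=1, random_state=3)
        m.fit(ds["graphs"], ds["y"], groups=ds["groups"])
        p1 = m.predict(ds["graphs"][:10])
        p2 = m.predict(ds["graphs"][:10])
        assert np.array_equal(p1, p2)
        assert ((p1[:, :2] >= 0) & (p1[:, :2] <= 1)).all()

    def test_sklearn_params_roundtrip(self):
        m = ComplexGCNScorer(epochs=3, learning_rate=0.01)
        clone_params = m.get_params()
        assert clone_params["epochs"] == 3
        m.set_params(epochs=5)
        assert m.epochs == 5

    def test_regressor_single_output(self, small_dataset):
        ds = small_dataset
        idx = np.flatnonzero(~np.isnan(ds["y"][:, 0]))[:60]
        graphs = [ds["graphs"][i] for i in idx]
        y = ds["y"][idx, 0] * 2.0 + 5.0  # fake potencies
        reg = GCNPotencyRegressor(epochs=2, random_state=0)
        reg.fit(graphs, y)
        preds = reg.predict(graphs)
        assert preds.shape == (60,)
        assert np.isfinite(preds).all()


class TestTrainingConfigValidation:
    def test_member_fold_count_coupled(self):
        with pytest.raises(ValueError):
            TrainingConfig(n_models=5, n_folds=6)
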
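import dataclasses

import numpy as np
import pytest

from pathformer._autodiff import Tensor, gather_matmul_sum
from pathformer.cohort_io import GdaTable, SignalingCohort, canonical_order
from pathformer.model import ModelConfig, PathFormerModel
from pathformer.sortpool import select_top_k

from conftest import make_sample
from oracles import oracle_forward


def build_model(cohort, gda, **overrides):
    cfg = ModelConfig(
        k=overrides.pop("k", 5),
        n_layers=overrides.pop("n_layers", 2),
        seed=overrides.pop("seed", 0),
        **overrides,
    )
    model = PathFormerModel(cohort, gda, cfg)
    model.transform.fit(cohort.samples)
    model.eval()
    return model


class TestOracleEquivalence:
    @pytest.mark.parametrize("qk_net", ["mlp", "gin"])
    @pytest.mark.parametrize("attn_scale", ["sqrt_d", "d"])
    def test_two_layer_forward_matches_loop_oracle(self, small_cohort, qk_net, attn_scale):
        """Production (batched, vectorized) forward equals an explicit-loop
        dense re-implementation of attention, FFN and readout to 1e-5."""
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda, qk_net=qk_net, attn_scale=attn_scale)
        for sample in cohort.samples[:4]:
            probs, _, _ = model.forward(sample)
            expected = oracle_forward(model, sample)
            np.testing.assert_allclose(probs, expected, atol=1e-5)

    def test_double_exp_flag_matches_oracle(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda, double_exp=True, qk_net="mlp")
        sample = cohort.samples[0]
        probs, _, _ = model.forward(sample)
        np.testing.assert_allclose(probs, oracle_forward(model, sample), atol=1e-5)


class TestAttention:
    def test_identical_rows_give_uniform_attention(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda, qk_net="mlp")
        layer = model.layers[0]
        k = 4
        z = Tensor(np.tile(np.random.default_rng(0).normal(size=(1, 1, model.cfg.d)), (1, k, 1)))
        p = Tensor(np.zeros((1, k, model.cfg.bound * len(cohort.universe))))
        att_s, v_hat = layer.attention(z, p, None)
        np.testing.assert_allclose(att_s.data, np.full((1, k, k), 1.0 / k), atol=1e-12)
        v = layer.v_proj(z).data
        np.testing.assert_allclose(v_hat.data, v.mean(axis=1, keepdims=True).repeat(k, 1), atol=1e-12)

    def test_single_gene_attention_is_identity(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda, qk_net="mlp")
        layer = model.layers[0]
        z = Tensor(np.random.default_rng(1).normal(size=(1, 1, model.cfg.d)))
        p = Tensor(np.zeros((1, 1, model.cfg.bound * len(cohort.universe))))
        att_s, v_hat = layer.attention(z, p, None)
        assert att_s.data == pytest.approx(1.0)
        np.testing.assert_allclose(v_hat.data, layer.v_proj(z).data, atol=1e-12)

    def test_attention_rows_stochastic_every_layer(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda)
        _, _, traces = model.forward_batch(cohort.samples[:6], want_traces=True)
        for trace in traces:
            assert len(trace.layers) == model.cfg.n_layers
            for att in trace.layers:
                assert att.shape == (model.cfg.k, model.cfg.k)
                np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-6)

    def test_ffn_with_zero_weights_is_residual_only(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda, qk_net="mlp")
        layer = model.layers[0]
        for lin in (layer.ffn1, layer.ffn2):
            lin.w.data[:] = 0.0
            lin.b.data[:] = 0.0
        x = Tensor(np.random.default_rng(2).normal(size=(2, 3, model.cfg.d)))
        np.testing.assert_allclose(layer.ffn(x, model._dropout).data, x.data, atol=1e-12)

    def test_multihead_rows_stochastic(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda, n_heads=4, qk_net="mlp")
        _, _, traces = model.forward_batch(cohort.samples[:2], want_traces=True)
        for att in traces[0].layers:
            np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-6)


class TestInitialFeatures:
    def test_input_dimension_is_one_plus_pathway_length(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda, bound=3)
        assert model.input_proj.w.shape == (1 + 3 * len(cohort.universe), model.cfg.d)

    def test_zero_inputs_give_projection_bias(self):
        universe_genes = ["A", "B"]
        cohort = SignalingCohort(
            universe=canonical_order(universe_genes),
            edges=frozenset(),
            samples=[make_sample("s", {"A": 0.0, "B": 0.0}, 0),
                     make_sample("t", {"A": 0.0, "B": 0.0}, 1)],
            class_names=["x", "y"],
        )
        model = build_model(cohort, GdaTable(scores={}), k=2, expr_transform="none")
        model.input_proj.b.data[:] = np.arange(model.cfg.d, dtype=float)
        z = model.initial_features(cohort.samples, ["A", "B"], np.zeros((2, 2 * 2)))
        for row in z.data.reshape(-1, model.cfg.d):
            np.testing.assert_allclose(row, model.input_proj.b.data, atol=1e-12)

    def test_same_inputs_same_rows(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda)
        s = cohort.samples[0]
        sub = select_top_k(model.selection, s)
        p = np.zeros((len(sub), model.cfg.bound * len(cohort.universe)))
        z1 = model.initial_features([s, s], sub, p)
        np.testing.assert_array_equal(z1.data[0], z1.data[1])

    def test_missing_expression_rejected(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda)
        bad = make_sample("bad", {"G0000": 1.0})
        with pytest.raises(KeyError, match="missing expression"):
            model.initial_features([bad], ["G0001"], np.zeros((1, model.cfg.bound * len(cohort.universe))))


class TestReadout:
    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(5)
        w = Tensor(rng.normal(size=(6, 3, 4)))
        o = Tensor(rng.normal(size=(2, 5, 4)))
        idx = np.array([4, 0, 2, 5, 1])
        z = gather_matmul_sum(w, idx, o).data
        perm = np.array([3, 1, 4, 0, 2])
        z_perm = gather_matmul_sum(w, idx[perm], Tensor(o.data[:, perm])).data
        np.testing.assert_allclose(z, z_perm, atol=1e-12)

    def test_single_gene_readout(self):
        rng = np.random.default_rng(6)
        w = Tensor(rng.normal(size=(3, 2, 4)))
        o = Tensor(rng.normal(size=(1, 1, 4)))
        z = gather_matmul_sum(w, np.array([1]), o).data[0]
        np.testing.assert_allclose(z, w.data[1] @ o.data[0, 0], atol=1e-12)

    def test_probabilities_sum_to_one(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda)
        probs, _, _ = model.forward_batch(cohort.samples)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-9)
        assert (probs.data >= 0).all()


class TestForward:
    def test_eval_mode_deterministic(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda)
        p1, _, _ = model.forward_batch(cohort.samples[:5])
        p2, _, _ = model.forward_batch(cohort.samples[:5])
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_layer_outputs_keep_shape(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda, n_layers=3)
        _, subsets, traces = model.forward_batch(cohort.samples[:1], want_traces=True)
        assert len(subsets[0]) == model.cfg.k
        assert all(att.shape == (model.cfg.k, model.cfg.k) for att in traces[0].layers)

    def test_untrained_model_near_chance(self, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda)
        acc = float(np.mean(model.predict(cohort.samples) == cohort.labels()))
        assert 0.3 <= acc <= 0.7

    def test_save_load_round_trip(self, tmp_path, small_cohort):
        cohort, gda, _ = small_cohort
        model = build_model(cohort, gda)
        before = model.forward_batch(cohort.samples[:4])[0].data
        model.save(tmp_path / "ckpt.npz")
        fresh = build_model(cohort, gda, seed=99)
        fresh.load_weights(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(fresh.forward_batch(cohort.samples[:4])[0].data, before)


class TestRelabelEquivariance:
    def test_gene_renaming_with_permuted_parameters_preserves_output(self, small_cohort):
        """Renaming all genes by an order-reversing bijection and permuting
        theta, readout rows and pathway-block input rows accordingly leaves
        predictions unchanged."""
        cohort, gda, _ = small_cohort
        n = len(cohort.universe)
        mapping = {g: f"Z{n - 1 - i:04d}" for i, g in enumerate(cohort.universe.genes)}

        renamed = SignalingCohort(
            universe=canonical_order([mapping[g] for g in cohort.universe.genes]),
            edges=frozenset(frozenset(mapping[g] for g in e) for e in cohort.edges),
            samples=[
                make_sample(s.sample_id, {mapping[g]: x for g, x in s.expression.items()}, s.label)
                for s in cohort.samples
            ],
            class_names=list(cohort.class_names),
        )
        gda2 = GdaTable(scores={mapping[g]: v for g, v in gda.scores.items()})

        model = build_model(cohort, gda, qk_net="mlp")
        rng = np.random.default_rng(7)
        model.selection.theta.data[:] = rng.normal(0, 1, n)
        model2 = build_model(renamed, gda2, qk_net="mlp")

        # permutation: position of mapping[g] in the renamed universe
        perm = np.array(
            [renamed.universe.h(mapping[g]) for g in cohort.universe.genes]
        )
        params1 = model.parameters()
        params2 = model2.parameters()
        for name, p in params1.items():
            params2[name].data[...] = p.data
        model2.selection.theta.data[perm] = model.selection.theta.data
        model2.selection.e[perm] = model.selection.e
        model2.readout_w.data[perm] = model.readout_w.data
        # permute pathway-block rows of every projection taking concat(., P)
        def permute_p_rows(w2, w1, offset):
            for d in range(model.cfg.bound):
                w2.data[offset + d * n + perm] = w1.data[offset + d * n :][: n]
        permute_p_rows(model2.input_proj.w, model.input_proj.w, 1)
        for l1, l2 in zip(model.layers, model2.layers):
            permute_p_rows(l2.q_net.fc1.w, l1.q_net.fc1.w, model.cfg.d)
            permute_p_rows(l2.k_net.fc1.w, l1.k_net.fc1.w, model.cfg.d)

        p1 = model.forward_batch(cohort.samples)[0].data
        p2 = model2.forward_batch(renamed.samples)[0].data
        np.testing.assert_allclose(p1, p2, atol=1e-8)
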
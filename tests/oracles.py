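"""Loop-level dense re-implementation of the encoder forward pass.

Everything here is written with explicit Python loops over genes and
feature indices, reading the production model's weights but sharing none of
its code path, so it serves as an independent oracle for the attention,
feed-forward and readout algebra.
"""

import numpy as np

from pathformer.sortpool import select_top_k


def mlp_apply(mlp, x):
    h = x @ mlp.fc1.w.data + mlp.fc1.b.data
    h = np.maximum(h, 0.0)
    return h @ mlp.fc2.w.data + mlp.fc2.b.data


def oracle_forward(model, sample):
    """Class probabilities for one sample, eval mode, by explicit loops."""
    cfg = model.cfg
    subset = select_top_k(model.selection, sample)
    K = len(subset)
    S = len(model.universe)

    p_rows = []
    net = model.encoder_snpmf.network_for(sample)
    from pathformer.snpmf import build_pathway_vector

    for g in subset:
        row = build_pathway_vector(net, g, cfg.bound, model.universe).toarray()[0]
        norm = np.sqrt(row.sum())
        p_rows.append(row / norm if norm > 1.0 else row)
    P = np.array(p_rows)

    # first-layer features: concat(expr, p(v)) through the input projection
    Z = np.zeros((K, cfg.d))
    for k, g in enumerate(subset):
        x = np.concatenate([[model.transform(g, sample.expression[g])], P[k]])
        for j in range(cfg.d):
            Z[k, j] = float(np.dot(x, model.input_proj.w.data[:, j])) + model.input_proj.b.data[j]

    # adjacency with self-loops on the subset-induced subgraph
    adj_hat = np.eye(K)
    pos = {g: i for i, g in enumerate(subset)}
    for i, gi in enumerate(subset):
        for j, gj in enumerate(subset):
            if net.has_edge(gi, gj):
                adj_hat[i, j] = 1.0

    for layer in model.layers:
        ZP = np.concatenate([Z, P], axis=1)
        if cfg.qk_net == "gin":
            def gin(netw):
                h = ZP @ netw.compress.w.data + netw.compress.b.data
                h = mlp_apply(netw.gin1, adj_hat @ h)
                h = mlp_apply(netw.gin2, adj_hat @ h)
                return h

            Q, Km = gin(layer.q_net), gin(layer.k_net)
        else:
            Q = np.array([mlp_apply(layer.q_net, ZP[k]) for k in range(K)])
            Km = np.array([mlp_apply(layer.k_net, ZP[k]) for k in range(K)])
        V = Z @ layer.v_proj.w.data + layer.v_proj.b.data

        scale = np.sqrt(layer.d_qk) if cfg.attn_scale == "sqrt_d" else float(cfg.d)
        att = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                att[i, j] = float(np.dot(Q[i], Km[j])) / scale
        if cfg.double_exp:
            att = np.exp(att)
        att_s = np.zeros_like(att)
        for i in range(K):
            e = np.exp(att[i] - att[i].max())
            att_s[i] = e / e.sum()
        v_hat = np.zeros_like(V)
        for i in range(K):
            for j in range(K):
                v_hat[i] += att_s[i, j] * V[j]

        # FFN with the residual from the block input
        out = np.zeros_like(v_hat)
        for i in range(K):
            h = np.maximum(v_hat[i] @ layer.ffn1.w.data + layer.ffn1.b.data, 0.0)
            out[i] = v_hat[i] + h @ layer.ffn2.w.data + layer.ffn2.b.data
        Z = out

    # readout: z = sum_k W_{h(v_k)} O_k, then the MLP head
    z = np.zeros(cfg.d_out)
    for k, g in enumerate(subset):
        z += model.readout_w.data[model.universe.h(g)] @ Z[k]
    logits = mlp_apply(model.head, z)
    e = np.exp(logits - logits.max())
    return e / e.sum()
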
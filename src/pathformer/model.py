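"""The PathFormer encoder stack and full model assembly.

Pipeline per sample: KD-Sortpool selects the gene subset Sn (size K,
expression-independent); SNPMF supplies the pathway matrix P (K x B*|S|);
the first-layer features concatenate each selected gene's transformed
expression value with its pathway vector (which doubles as a positional
encoding over the canonical gene order) and project to the model width d;
L Pathway-enhanced Attention (PAM) encoder layers follow; a gene-order-
indexed readout z = sum_k W_{h(v_k)} O_k and an MLP head produce class
probabilities.

PAM computes queries and keys from concat(Z, P) — via two GIN graph
convolutions on the subgraph induced by Sn (default, matching the
experimental setup) or via 2-layer MLPs — and values from a linear map of Z
alone; attention is row-softmaxed scaled dot product.  The feed-forward
block is Dropout -> FC -> ReLU -> Dropout -> FC with a residual connection
from the tensor entering the first FC to the block output.

All trainable pieces run on the package's numpy autodiff core; everything is
float64 and seeded, so evaluation-mode forward passes are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Parameter, Tensor, concat, gather_matmul_sum, softmax
from .cohort_io import ExpressionTransform, GdaTable, Sample, SignalingCohort
from .snpmf import PathwayEncoder
from .sortpool import SelectionState, select_top_k

__all__ = ["ModelConfig", "PathFormerModel", "AttentionTrace"]


@dataclass
class ModelConfig:
    """Architecture and encoding hyperparameters.

    Defaults follow the reference experimental setup: two encoder layers of
    width 32, GIN-based query/key networks (hidden and output width 32),
    other MLPs two layers with hidden width 64.  ``bound`` is the SNPMF
    distance bound B.  ``attn_scale`` divides Q.K^T by sqrt(d) (standard) or
    d.  ``scale_values_by_eps`` multiplies first-layer features by K*eps(v)
    (Sortpool-style straight-through signal into the importance vector);
    off by default.
    """

    k: int = 100
    n_layers: int = 2
    d: int = 32
    d_out: int = 32
    bound: int = 2
    qk_net: str = "gin"  # or "mlp"
    mlp_hidden: int = 64
    gin_hidden: int = 32
    dropout_p: float = 0.1
    attn_scale: str = "sqrt_d"  # or "d"
    n_heads: int = 1
    double_exp: bool = False
    snpmf_strict_lt: bool = False
    snpmf_on_subset: bool = False
    scale_values_by_eps: bool = False
    expr_transform: str = "zscore"
    seed: int = 0

    def validate(self) -> None:
        if self.n_layers < 1 or self.d < 1 or self.k < 1 or self.bound < 1:
            raise ValueError("n_layers, d, k and bound must all be >= 1")
        if self.qk_net not in ("gin", "mlp"):
            raise ValueError("qk_net must be 'gin' or 'mlp'")
        if self.attn_scale not in ("sqrt_d", "d"):
            raise ValueError("attn_scale must be 'sqrt_d' or 'd'")
        if self.d % self.n_heads != 0:
            raise ValueError("d must be divisible by n_heads")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.w = Parameter(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self) -> dict[str, Parameter]:
        return {f"{self.name}.w": self.w, f"{self.name}.b": self.b}


class MLP:
    """Two-layer perceptron with ReLU hidden activation."""

    def __init__(self, d_in: int, hidden: int, d_out: int, rng, name: str):
        self.fc1 = Linear(d_in, hidden, rng, f"{name}.fc1")
        self.fc2 = Linear(hidden, d_out, rng, f"{name}.fc2")

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def parameters(self) -> dict[str, Parameter]:
        return {**self.fc1.parameters(), **self.fc2.parameters()}


class GinQK:
    """Two GIN graph-convolution layers producing Q or K on the Sn subgraph.

    Input features concat(Z, P) are first compressed by a linear map (GIN on
    B*|S|-wide features would be wasteful); each GIN layer computes
    MLP((I + A) h) where A is the adjacency of the subgraph induced by Sn.
    """

    def __init__(self, d_in: int, d: int, hidden: int, rng, name: str):
        self.compress = Linear(d_in, d, rng, f"{name}.compress")
        self.gin1 = MLP(d, hidden, hidden, rng, f"{name}.gin1")
        self.gin2 = MLP(hidden, hidden, hidden, rng, f"{name}.gin2")

    def __call__(self, x: Tensor, adj_hat: Tensor) -> Tensor:
        h = self.compress(x)
        h = self.gin1(adj_hat @ h)
        h = self.gin2(adj_hat @ h)
        return h

    def parameters(self) -> dict[str, Parameter]:
        return {
            **self.compress.parameters(),
            **self.gin1.parameters(),
            **self.gin2.parameters(),
        }


class EncoderLayer:
    """One PathFormer encoder layer: PAM attention + feed-forward block."""

    def __init__(self, cfg: ModelConfig, d_pam_in: int, rng, name: str):
        self.cfg = cfg
        d = cfg.d
        if cfg.qk_net == "gin":
            self.q_net = GinQK(d_pam_in, d, cfg.gin_hidden, rng, f"{name}.q")
            self.k_net = GinQK(d_pam_in, d, cfg.gin_hidden, rng, f"{name}.k")
            self.d_qk = cfg.gin_hidden
        else:
            self.q_net = MLP(d_pam_in, cfg.mlp_hidden, d, rng, f"{name}.q")
            self.k_net = MLP(d_pam_in, cfg.mlp_hidden, d, rng, f"{name}.k")
            self.d_qk = d
        self.v_proj = Linear(d, d, rng, f"{name}.v")
        self.ffn1 = Linear(d, cfg.mlp_hidden, rng, f"{name}.ffn1")
        self.ffn2 = Linear(cfg.mlp_hidden, d, rng, f"{name}.ffn2")
        self.name = name

    def _qk(self, zp: Tensor, adj_hat: Tensor | None) -> tuple[Tensor, Tensor]:
        if self.cfg.qk_net == "gin":
            return self.q_net(zp, adj_hat), self.k_net(zp, adj_hat)
        return self.q_net(zp), self.k_net(zp)

    def attention(
        self, z: Tensor, p: Tensor, adj_hat: Tensor | None
    ) -> tuple[Tensor, Tensor]:
        """PAM: returns (row-softmaxed attention, weighted values V_hat)."""
        zp = concat([z, p], axis=-1)
        q, k = self._qk(zp, adj_hat)
        v = self.v_proj(z)
        scale = np.sqrt(self.d_qk) if self.cfg.attn_scale == "sqrt_d" else float(self.cfg.d)
        n_heads = self.cfg.n_heads
        if n_heads == 1:
            att = (q @ k.swap_last()) / scale
            if self.cfg.double_exp:
                att = att.exp()
            att_s = softmax(att, axis=-1)
            return att_s, att_s @ v
        # multi-head: split the feature axis, attend per head, concatenate
        dh_qk = self.d_qk // n_heads
        dh_v = self.cfg.d // n_heads
        att_heads, out_heads = [], []
        for hh in range(n_heads):
            qs = q[..., hh * dh_qk : (hh + 1) * dh_qk]
            ks = k[..., hh * dh_qk : (hh + 1) * dh_qk]
            vs = v[..., hh * dh_v : (hh + 1) * dh_v]
            att = (qs @ ks.swap_last()) / np.sqrt(dh_qk)
            if self.cfg.double_exp:
                att = att.exp()
            att_s = softmax(att, axis=-1)
            att_heads.append(att_s)
            out_heads.append(att_s @ vs)
        mean_att = att_heads[0]
        for a in att_heads[1:]:
            mean_att = mean_att + a
        return mean_att / n_heads, concat(out_heads, axis=-1)

    def ffn(self, x: Tensor, dropout) -> Tensor:
        x1 = dropout(x)
        h = dropout(self.ffn1(x1).relu())
        return x1 + self.ffn2(h)

    def __call__(
        self, z: Tensor, p: Tensor, adj_hat: Tensor | None, dropout
    ) -> tuple[Tensor, Tensor]:
        att_s, v_hat = self.attention(z, p, adj_hat)
        return self.ffn(v_hat, dropout), att_s

    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for mod in (self.q_net, self.k_net, self.v_proj, self.ffn1, self.ffn2):
            out.update(mod.parameters())
        return out


@dataclass
class AttentionTrace:
    """Per-sample attention matrices retained for co-effect interpretation."""

    sample_id: str
    subset: list[str]
    layers: list[np.ndarray]  # L matrices, each K x K, row-stochastic


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------


class PathFormerModel:
    """KD-Sortpool + SNPMF + PAM encoder stack + gene-indexed readout."""

    def __init__(self, cohort: SignalingCohort, gda: GdaTable, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        self.cohort = cohort
        self.universe = cohort.universe
        rng = np.random.default_rng(cfg.seed)
        self._rng = np.random.default_rng(cfg.seed + 1)  # dropout stream
        self.training = False

        self.selection = SelectionState(self.universe, cfg.k, gda)
        self.encoder_snpmf = PathwayEncoder(
            cohort, cfg.bound, strict_lt=cfg.snpmf_strict_lt, on_subset=cfg.snpmf_on_subset
        )
        self.transform = ExpressionTransform(cfg.expr_transform)

        p_len = cfg.bound * len(self.universe)
        self.input_proj = Linear(1 + p_len, cfg.d, rng, "input_proj")
        # block-wise Xavier: the expression column gets fan_in=1 scale so the
        # 1-dim expression signal is not drowned by the B|S|-dim pathway block
        limit_e = np.sqrt(6.0 / (1 + cfg.d))
        self.input_proj.w.data[0, :] = rng.uniform(-limit_e, limit_e, size=cfg.d)
        self.layers = [
            EncoderLayer(cfg, cfg.d + p_len, rng, f"layer{i}") for i in range(cfg.n_layers)
        ]
        # per-gene readout matrices as one |S| x d_out x d tensor (Xavier)
        limit = np.sqrt(6.0 / (cfg.d_out + cfg.d))
        self.readout_w = Parameter(
            rng.uniform(-limit, limit, size=(len(self.universe), cfg.d_out, cfg.d))
        )
        self.head = MLP(cfg.d_out, cfg.mlp_hidden, cohort.n_classes, rng, "head")

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {"selection.theta": self.selection.theta}
        out.update(self.input_proj.parameters())
        for layer in self.layers:
            out.update(layer.parameters())
        out["readout_w"] = self.readout_w
        out.update(self.head.parameters())
        return out

    def train(self) -> "PathFormerModel":
        self.training = True
        return self

    def eval(self) -> "PathFormerModel":
        self.training = False
        return self

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.cfg.dropout_p
        if not self.training or p <= 0:
            return x
        mask = (self._rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    # -- forward --------------------------------------------------------------
    def _group_samples(self, samples: list[Sample]) -> dict[frozenset, list[int]]:
        groups: dict[frozenset, list[int]] = {}
        for i, s in enumerate(samples):
            groups.setdefault(s.present_genes, []).append(i)
        return groups

    @staticmethod
    def _row_normalize(p_dense: np.ndarray) -> np.ndarray:
        """Scale each pathway vector to unit L2 norm (binary vectors have norm
        sqrt(popcount), which varies by orders of magnitude with degree)."""
        norms = np.sqrt(p_dense.sum(axis=-1, keepdims=True))
        return p_dense / np.maximum(norms, 1.0)

    def initial_features(self, samples: list[Sample], subset: list[str], p_dense: np.ndarray) -> Tensor:
        """First-layer input: concat(expr, normalized p(v)) projected to d.

        `p_dense` is the K x (B|S|) row-normalized pathway matrix shared by
        the batch; returns a (batch, K, d) tensor.
        """
        batch = len(samples)
        k = len(subset)
        expr = np.empty((batch, k, 1))
        for b, s in enumerate(samples):
            for j, g in enumerate(subset):
                if g not in s.expression:
                    raise KeyError(f"gene {g} missing expression in sample {s.sample_id}")
                expr[b, j, 0] = self.transform(g, s.expression[g])
        x = np.concatenate(
            [expr, np.broadcast_to(p_dense, (batch, k, p_dense.shape[1]))], axis=-1
        )
        return self.input_proj(Tensor(x))

    def forward_batch(
        self, samples: list[Sample], want_traces: bool = False
    ) -> tuple[Tensor, list[list[str]], list[AttentionTrace]]:
        """Class probabilities for a batch; also subsets and (optional) traces.

        Samples sharing a present-gene set share selection, pathway matrix and
        attention structure and are processed as one dense (batch, K, d)
        stack.
        """
        probs_by_index: list[Tensor | None] = [None] * len(samples)
        subsets: list[list[str] | None] = [None] * len(samples)
        traces: list[AttentionTrace] = []
        for present, indices in self._group_samples(samples).items():
            group = [samples[i] for i in indices]
            rep = group[0]
            subset = select_top_k(self.selection, rep)
            p_sparse = self.encoder_snpmf.matrix(rep, subset)
            p_dense = self._row_normalize(np.asarray(p_sparse.todense()))
            net = self.encoder_snpmf.network_for(rep)
            kk = len(subset)
            pos = {g: j for j, g in enumerate(subset)}
            adj = np.eye(kk)
            for u, v in net.edges(subset):
                if u in pos and v in pos:
                    adj[pos[u], pos[v]] = 1.0
                    adj[pos[v], pos[u]] = 1.0
            adj_hat = Tensor(adj)

            z = self.initial_features(group, subset, p_dense)
            if self.cfg.scale_values_by_eps:
                eps, idx = self.selection.eps_tensor(rep)
                sel_pos = [int(np.searchsorted(idx, self.universe.h(g))) for g in subset]
                scale = eps[np.array(sel_pos)] * float(len(idx))
                z = z * scale.reshape(1, kk, 1)
            p_t = Tensor(np.broadcast_to(p_dense, (len(group),) + p_dense.shape).copy())
            layer_atts: list[np.ndarray] = []
            for layer in self.layers:
                z, att_s = layer(z, p_t, adj_hat, self._dropout)
                if want_traces:
                    layer_atts.append(att_s.data.copy())
            sel_idx = np.array([self.universe.h(g) for g in subset], dtype=int)
            zvec = gather_matmul_sum(self.readout_w, sel_idx, z)
            logits = self.head(zvec)
            p_out = softmax(logits, axis=-1)
            for b, i in enumerate(indices):
                probs_by_index[i] = p_out[b : b + 1]
                subsets[i] = subset
                if want_traces:
                    traces.append(
                        AttentionTrace(
                            sample_id=samples[i].sample_id,
                            subset=subset,
                            layers=[a[b] for a in layer_atts],
                        )
                    )
        probs = concat([p for p in probs_by_index], axis=0)
        return probs, subsets, traces

    def forward(self, sample: Sample) -> tuple[np.ndarray, list[str], AttentionTrace]:
        """Single-sample prediction: (probability vector, Sn, attention trace)."""
        probs, subsets, traces = self.forward_batch([sample], want_traces=True)
        return probs.data[0], subsets[0], traces[0]

    def predict(self, samples: list[Sample]) -> np.ndarray:
        probs, _, _ = self.forward_batch(samples)
        return np.argmax(probs.data, axis=1)

    # -- losses ---------------------------------------------------------------
    def gsc_terms(self, samples: list[Sample]) -> Tensor:
        """Mean over samples of sum_{v in Sn} eps(v)(1 - e(v)), differentiable
        in theta with the subset held fixed (hard top-K)."""
        total: Tensor | None = None
        for present, indices in self._group_samples(samples).items():
            rep = next(s for s in samples if s.present_genes == present)
            eps, idx = self.selection.eps_tensor(rep)
            subset = select_top_k(self.selection, rep)
            sel_pos = np.array(
                [int(np.searchsorted(idx, self.universe.h(g))) for g in subset]
            )
            one_minus_e = 1.0 - self.selection.e[idx[sel_pos]]
            term = (eps[sel_pos] * Tensor(one_minus_e)).sum() * float(len(indices))
            total = term if total is None else total + term
        return total / float(len(samples))

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {name: p.data for name, p in self.parameters().items()}
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        meta = {
            "config": dataclasses.asdict(self.cfg),
            "class_names": self.cohort.class_names,
            "transform": {
                "kind": self.transform.kind,
                "mean": self.transform.mean_,
                "std": self.transform.std_,
            },
        }
        sidecar.write_text(json.dumps(meta, indent=1))

    def load_weights(self, path: str | Path) -> None:
        data = np.load(Path(path).with_suffix(".npz"))
        for name, p in self.parameters().items():
            p.data[...] = data[name]
        sidecar = Path(path).with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            self.transform.kind = meta["transform"]["kind"]
            self.transform.mean_ = {k: float(v) for k, v in meta["transform"]["mean"].items()}
            self.transform.std_ = {k: float(v) for k, v in meta["transform"]["std"].items()}

    def state_copy(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.parameters().items():
            p.data[...] = state[name]
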
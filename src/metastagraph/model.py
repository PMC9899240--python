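"""Contrastive embedding of time-evolving graphs.

Each snapshot ``G_t`` is encoded by a multi-head self-attention encoder
whose attention is masked by the snapshot's adjacency matrix: a node may
only attend to itself, its neighbours, and an auxiliary *master node* that
is connected to everything.  The encoder output at the master row is the
graph embedding ``z_t``; it is passed as the master input of the next
snapshot, so temporal context is carried recurrently over windows of
length ``l``.  A two-hidden-layer projection head maps ``z_t`` to the
final embedding ``g_t`` in R^d.

Training is contrastive: for a batch of anchor times t, the embedding of
``G_{t+1}`` is the positive, under the InfoNCE loss

    L = -log exp(g_t . g_{t+1} / tau) / sum_i exp(g_t . g_i / tau)

with raw dot-product similarity and temperature ``tau``, where i runs
over the positive plus the embeddings of all batch anchors — the anchor's
own embedding included.  The self-similarity term keeps the embedding
norms bounded and makes chains of consecutive snapshots collapse into
tight clusters.  Under metastability, consecutive snapshots almost surely
share a state, so pulling consecutive embeddings together transfers the
state structure to the low-dimensional space.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .autodiff import Tensor
from .graphgen import TimeEvolvingGraph

__all__ = [
    "positional_encoding",
    "attention_mask",
    "info_nce_loss",
    "GraphContrastiveEmbedder",
]

FEATURE_MODES = ("constant", "one_hot", "degree")


def _dt(x: float):
    return np.asarray(x, dtype=ad.get_dtype())


def positional_encoding(n_nodes: int, d_m: int) -> np.ndarray:
    """Sinusoidal positional encoding, one row per node position.

    ``p[pos, 2i] = sin(pos / 10000^(2i/d_m))`` and
    ``p[pos, 2i+1] = cos(pos / 10000^(2i/d_m))``.
    """
    if d_m % 2 != 0:
        raise ValueError("d_m must be even")
    pos = np.arange(n_nodes)[:, None]
    i2 = np.arange(0, d_m, 2)[None, :]
    angle = pos / np.power(10000.0, i2 / d_m)
    pe = np.empty((n_nodes, d_m))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def attention_mask(A: np.ndarray) -> np.ndarray:
    """Build the (n+1) x (n+1) boolean attention mask for one snapshot.

    Row/column 0 belong to the master node, which attends to and is
    attended by every node.  The remaining block is the adjacency matrix
    plus self-connections on the diagonal (so isolated nodes still have a
    well-defined softmax row).  Masked-out pairs receive probability
    exactly 0 in the attention softmax.
    """
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.diag(A).any():
        raise ValueError("adjacency must have a zero diagonal")
    n = A.shape[0]
    mask = np.zeros((n + 1, n + 1), dtype=bool)
    mask[0, :] = True
    mask[:, 0] = True
    mask[1:, 1:] = A.astype(bool)
    mask[np.arange(n + 1), np.arange(n + 1)] = True
    return mask


def info_nce_loss(g_hat_t: np.ndarray, g_hat_pos: np.ndarray,
                  g_hat_batch: np.ndarray, tau: float = 1.0) -> float:
    """InfoNCE for one anchor: positive against a batch of candidates.

    ``-log( exp(g_t . g_pos / tau) / sum_i exp(g_t . g_i / tau) )``
    with raw dot-product similarity.  ``g_hat_pos`` must be one row of
    ``g_hat_batch``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    g_hat_batch = np.atleast_2d(g_hat_batch)
    if g_hat_batch.shape[0] < 2:
        raise ValueError("need a batch of at least 2 candidates")
    sims = g_hat_batch @ np.asarray(g_hat_t) / tau
    pos = float(np.asarray(g_hat_t) @ np.asarray(g_hat_pos)) / tau
    m = sims.max()
    return float(np.log(np.exp(sims - m).sum()) - (pos - m))


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out))


class GraphContrastiveEmbedder(BaseEstimator):
    """Masked-attention encoder with recurrent master-node pooling.

    A scikit-learn style estimator: ``fit`` trains on a
    :class:`~metastagraph.graphgen.TimeEvolvingGraph`; ``transform`` maps a
    graph sequence to a (T, d) embedding matrix.

    Parameters
    ----------
    d : int
        Output embedding dimension (2 for visualisation, 32 for clustering
        comparisons).
    d_m : int
        Encoder width (must be divisible by ``n_heads``).
    n_heads, n_layers : int
        Attention heads and stacked encoder layers.
    d_ff : int
        Feed-forward hidden width (defaults to 2 * d_m).
    window_l : int
        Temporal recurrence length l: the master state is rolled forward
        over l consecutive snapshots starting from the learnable initial
        vector.
    tau : float
        InfoNCE temperature.
    batch_size : int
        Anchors per optimisation step.
    epochs, steps_per_epoch : int
        Training length; one epoch is ``steps_per_epoch`` Adam steps.
    learning_rate : float
        Adam step size (other Adam parameters at their defaults).
    use_positional_encoding : bool
        Add sinusoidal node-position encodings to the input features.
    feature_mode : {"constant", "one_hot", "degree"}
        Raw per-node input features.  ``constant`` (default) and ``degree``
        (standardised node degree) both make the encoder depend on topology
        alone; ``degree`` gives the contrastive objective an input-dependent
        signal at initialisation and is what the dataset presets use.
    seed : int
        Seed for parameter initialisation and anchor sampling.

    Attributes
    ----------
    params_ : dict[str, Tensor]
        Trained parameters.
    loss_curve_ : list[float]
        Mean InfoNCE loss per epoch.
    n_nodes_ : int
        Node count the model was fitted for.
    """

    def __init__(self, d: int = 32, d_m: int = 32, n_heads: int = 4,
                 n_layers: int = 3, d_ff: int | None = None, window_l: int = 3,
                 tau: float = 1.0, batch_size: int = 64, epochs: int = 50,
                 steps_per_epoch: int = 8, learning_rate: float = 1e-3,
                 use_positional_encoding: bool = False,
                 feature_mode: str = "constant", seed: int = 0):
        self.d = d
        self.d_m = d_m
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.window_l = window_l
        self.tau = tau
        self.batch_size = batch_size
        self.epochs = epochs
        self.steps_per_epoch = steps_per_epoch
        self.learning_rate = learning_rate
        self.use_positional_encoding = use_positional_encoding
        self.feature_mode = feature_mode
        self.seed = seed

    # -- validation and setup ---------------------------------------------
    def _validate(self):
        if self.d_m % self.n_heads != 0:
            raise ValueError("d_m must be divisible by n_heads")
        if self.window_l < 1:
            raise ValueError("window_l must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")

    def _raw_dim(self, n: int) -> int:
        return n if self.feature_mode == "one_hot" else 1

    def _init_params(self, n: int, rng: np.random.Generator) -> dict[str, Tensor]:
        d_m = self.d_m
        d_ff = self.d_ff or 2 * d_m
        p: dict[str, np.ndarray] = {
            "W_in": _xavier(rng, self._raw_dim(n), d_m),
            "b_in": np.zeros(d_m),
            "z0": rng.standard_normal(d_m) * 0.1,
        }
        for i in range(self.n_layers):
            for nm in ("q", "k", "v", "o"):
                p[f"L{i}_W{nm}"] = _xavier(rng, d_m, d_m)
                p[f"L{i}_b{nm}"] = np.zeros(d_m)
            p[f"L{i}_ln1_g"] = np.ones(d_m)
            p[f"L{i}_ln1_b"] = np.zeros(d_m)
            p[f"L{i}_ln2_g"] = np.ones(d_m)
            p[f"L{i}_ln2_b"] = np.zeros(d_m)
            p[f"L{i}_Wf1"] = _xavier(rng, d_m, d_ff)
            p[f"L{i}_bf1"] = np.zeros(d_ff)
            p[f"L{i}_Wf2"] = _xavier(rng, d_ff, d_m)
            p[f"L{i}_bf2"] = np.zeros(d_m)
        p["H_W1"] = _xavier(rng, d_m, d_m)
        p["H_b1"] = np.zeros(d_m)
        p["H_W2"] = _xavier(rng, d_m, d_m)
        p["H_b2"] = np.zeros(d_m)
        p["H_Wout"] = _xavier(rng, d_m, self.d)
        p["H_bout"] = np.zeros(self.d)
        return {k: Tensor(v, requires_grad=True) for k, v in p.items()}

    def _prepare(self, g: TimeEvolvingGraph) -> dict:
        """Precompute per-snapshot masks and raw node features."""
        g.validate()
        n, T = g.n, g.T
        N = n + 1
        masks = np.zeros((T, N, N), dtype=bool)
        masks[:, 0, :] = True
        masks[:, :, 0] = True
        masks[:, 1:, 1:] = g.snapshots
        masks[:, np.arange(N), np.arange(N)] = True
        if self.feature_mode == "one_hot":
            feats = np.broadcast_to(np.eye(n), (T, n, n))
        elif self.feature_mode == "degree":
            # standardised over the whole sequence: without an O(1) spread in
            # the inputs the initial embeddings are nearly input-independent
            # and the contrastive gradient vanishes (a plateau)
            deg = (g.snapshots.sum(axis=2) / max(n - 1, 1)).astype(float)
            feats = ((deg - deg.mean()) / (deg.std() + 1e-8))[:, :, None]
        else:
            feats = np.ones((T, n, 1))
        pe = positional_encoding(n, self.d_m) if self.use_positional_encoding else None
        return {"masks": masks, "feats": feats, "pe": pe, "n": n, "T": T}

    # -- forward pass -------------------------------------------------------
    def _encode_step(self, z: Tensor, data: dict, ts: np.ndarray,
                     capture: list | None = None) -> Tensor:
        """One recurrent step: encode snapshots `ts` with master input `z`.

        z : Tensor (B, 1, d_m); returns the new master state, same shape.
        """
        p = self.params_
        d_m = self.d_m
        feats = data["feats"][ts]  # (B, n, d_raw)
        B, n_real = feats.shape[0], feats.shape[1]
        x_nodes = (Tensor(feats.reshape(B * n_real, -1)) @ p["W_in"] + p["b_in"]) \
            .reshape(B, n_real, d_m)
        if data["pe"] is not None:
            x_nodes = x_nodes + Tensor(data["pe"])
        x = ad.concat([z, x_nodes], axis=1)  # (B, N, d_m)
        N = n_real + 1
        # additive attention mask: 0 on allowed pairs, -1e30 on forbidden ones
        # (forbidden attention probabilities underflow to exactly 0)
        add_mask = np.where(data["masks"][ts][:, None, :, :], _dt(0.0), _dt(-1e30))
        H = self.n_heads
        dh = d_m // H
        scale = 1.0 / np.sqrt(dh)

        def linear(inp, W, b, d_out):
            return (inp.reshape(B * N, -1) @ p[W] + p[b]).reshape(B, N, d_out)

        for i in range(self.n_layers):
            q = linear(x, f"L{i}_Wq", f"L{i}_bq", d_m).reshape(B, N, H, dh).transpose(0, 2, 1, 3)
            k = linear(x, f"L{i}_Wk", f"L{i}_bk", d_m).reshape(B, N, H, dh).transpose(0, 2, 1, 3)
            v = linear(x, f"L{i}_Wv", f"L{i}_bv", d_m).reshape(B, N, H, dh).transpose(0, 2, 1, 3)
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale
            attn = scores.masked_softmax_additive(add_mask)  # (B, H, N, N)
            if capture is not None:
                capture.append(attn)
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, d_m)
            x = (x + linear(ctx, f"L{i}_Wo", f"L{i}_bo", d_m)).layer_norm(
                p[f"L{i}_ln1_g"], p[f"L{i}_ln1_b"])
            ff = linear(linear(x, f"L{i}_Wf1", f"L{i}_bf1", self.d_ff or 2 * d_m).relu(),
                        f"L{i}_Wf2", f"L{i}_bf2", d_m)
            x = (x + ff).layer_norm(p[f"L{i}_ln2_g"], p[f"L{i}_ln2_b"])
        return x[:, 0:1, :]

    def _head(self, z: Tensor) -> Tensor:
        """Projection head: two hidden ReLU layers, then a final affine map to R^d."""
        p = self.params_
        h = (z @ p["H_W1"] + p["H_b1"]).relu()
        h = (h @ p["H_W2"] + p["H_b2"]).relu()
        return h @ p["H_Wout"] + p["H_bout"]

    def _initial_master(self, B: int) -> Tensor:
        return self.params_["z0"].reshape(1, 1, self.d_m) * Tensor(np.ones((B, 1, 1)))

    def _forward_window(self, data: dict, anchors: np.ndarray,
                        with_positive: bool = False, capture: list | None = None):
        """Roll the master state over windows [t-l+1, t] for each anchor t.

        Returns ``g_t`` (B, d) and, optionally, ``g_{t+1}`` computed by
        extending the same rolled state one step.
        """
        l = self.window_l
        z = self._initial_master(len(anchors))
        for k in range(l):
            # window start clamps at 0 so anchors earlier than l-1 still get
            # a window ending exactly at t (snapshot 0 is repeated)
            ts = np.clip(anchors - (l - 1) + k, 0, None)
            z = self._encode_step(z, data, ts, capture=capture if k == l - 1 else None)
        g_t = self._head(z.reshape(len(anchors), self.d_m))
        if not with_positive:
            return g_t
        z_pos = self._encode_step(z, data, anchors + 1)
        g_pos = self._head(z_pos.reshape(len(anchors), self.d_m))
        return g_t, g_pos

    # -- estimator API ------------------------------------------------------
    def fit(self, g: TimeEvolvingGraph, y=None):
        """Train on a time-evolving graph with the contrastive objective."""
        self._validate()
        l = self.window_l
        if g.T <= l + 1:
            raise ValueError(f"need T > window_l + 1 = {l + 1} snapshots, got {g.T}")
        rng = np.random.default_rng(self.seed)
        self.n_nodes_ = g.n
        self.params_ = self._init_params(g.n, rng)
        data = self._prepare(g)
        lo, hi = l - 1, g.T - 2  # anchors t with full window and a positive at t+1
        n_valid = hi - lo + 1
        B = min(self.batch_size, n_valid)
        if B < 2:
            raise ValueError("not enough anchor time points for a contrastive batch")
        opt = ad.Adam(self.params_, lr=self.learning_rate)
        self.loss_curve_ = []
        inv_tau = 1.0 / self.tau
        for _epoch in range(self.epochs):
            epoch_losses = []
            for _step in range(self.steps_per_epoch):
                anchors = rng.integers(lo, hi + 1, size=B)
                g_t, g_pos = self._forward_window(data, anchors, with_positive=True)
                # InfoNCE: the denominator runs over the mini-batch embeddings
                # (the anchor's own embedding included) plus the positive.
                # The self-similarity term bounds the embedding norms and is
                # what makes same-state chains collapse into tight clusters;
                # with positives-only negatives the norms grow without bound
                # and instance-level repulsion shreds the cluster structure.
                s_pos = ((g_t * g_pos).sum(axis=1) * inv_tau).reshape(B, 1)
                den = (g_t @ g_t.transpose(1, 0)) * inv_tau  # (B, B)
                logits = ad.concat([s_pos, den], axis=1)     # (B, B+1)
                loss = -(logits.log_softmax()[:, 0].mean())
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(loss.item())
            self.loss_curve_.append(float(np.mean(epoch_losses)))
        return self

    def transform(self, g: TimeEvolvingGraph, chunk: int = 256) -> np.ndarray:
        """Embed every snapshot; returns a (T, d) array.

        Each snapshot t is embedded exactly as during training: the master
        state is rolled from the learnable initial vector over the sliding
        window [t-l+1, t] (clamped at the sequence start) and projected
        through the head.
        """
        self._check_fitted(g)
        data = self._prepare(g)
        T = g.T
        out = np.empty((T, self.d))
        with ad.no_grad():
            for c in range(0, T, chunk):
                anchors = np.arange(c, min(c + chunk, T))
                out[anchors] = self._forward_window(data, anchors).data
        return out

    def fit_transform(self, g: TimeEvolvingGraph, y=None) -> np.ndarray:
        return self.fit(g).transform(g)

    def _check_fitted(self, g: TimeEvolvingGraph | None = None):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted; call fit() first")
        if g is not None and g.n != self.n_nodes_:
            raise ValueError(f"model was fitted for {self.n_nodes_} nodes, got {g.n}")

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Save parameters (.npz) with a JSON sidecar holding the config."""
        self._check_fitted()
        path = Path(path)
        arrays = {k: v.data for k, v in self.params_.items()}
        arrays["meta_n_nodes"] = np.array(self.n_nodes_)
        np.savez(path, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        with sidecar.open("w") as fh:
            json.dump(self.get_params(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "GraphContrastiveEmbedder":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        with sidecar.open() as fh:
            params = json.load(fh)
        model = cls(**params)
        with np.load(path) as arc:
            model.n_nodes_ = int(arc["meta_n_nodes"])
            model.params_ = {k: Tensor(arc[k], requires_grad=True)
                             for k in arc.files if k != "meta_n_nodes"}
        model.loss_curve_ = []
        return model
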
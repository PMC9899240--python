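"""Node relevance via attention-gradient relevance propagation.

Which nodes does the model rely on when it embeds a snapshot?  Following
the gradient-weighted attention rollout family of transformer explanation
methods, the relevance of the embedding ``g_t`` is redistributed backwards
through the encoder: for each attention layer we take the head-averaged
elementwise product of the attention matrix with its gradient (w.r.t. a
uniform positive seed over the components of ``g_t``), clamp negative
contributions to zero, add the identity (the residual path), row-normalise
and accumulate across layers by matrix multiplication.  The master-node
row of the accumulated matrix, restricted to the real nodes, scores how
much each node contributed to the snapshot's embedding.

Because the embedding is a similarity-model output rather than a class
logit, the relevance seed is a uniform positive vector over the embedding
components.  Per-state maps are obtained by summing per-snapshot
relevances over the snapshots assigned (by clustering) to each state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphgen import TimeEvolvingGraph
from .model import GraphContrastiveEmbedder

__all__ = ["RelevanceMap", "snapshot_relevance", "batch_relevance", "state_relevance"]


@dataclass
class RelevanceMap:
    """Per-snapshot and per-state node relevance scores."""

    per_snapshot: np.ndarray  # (T, n) non-negative
    per_state: np.ndarray  # (s, n)
    state_labels: np.ndarray  # (T,)
    normalization: str = "max_one"


def _rollout(attn_list: list[np.ndarray], grad_list: list[np.ndarray]) -> np.ndarray:
    """Gradient-weighted attention rollout for a batch.

    attn/grad arrays have shape (B, H, N, N).  Returns (B, N, N).
    """
    B, _, N, _ = attn_list[0].shape
    R = np.broadcast_to(np.eye(N), (B, N, N)).copy()
    for A, G in zip(attn_list, grad_list):
        bar = np.clip((G * A).mean(axis=1), 0.0, None)  # head-averaged, positive part
        bar = bar + np.eye(N)[None]
        bar = bar / bar.sum(axis=-1, keepdims=True)
        R = bar @ R
    return R


def batch_relevance(model: GraphContrastiveEmbedder, g: TimeEvolvingGraph,
                    times: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Relevance vectors for many snapshots; returns (len(times), n).

    For each time t the model rolls its recurrence window up to t, the
    embedding components are summed with uniform positive weight, and the
    attention gradients of the final encode step drive the rollout.
    Snapshots are processed in batches; their graphs are independent, so
    per-sample gradients are exact.
    """
    model._check_fitted(g)
    times = np.asarray(times, dtype=int)
    if times.size and (times.min() < 0 or times.max() >= g.T):
        raise ValueError("time index out of range")
    data = model._prepare(g)
    out = np.empty((len(times), g.n))
    for c in range(0, len(times), chunk):
        anchors = times[c:c + chunk]
        capture: list = []
        g_t = model._forward_window(data, anchors, capture=capture)
        seed = g_t.sum()
        for p in model.params_.values():
            p.zero_grad()
        seed.backward()
        attn = [a.data for a in capture]
        grads = [a.grad if a.grad is not None else np.zeros_like(a.data) for a in capture]
        R = _rollout(attn, grads)
        out[c:c + chunk] = R[:, 0, 1:]
    return out


def snapshot_relevance(model: GraphContrastiveEmbedder, g: TimeEvolvingGraph,
                       t: int) -> np.ndarray:
    """Relevance of each real node for the embedding of snapshot t."""
    return batch_relevance(model, g, np.array([t]))[0]


def state_relevance(per_snapshot: np.ndarray, cluster_labels: np.ndarray,
                    normalization: str = "max_one") -> np.ndarray:
    """Sum per-snapshot relevances within each state; optionally scale rows to max 1.

    ``cluster_labels`` are the k-means state assignments of the same
    snapshots (not ground truth).  Returns an (s, n) matrix.
    """
    per_snapshot = np.asarray(per_snapshot, dtype=float)
    cluster_labels = np.asarray(cluster_labels, dtype=int)
    if len(cluster_labels) != len(per_snapshot):
        raise ValueError("labels must align with per-snapshot rows")
    if normalization not in ("none", "max_one"):
        raise ValueError("normalization must be 'none' or 'max_one'")
    s = int(cluster_labels.max()) + 1
    out = np.zeros((s, per_snapshot.shape[1]))
    np.add.at(out, cluster_labels, per_snapshot)
    if normalization == "max_one":
        peaks = out.max(axis=1, keepdims=True)
        np.divide(out, peaks, out=out, where=peaks > 0)
    return out


def relevance_map(model: GraphContrastiveEmbedder, g: TimeEvolvingGraph,
                  cluster_labels: np.ndarray, times: np.ndarray | None = None,
                  normalization: str = "max_one") -> RelevanceMap:
    """Full relevance analysis over a set of snapshots (default: all)."""
    if times is None:
        times = np.arange(g.T)
    times = np.asarray(times, dtype=int)
    cluster_labels = np.asarray(cluster_labels, dtype=int)
    if len(cluster_labels) != len(times):
        raise ValueError("cluster_labels must align with times")
    per_snapshot = batch_relevance(model, g, times)
    per_state = state_relevance(per_snapshot, cluster_labels, normalization)
    return RelevanceMap(per_snapshot=per_snapshot, per_state=per_state,
                        state_labels=cluster_labels, normalization=normalization)


def plot_relevance(g: TimeEvolvingGraph, relevance: np.ndarray, ax=None,
                   cmap: str = "YlOrBr"):
    """Best-effort rendering: nodes at their coordinates coloured by relevance."""
    import matplotlib.pyplot as plt

    if g.coords is None:
        raise ValueError("graph has no node coordinates to plot")
    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(g.coords[:, 0], g.coords[:, 1], c=relevance, cmap=cmap, s=60,
                    edgecolors="k", linewidths=0.3)
    ax.set_xlabel("a")
    ax.set_ylabel("b")
    plt.colorbar(sc, ax=ax, label="relevance")
    return ax
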
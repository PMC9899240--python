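"""Time-evolving graphs from OTU count tables.

Microbial co-occurrence preprocessing: a base graph over taxa is built by
thresholding the absolute Pearson correlation between OTU count columns;
the snapshot at sample t is the base graph with every edge incident to a
taxon whose count is zero at t removed.  Presence/absence of taxa thus
drives the temporal rewiring.

Because public accessions for the studies this emulates are not bundled,
the module also ships a synthetic OTU fixture generator: block-correlated
counts with a hidden Markov regime process, each regime silencing one
taxon block, which yields a metastable snapshot sequence with known
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graphgen import TimeEvolvingGraph

__all__ = [
    "OTUTable",
    "correlation_base_graph",
    "zero_mask_snapshots",
    "synth_otu_fixture",
    "read_otu_table",
    "write_otu_table",
]


@dataclass
class OTUTable:
    """A samples-by-taxa count matrix with sample times and taxon ids."""

    counts: np.ndarray  # (T, p) non-negative ints
    sample_times: list
    taxon_ids: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a (T, p) matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        T, p = self.counts.shape
        if len(self.sample_times) != T or len(self.taxon_ids) != p:
            raise ValueError("sample_times/taxon_ids lengths must match counts")

    @property
    def T(self) -> int:
        return self.counts.shape[0]

    @property
    def p(self) -> int:
        return self.counts.shape[1]


def correlation_base_graph(table: OTUTable, corr_threshold: float = 0.3) -> np.ndarray:
    """Base adjacency over taxa: edge iff |Pearson r| >= threshold.

    Negative correlations (co-exclusion) also produce edges.  Zero-variance
    columns cannot be correlated; they are left edgeless with a warning.
    """
    if table.p < 2:
        raise ValueError("need at least 2 taxa")
    X = table.counts.astype(float)
    std = X.std(axis=0)
    dead = std == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance taxon column(s); treated as uncorrelated",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) >= corr_threshold
    adj[dead, :] = False
    adj[:, dead] = False
    np.fill_diagonal(adj, False)
    return adj


def zero_mask_snapshots(base: np.ndarray, table: OTUTable) -> TimeEvolvingGraph:
    """Per-sample snapshots: drop every base edge touching a zero-count taxon."""
    base = np.asarray(base, dtype=bool)
    if base.shape != (table.p, table.p):
        raise ValueError(f"base graph must be {table.p} x {table.p}")
    present = table.counts > 0  # (T, p)
    snaps = base[None, :, :] & present[:, :, None] & present[:, None, :]
    return TimeEvolvingGraph(snaps, node_ids=list(table.taxon_ids))


def synth_otu_fixture(T: int = 200, p: int = 30, n_states: int = 2,
                      zero_rate: float = 0.9, stay_prob: float = 0.98,
                      base_lambda: float = 20.0, seed: int = 0):
    """Synthetic OTU table with hidden metastable regimes.

    Taxa are split into ``n_states`` blocks plus a shared remainder.  Counts
    are ``1 + Poisson`` draws whose rates share a per-block lognormal factor
    at each time point, so columns within a block are positively correlated.
    A hidden Markov chain with per-step stay probability ``stay_prob``
    switches between regimes; regime k silences (sets to zero with
    probability ``zero_rate``) the counts of block k.  With ``zero_rate=0``
    no count is ever zero and the snapshot sequence is constant.

    Returns
    -------
    (OTUTable, ndarray)
        The table and the hidden regime label per sample.
    """
    if n_states < 1 or p < n_states:
        raise ValueError("need p >= n_states >= 1")
    rng = np.random.default_rng(seed)
    # hidden regime chain
    labels = np.empty(T, dtype=int)
    labels[0] = rng.integers(n_states)
    flips = rng.random(T - 1) > stay_prob
    for t in range(1, T):
        if flips[t - 1]:
            shift = 1 + rng.integers(max(1, n_states - 1))
            labels[t] = (labels[t - 1] + shift) % n_states
        else:
            labels[t] = labels[t - 1]
    block = np.arange(p) % n_states  # block id per taxon
    factors = rng.lognormal(mean=0.0, sigma=0.6, size=(T, n_states))
    lam = base_lambda * factors[:, block]
    counts = 1 + rng.poisson(lam)
    silenced = (block[None, :] == labels[:, None]) & (rng.random((T, p)) < zero_rate)
    counts = np.where(silenced, 0, counts)
    table = OTUTable(counts=counts,
                     sample_times=list(range(T)),
                     taxon_ids=[f"OTU_{j:03d}" for j in range(p)])
    return table, labels


def read_otu_table(path: str | Path) -> OTUTable:
    """Read a flat TSV OTU table: first column sample id, header row of taxon ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OTUTable(counts=df.to_numpy(),
                    sample_times=list(df.index),
                    taxon_ids=list(df.columns))


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, index=table.sample_times, columns=table.taxon_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
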
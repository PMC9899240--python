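"""Time-evolving graphs with planted metastable structure.

A trajectory hopping between potential wells is turned into a sequence of
graph snapshots over a fixed node set with random planar coordinates.
Each snapshot starts from the complete graph and removes edges according
to where the trajectory currently sits, so the graph tracks the
instantaneous point and inherits the trajectory's metastability:

* **positional ring data** — edges between nodes inside a moving circle
  (centred at the current trajectory point) are removed at random; which
  nodes are affected depends on the well, so states differ only by node
  *position*, not by topology;
* **positional double-well data** — in one state, edges among nodes whose
  vertical coordinate lies above the trajectory's mean x1 are removed; in
  the other state, edges among the complementary "lower" nodes are.  The
  planted independent set makes the state decodable from the snapshot;
* **non-positional data** — nodes inside the moving circle are pruned to a
  per-state target degree among themselves, so the states differ by a
  purely topological feature (inside-subgraph degree).

Independently of the planted pattern, every snapshot loses a small random
fraction of the remaining "outside" edges as noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "GraphGenConfig",
    "TimeEvolvingGraph",
    "gen_positional_swell",
    "gen_positional_doublewell",
    "gen_nonpositional",
    "snapshot_edge_stats",
    "write_snapshots",
    "read_snapshots",
]


@dataclass(frozen=True)
class GraphGenConfig:
    """Parameters of snapshot generation.

    Parameters
    ----------
    n : int
        Number of nodes.
    radius : float
        Radius r of the moving circle centred at the trajectory point.
    inside_removal_prob : float
        Probability of removing each eligible edge inside the circle
        (positional generators).
    noise_removal_prob : float
        Probability of removing each edge with at least one endpoint
        outside the circle (all generators).
    per_state_degree : dict[int, int]
        Target neighbour count among inside-circle nodes, per state
        (non-positional generator only).
    coord_seed, edge_seed : int
        Seeds for node coordinates and for edge removals.
    coord_box : tuple
        (xmin, xmax, ymin, ymax) box for uniform node coordinates; the
        default encloses the unit ring and the double-well minima.
    """

    n: int = 50
    radius: float = 1.2
    inside_removal_prob: float = 0.8
    noise_removal_prob: float = 0.01
    per_state_degree: dict = field(default_factory=dict)
    coord_seed: int = 0
    edge_seed: int = 1
    coord_box: tuple = (-2.0, 2.0, -2.0, 2.0)

    def __post_init__(self):
        if not (0.0 <= self.inside_removal_prob <= 1.0
                and 0.0 <= self.noise_removal_prob <= 1.0):
            raise ValueError("removal probabilities must lie in [0, 1]")
        if any(v >= self.n for v in self.per_state_degree.values()):
            raise ValueError("per-state degrees must be < n")
        if self.n < 2:
            raise ValueError("need at least 2 nodes")


@dataclass
class TimeEvolvingGraph:
    """An ordered sequence of symmetric binary snapshots on a fixed node set."""

    snapshots: np.ndarray  # (T, n, n) bool, symmetric, zero diagonal
    coords: np.ndarray | None = None  # (n, 2)
    states: np.ndarray | None = None  # (T,)
    node_ids: list | None = None

    def __post_init__(self):
        self.snapshots = np.asarray(self.snapshots, dtype=bool)
        if self.snapshots.ndim != 3 or self.snapshots.shape[1] != self.snapshots.shape[2]:
            raise ValueError("snapshots must be a (T, n, n) array")
        if self.states is not None:
            self.states = np.asarray(self.states, dtype=int)
            if len(self.states) != len(self.snapshots):
                raise ValueError("states must have length T")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.n, 2):
                raise ValueError("coords must have shape (n, 2)")
        if self.node_ids is None:
            self.node_ids = list(range(self.n))

    @property
    def n(self) -> int:
        return self.snapshots.shape[1]

    @property
    def T(self) -> int:
        return self.snapshots.shape[0]

    def __len__(self) -> int:
        return self.T

    def subsequence(self, index) -> "TimeEvolvingGraph":
        """Restrict to a subset/slice of time points (same node set)."""
        states = None if self.states is None else self.states[index]
        return TimeEvolvingGraph(self.snapshots[index], coords=self.coords,
                                 states=states, node_ids=list(self.node_ids))

    def edge_counts(self) -> np.ndarray:
        return self.snapshots.sum(axis=(1, 2)) // 2

    def validate(self) -> None:
        if not np.array_equal(self.snapshots, np.swapaxes(self.snapshots, 1, 2)):
            raise ValueError("snapshots must be symmetric")
        if self.snapshots[:, np.arange(self.n), np.arange(self.n)].any():
            raise ValueError("snapshots must have zero diagonal")


def _random_coords(cfg: GraphGenConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.coord_seed)
    xmin, xmax, ymin, ymax = cfg.coord_box
    coords = np.empty((cfg.n, 2))
    coords[:, 0] = rng.uniform(xmin, xmax, cfg.n)
    coords[:, 1] = rng.uniform(ymin, ymax, cfg.n)
    return coords


def _complete(n: int) -> np.ndarray:
    a = np.ones((n, n), dtype=bool)
    np.fill_diagonal(a, False)
    return a


def _remove_random(adj: np.ndarray, eligible: np.ndarray, prob: float,
                   rng: np.random.Generator) -> None:
    """Remove each currently-present eligible edge with probability `prob` (in place)."""
    if prob <= 0.0:
        return
    n = adj.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    cand = eligible[iu, ju] & adj[iu, ju]
    if not cand.any():
        return
    drop = cand & (rng.random(len(iu)) < prob)
    adj[iu[drop], ju[drop]] = False
    adj[ju[drop], iu[drop]] = False


def _noise_mask(inside: np.ndarray) -> np.ndarray:
    """Edges with at least one endpoint outside the inside-set."""
    outside = ~inside
    return outside[:, None] | outside[None, :]


def gen_positional_swell(traj: Trajectory, cfg: GraphGenConfig) -> TimeEvolvingGraph:
    """Positional data from a 2-D ring-potential trajectory.

    At each time t, edges whose *both* endpoints lie inside the circle of
    ``cfg.radius`` around the trajectory point are removed with
    ``inside_removal_prob``; edges touching the outside are removed with
    ``noise_removal_prob``.  Snapshots are rebuilt from the complete graph
    at every t.
    """
    if traj.points.shape[1] != 2:
        raise ValueError("positional ring generator needs a 2-D trajectory")
    coords = _random_coords(cfg)
    rng = np.random.default_rng(cfg.edge_seed)
    T = len(traj)
    snaps = np.empty((T, cfg.n, cfg.n), dtype=bool)
    for t in range(T):
        inside = np.linalg.norm(coords - traj.points[t], axis=1) < cfg.radius
        adj = _complete(cfg.n)
        _remove_random(adj, inside[:, None] & inside[None, :], cfg.inside_removal_prob, rng)
        _remove_random(adj, _noise_mask(inside), cfg.noise_removal_prob, rng)
        snaps[t] = adj
    return TimeEvolvingGraph(snaps, coords=coords, states=traj.states.copy())


def gen_positional_doublewell(traj: Trajectory, cfg: GraphGenConfig) -> TimeEvolvingGraph:
    """Positional data from a 1-D double-well trajectory.

    The threshold m is the trajectory mean of x1.  In state 1 snapshots,
    edges among nodes with vertical coordinate b_j > m are removed with
    ``inside_removal_prob``; in state 0 snapshots, edges among nodes with
    b_j <= m are.  Remaining edges touching the complementary set are
    subject to noise removal.
    """
    if traj.points.shape[1] != 1:
        raise ValueError("positional double-well generator needs a 1-D trajectory")
    coords = _random_coords(cfg)
    m = float(traj.points[:, 0].mean())
    upper = coords[:, 1] > m
    rng = np.random.default_rng(cfg.edge_seed)
    T = len(traj)
    snaps = np.empty((T, cfg.n, cfg.n), dtype=bool)
    for t in range(T):
        target = upper if traj.states[t] == 1 else ~upper
        adj = _complete(cfg.n)
        _remove_random(adj, target[:, None] & target[None, :], cfg.inside_removal_prob, rng)
        _remove_random(adj, _noise_mask(target), cfg.noise_removal_prob, rng)
        snaps[t] = adj
    return TimeEvolvingGraph(snaps, coords=coords, states=traj.states.copy())


def upper_node_set(traj: Trajectory, cfg: GraphGenConfig) -> np.ndarray:
    """Boolean mask of the planted "upper" nodes used by the double-well rule."""
    coords = _random_coords(cfg)
    return coords[:, 1] > float(traj.points[:, 0].mean())


def gen_nonpositional(traj: Trajectory, cfg: GraphGenConfig) -> TimeEvolvingGraph:
    """Non-positional data: per-state degree cap inside the moving circle.

    At each time t, the nodes inside the circle around the trajectory point
    (1-D trajectories are embedded as (x, 0)) have their edges to other
    inside nodes pruned uniformly at random until every inside node has at
    most ``per_state_degree[state(t)]`` inside neighbours.  Outside edges
    are only subject to noise removal.
    """
    states_present = set(np.unique(traj.states).tolist())
    missing = states_present - set(cfg.per_state_degree)
    if missing:
        raise ValueError(f"per_state_degree missing states {sorted(missing)}")
    coords = _random_coords(cfg)
    centres = traj.points
    if centres.shape[1] == 1:
        centres = np.hstack([centres, np.zeros_like(centres)])
    rng = np.random.default_rng(cfg.edge_seed)
    T = len(traj)
    snaps = np.empty((T, cfg.n, cfg.n), dtype=bool)
    for t in range(T):
        inside = np.linalg.norm(coords - centres[t], axis=1) < cfg.radius
        adj = _complete(cfg.n)
        _prune_to_degree(adj, inside, cfg.per_state_degree[int(traj.states[t])], rng)
        _remove_random(adj, _noise_mask(inside), cfg.noise_removal_prob, rng)
        snaps[t] = adj
    return TimeEvolvingGraph(snaps, coords=coords, states=traj.states.copy())


def _prune_to_degree(adj: np.ndarray, inside: np.ndarray, k: int,
                     rng: np.random.Generator) -> None:
    """Keep a random max-degree-<=k subgraph of the inside-inside edges (in place)."""
    idx = np.flatnonzero(inside)
    m = len(idx)
    if m < 2:
        return
    iu, ju = np.triu_indices(m, k=1)
    order = rng.permutation(len(iu))
    deg = np.zeros(m, dtype=int)
    keep = np.zeros(len(iu), dtype=bool)
    for e in order:
        a, b = iu[e], ju[e]
        if deg[a] < k and deg[b] < k:
            keep[e] = True
            deg[a] += 1
            deg[b] += 1
    drop = ~keep
    adj[idx[iu[drop]], idx[ju[drop]]] = False
    adj[idx[ju[drop]], idx[iu[drop]]] = False


def snapshot_edge_stats(g: TimeEvolvingGraph) -> dict:
    """Mean/min/max edge counts per snapshot, overall and per state."""
    counts = g.edge_counts()
    out = {
        "mean": float(counts.mean()),
        "min": int(counts.min()),
        "max": int(counts.max()),
        "per_state": {},
    }
    if g.states is not None:
        for s in np.unique(g.states):
            c = counts[g.states == s]
            out["per_state"][int(s)] = {
                "mean": float(c.mean()), "min": int(c.min()), "max": int(c.max()),
            }
    return out


# -- serialization -----------------------------------------------------------

def write_snapshots(g: TimeEvolvingGraph, outdir: str | Path,
                    config: dict | None = None) -> None:
    """Write one TSV edge list per snapshot plus a JSON manifest.

    ``snapshot_<t>.tsv`` holds columns u, v (0-based, u < v, tab-separated,
    header line); ``manifest.json`` records n, T, states, coordinates and
    the generating configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(g.T - 1)))
    for t in range(g.T):
        iu, ju = np.nonzero(np.triu(g.snapshots[t], k=1))
        with (outdir / f"snapshot_{t:0{width}d}.tsv").open("w") as fh:
            fh.write("u\tv\n")
            for a, b in zip(iu, ju):
                fh.write(f"{a}\t{b}\n")
    manifest = {
        "n": int(g.n),
        "T": int(g.T),
        "node_ids": list(map(str, g.node_ids)),
        "states": None if g.states is None else [int(s) for s in g.states],
        "coords": None if g.coords is None else [[float(v) for v in row] for row in g.coords],
        "config": config or {},
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_snapshots(indir: str | Path) -> TimeEvolvingGraph:
    """Read a dataset written by :func:`write_snapshots`."""
    indir = Path(indir)
    with (indir / "manifest.json").open() as fh:
        manifest = json.load(fh)
    n, T = manifest["n"], manifest["T"]
    snaps = np.zeros((T, n, n), dtype=bool)
    files = sorted(indir.glob("snapshot_*.tsv"))
    if len(files) != T:
        raise ValueError(f"expected {T} snapshot files, found {len(files)}")
    for t, path in enumerate(files):
        edges = np.loadtxt(path, delimiter="\t", skiprows=1, dtype=int, ndmin=2)
        if edges.size:
            snaps[t, edges[:, 0], edges[:, 1]] = True
            snaps[t, edges[:, 1], edges[:, 0]] = True
    coords = manifest.get("coords")
    states = manifest.get("states")
    return TimeEvolvingGraph(
        snaps,
        coords=None if coords is None else np.asarray(coords, dtype=float),
        states=None if states is None else np.asarray(states, dtype=int),
        node_ids=manifest.get("node_ids"),
    )


def config_dict(cfg: GraphGenConfig) -> dict:
    d = asdict(cfg)
    d["per_state_degree"] = {str(k): int(v) for k, v in cfg.per_state_degree.items()}
    return d
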
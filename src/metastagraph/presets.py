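"""Experiment presets: dataset + model configurations bundled by name.

Each preset fixes the SDE, the graph generator and the model
hyperparameters for one benchmark dataset family:

* ``npos_2well`` — non-positional double-well data (states differ by the
  inside-circle degree target; learnable from topology alone, PE off);
* ``pos_2well``  — positional double-well data (state-conditional
  half-plane edge removal; PE on);
* ``pos_3well``  — positional three-well ring data (moving-circle removal;
  PE on);
* ``otu_fixture`` — synthetic OTU table turned into a snapshot sequence
  through the correlation-graph / zero-masking path.

``*_small`` variants keep the physical duration of the simulated dynamics
(T * dt = 100 time units) while coarsening the sampling step and shrinking
the node set, so a full train-and-evaluate cycle runs in minutes on one
CPU core.

A single global seed deterministically derives all per-component seeds
(trajectory noise, node coordinates, edge removals, parameter init /
anchor sampling, k-means restarts) via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .dynamics import PotentialSpec, simulate
from .graphgen import (GraphGenConfig, TimeEvolvingGraph, gen_nonpositional,
                       gen_positional_doublewell, gen_positional_swell)
from .otu import correlation_base_graph, synth_otu_fixture, zero_mask_snapshots

__all__ = ["ExperimentConfig", "PRESETS", "get_preset", "derive_seeds", "generate_dataset"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    name: str
    generator: str  # swell | doublewell | nonpositional | otu
    potential: dict = field(default_factory=dict)
    graphgen: dict = field(default_factory=dict)
    otu: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    n_states: int = 2
    train_fraction: float = 0.8
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Derive per-component seeds from one global seed (documented order)."""
    names = ["trajectory", "coords", "edges", "model", "kmeans", "otu"]
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(len(names))
    return {nm: int(c.generate_state(1)[0] % (2**31)) for nm, c in zip(names, children)}


def _preset(name, generator, potential, graphgen, model, n_states, otu=None):
    return ExperimentConfig(name=name, generator=generator, potential=potential,
                            graphgen=graphgen, otu=otu or {}, model=model,
                            n_states=n_states)


# Full-scale presets use T=10000 samples at dt=0.01; the *_small variants
# sample the same 100 time units of dynamics at dt=0.05 with T=2000.
_DW = dict(kind="double_well", beta=2.0)
_SW = dict(kind="s_well", s=3, beta=1.0)

PRESETS: dict[str, ExperimentConfig] = {}


def _register(cfg: ExperimentConfig) -> None:
    PRESETS[cfg.name] = cfg


_register(_preset(
    "npos_2well", "nonpositional",
    dict(_DW, dt=0.01, n_steps=10000),
    dict(n=150, radius=1.2, noise_removal_prob=0.01,
         per_state_degree={0: 8, 1: 30}),
    dict(d=32, epochs=200, use_positional_encoding=False, feature_mode="degree"),
    n_states=2,
))
_register(_preset(
    "npos_2well_small", "nonpositional",
    dict(_DW, dt=0.05, n_steps=2000),
    dict(n=50, radius=1.2, noise_removal_prob=0.01,
         per_state_degree={0: 3, 1: 12}),
    dict(d=32, epochs=50, use_positional_encoding=False, feature_mode="degree"),
    n_states=2,
))
_register(_preset(
    "pos_2well", "doublewell",
    dict(_DW, dt=0.01, n_steps=10000),
    dict(n=100, inside_removal_prob=0.8, noise_removal_prob=0.01),
    dict(d=32, epochs=200, use_positional_encoding=True),
    n_states=2,
))
_register(_preset(
    "pos_2well_small", "doublewell",
    dict(_DW, dt=0.05, n_steps=2000),
    dict(n=50, inside_removal_prob=0.8, noise_removal_prob=0.01),
    dict(d=32, epochs=50, use_positional_encoding=True),
    n_states=2,
))
_register(_preset(
    "pos_3well", "swell",
    dict(_SW, dt=0.01, n_steps=10000),
    dict(n=150, radius=1.0, inside_removal_prob=0.9, noise_removal_prob=0.01),
    dict(d=32, epochs=200, use_positional_encoding=True),
    n_states=3,
))
_register(_preset(
    "pos_3well_small", "swell",
    dict(_SW, dt=0.05, n_steps=2000),
    dict(n=50, radius=1.0, inside_removal_prob=0.9, noise_removal_prob=0.01),
    dict(d=32, epochs=50, use_positional_encoding=True),
    n_states=3,
))
_register(_preset(
    "demo", "nonpositional",
    dict(_DW, dt=0.05, n_steps=600),
    dict(n=20, radius=1.5, noise_removal_prob=0.01, per_state_degree={0: 2, 1: 10}),
    dict(d=4, d_m=16, epochs=15, steps_per_epoch=4, batch_size=32,
         use_positional_encoding=False, feature_mode="degree"),
    n_states=2,
))
_register(_preset(
    "otu_fixture", "otu",
    {}, {}, dict(d=32, epochs=50, use_positional_encoding=False, feature_mode="degree"),
    n_states=2,
    otu=dict(T=300, p=40, n_states=2, zero_rate=0.9, corr_threshold=0.3),
))


def get_preset(name: str, seed: int = 0) -> ExperimentConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = dataclasses.replace(PRESETS[name])
    cfg = ExperimentConfig.from_dict(cfg.to_dict())  # deep copy
    cfg.seed = seed
    return cfg


def generate_dataset(cfg: ExperimentConfig) -> TimeEvolvingGraph:
    """Run the generator chain of a config and return the snapshot sequence."""
    seeds = derive_seeds(cfg.seed)
    if cfg.generator == "otu":
        kwargs = dict(cfg.otu)
        thr = kwargs.pop("corr_threshold", 0.3)
        table, labels = synth_otu_fixture(seed=seeds["otu"], **kwargs)
        base = correlation_base_graph(table, corr_threshold=thr)
        g = zero_mask_snapshots(base, table)
        g.states = np.asarray(labels, dtype=int)
        return g
    spec = PotentialSpec(seed=seeds["trajectory"], **cfg.potential)
    traj = simulate(spec)
    gg_kwargs = dict(cfg.graphgen)
    if "per_state_degree" in gg_kwargs:
        gg_kwargs["per_state_degree"] = {
            int(k): int(v) for k, v in gg_kwargs["per_state_degree"].items()
        }
    gcfg = GraphGenConfig(coord_seed=seeds["coords"], edge_seed=seeds["edges"], **gg_kwargs)
    gen = {
        "swell": gen_positional_swell,
        "doublewell": gen_positional_doublewell,
        "nonpositional": gen_nonpositional,
    }[cfg.generator]
    return gen(traj, gcfg)
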
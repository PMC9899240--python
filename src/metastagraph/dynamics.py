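"""Metastable trajectories from overdamped Langevin dynamics.

Two potential landscapes are provided:

* an s-well "ring" potential in the plane,
  ``V(x) = cos(s * atan2(x2, x1)) + 10 * (sqrt(x1^2 + x2^2) - 1)^2``,
  whose minima sit at radius 1 at angles theta_k = (2k + 1) * pi / s;
* the scalar double-well ``V(x) = x^4 / 4 - x^2 / 2`` with minima at +-1.

Trajectories are sampled with the Euler-Maruyama scheme for
``dX = -grad V(X) dt + sqrt(2 / beta) dW``.  The inverse temperature beta
controls how rare the hops between wells are: the higher beta, the longer
the dwell times.  Every step is labelled with the index of the well whose
basin the point occupies, giving ground-truth metastable state labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PotentialSpec",
    "Trajectory",
    "potential_value",
    "potential_gradient",
    "assign_state",
    "assign_states",
    "simulate",
    "write_trajectory",
    "read_trajectory",
]

_DIVERGENCE_BOUND = 1e6


@dataclass(frozen=True)
class PotentialSpec:
    """Configuration of one Langevin simulation.

    Parameters
    ----------
    kind : {"s_well", "double_well"}
        Potential landscape.  ``s_well`` lives in 2-D, ``double_well`` in 1-D.
    s : int
        Number of wells (ring potential only; the double well has s = 2).
    beta : float
        Inverse temperature; larger values make inter-well hops rarer.
    dt : float
        Euler-Maruyama step size.
    n_steps : int
        Number of recorded points T.
    seed : int
        Seed for the Wiener increments.
    x0 : tuple or float, optional
        Starting point.  Defaults to a well minimum: (cos(pi/s), sin(pi/s))
        for the ring, -1.0 for the double well.
    """

    kind: str
    s: int = 2
    beta: float = 2.0
    dt: float = 1e-2
    n_steps: int = 1000
    seed: int = 0
    x0: tuple | float | None = None

    def __post_init__(self):
        if self.kind not in ("s_well", "double_well"):
            raise ValueError(f"unknown potential kind: {self.kind!r}")
        if self.dt <= 0 or self.beta <= 0 or self.n_steps < 1:
            raise ValueError("dt and beta must be positive, n_steps >= 1")
        if self.kind == "s_well" and self.s < 2:
            raise ValueError("s_well needs s >= 2")

    @property
    def dim(self) -> int:
        return 2 if self.kind == "s_well" else 1

    @property
    def n_states(self) -> int:
        return self.s if self.kind == "s_well" else 2

    def start_point(self) -> np.ndarray:
        if self.x0 is not None:
            x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        elif self.kind == "s_well":
            theta = np.pi / self.s
            x0 = np.array([np.cos(theta), np.sin(theta)])
        else:
            x0 = np.array([-1.0])
        if x0.shape != (self.dim,):
            raise ValueError(f"x0 must have dimension {self.dim} for kind={self.kind!r}")
        return x0


@dataclass
class Trajectory:
    """A sampled path with per-step metastable state labels."""

    points: np.ndarray  # (T, dim)
    states: np.ndarray  # (T,) ints in {0..n_states-1}
    spec: PotentialSpec = field(repr=False)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.states = np.asarray(self.states, dtype=int)
        if len(self.states) != len(self.points):
            raise ValueError("states and points must have equal length")
        if self.states.size and self.states.max() >= self.spec.n_states:
            raise ValueError("state label out of range")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_transitions(self) -> int:
        return int(np.sum(self.states[1:] != self.states[:-1]))


def _check_dim(x: np.ndarray, spec: PotentialSpec) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (spec.dim,):
        raise ValueError(f"point dimension {x.shape} does not match kind={spec.kind!r}")
    return x


def potential_value(x, spec: PotentialSpec) -> float:
    """Evaluate the potential V at a single point."""
    x = _check_dim(x, spec)
    if spec.kind == "double_well":
        v = x[0]
        return float(v**4 / 4.0 - v**2 / 2.0)
    x1, x2 = x
    theta = np.arctan2(x2, x1)  # atan2(0, 0) = 0 by convention
    r = np.hypot(x1, x2)
    return float(np.cos(spec.s * theta) + 10.0 * (r - 1.0) ** 2)


def potential_gradient(x, spec: PotentialSpec) -> np.ndarray:
    """Analytic gradient of the potential at a single point."""
    x = _check_dim(x, spec)
    if spec.kind == "double_well":
        v = x[0]
        return np.array([v**3 - v])
    x1, x2 = x
    r2 = x1 * x1 + x2 * x2
    if r2 == 0.0:
        # The angular term is singular at the origin; the radial term pulls
        # toward the ring in every direction.  Return the radial part only.
        return np.zeros(2)
    r = np.sqrt(r2)
    theta = np.arctan2(x2, x1)
    dang = -spec.s * np.sin(spec.s * theta)
    # grad theta = (-x2, x1) / r^2 ; grad r = (x1, x2) / r
    grad = np.empty(2)
    grad[0] = dang * (-x2 / r2) + 20.0 * (r - 1.0) * (x1 / r)
    grad[1] = dang * (x1 / r2) + 20.0 * (r - 1.0) * (x2 / r)
    return grad


def assign_state(x, spec: PotentialSpec) -> int:
    """Ground-truth well label of a point.

    Double well: 0 for x < 0, else 1.  Ring: index of the angular sector of
    width 2*pi/s centred on well minimum theta_k = (2k+1)*pi/s, i.e.
    ``floor(theta * s / (2*pi))`` with theta wrapped to [0, 2*pi); boundary
    angles fall deterministically into the lower-index sector.
    """
    x = _check_dim(x, spec)
    if spec.kind == "double_well":
        return 0 if x[0] < 0 else 1
    theta = float(np.arctan2(x[1], x[0])) % (2.0 * np.pi)
    k = int(theta * spec.s / (2.0 * np.pi))
    return min(k, spec.s - 1)  # guard against theta == 2*pi after rounding


def simulate(spec: PotentialSpec) -> Trajectory:
    """Sample one Euler-Maruyama path and label every step.

    Raises
    ------
    FloatingPointError
        If the path diverges (|X| > 1e6), which indicates the step size is
        too large for the chosen potential.
    """
    rng = np.random.default_rng(spec.seed)
    dim = spec.dim
    points = np.empty((spec.n_steps, dim))
    x = spec.start_point().copy()
    noise = rng.standard_normal((spec.n_steps, dim)) * np.sqrt(2.0 * spec.dt / spec.beta)
    dt = spec.dt
    if spec.kind == "double_well":
        v = float(x[0])
        for k in range(spec.n_steps):
            points[k, 0] = v
            v += -(v * v * v - v) * dt + noise[k, 0]
            if abs(v) > _DIVERGENCE_BOUND:
                raise FloatingPointError(
                    f"trajectory diverged at step {k} (|X| > {_DIVERGENCE_BOUND:g}); reduce dt"
                )
    else:
        s = spec.s
        x1, x2 = float(x[0]), float(x[1])
        for k in range(spec.n_steps):
            points[k, 0] = x1
            points[k, 1] = x2
            r2 = x1 * x1 + x2 * x2
            if r2 == 0.0:
                g1 = g2 = 0.0
            else:
                r = math.sqrt(r2)
                dang = -s * math.sin(s * math.atan2(x2, x1))
                rad = 20.0 * (r - 1.0) / r
                g1 = dang * (-x2 / r2) + rad * x1
                g2 = dang * (x1 / r2) + rad * x2
            x1 += -g1 * dt + noise[k, 0]
            x2 += -g2 * dt + noise[k, 1]
            if abs(x1) > _DIVERGENCE_BOUND or abs(x2) > _DIVERGENCE_BOUND:
                raise FloatingPointError(
                    f"trajectory diverged at step {k} (|X| > {_DIVERGENCE_BOUND:g}); reduce dt"
                )
    states = assign_states(points, spec)
    return Trajectory(points=points, states=states, spec=spec)


def assign_states(points: np.ndarray, spec: PotentialSpec) -> np.ndarray:
    """Vectorised :func:`assign_state` over the rows of a (T, dim) array."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if spec.kind == "double_well":
        return (points[:, 0] >= 0).astype(int)
    theta = np.arctan2(points[:, 1], points[:, 0]) % (2.0 * np.pi)
    return np.minimum((theta * spec.s / (2.0 * np.pi)).astype(int), spec.s - 1)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as TSV: time_index, x1[, x2], state."""
    path = Path(path)
    dim = traj.points.shape[1]
    cols = ["time_index", "x1"] + (["x2"] if dim == 2 else []) + ["state"]
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, (p, s) in enumerate(zip(traj.points, traj.states)):
            vals = [str(i)] + [f"{v:.17g}" for v in p] + [str(int(s))]
            fh.write("\t".join(vals) + "\n")


def read_trajectory(path: str | Path, spec: PotentialSpec) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    raw = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    points = raw[:, 1:-1]
    states = raw[:, -1].astype(int)
    return Trajectory(points=points, states=states, spec=spec)
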
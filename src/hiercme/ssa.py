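"""Exact stochastic simulation (Gillespie direct method).

Serves as the independent verification oracle for the analytical PGF
machinery: end states sampled at a single time per trajectory are binned
into an empirical pmf and compared to the inverted analytic pmf in total
variation.  The ensemble sampler advances all trajectories synchronously,
one reaction event per vectorized iteration; it draws the same exponential
waiting times and reaction choices as a per-trajectory direct method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inversion import PMF, total_variation  # re-exported: total_variation
from .network import InitialCondition, ReactionNetwork, change_vectors, propensities

__all__ = [
    "Trajectory",
    "simulate_ssa",
    "sample_states",
    "empirical_pmf",
    "total_variation",
]


@dataclass
class Trajectory:
    """Event times and the state after each event (row 0 is the initial state)."""

    times: np.ndarray
    states: np.ndarray
    seed: int

    def __post_init__(self):
        if (np.diff(self.times) < 0).any():
            raise ValueError("event times must be non-decreasing")
        if (self.states < 0).any():
            raise ValueError("negative molecule counts")

    def state_at(self, t: float) -> np.ndarray:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.states[max(idx, 0)]

    def to_tsv(self, species) -> str:
        lines = ["time\t" + "\t".join(species)]
        for t, x in zip(self.times, self.states):
            lines.append(f"{t!r}\t" + "\t".join(str(int(v)) for v in x))
        return "\n".join(lines) + "\n"


def _draw_x0(net: ReactionNetwork, x0, rng, size=None):
    if isinstance(x0, InitialCondition):
        if x0.n != net.n:
            raise ValueError("initial condition species count mismatch")
        shape = (size, net.n) if size else (net.n,)
        out = np.zeros(shape, dtype=np.int64)
        for i, (kind, v) in enumerate(zip(x0.kinds, x0.values)):
            if kind == "det":
                out[..., i] = int(v)
            else:
                out[..., i] = rng.poisson(v, size=size) if size else rng.poisson(v)
        return out
    arr = np.asarray(x0, dtype=np.int64)
    if arr.shape != (net.n,) or (arr < 0).any():
        raise ValueError("x0 must be a non-negative integer state vector")
    return np.tile(arr, (size, 1)) if size else arr.copy()


def simulate_ssa(net: ReactionNetwork, x0, t_end: float, seed: int) -> Trajectory:
    """One exact realization of the Markov jump process up to ``t_end``."""
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    rng = np.random.default_rng(seed)
    x = _draw_x0(net, x0, rng)
    nu = change_vectors(net).T  # (m, n)
    times = [0.0]
    states = [x.copy()]
    t = 0.0
    while True:
        alpha = propensities(net, x)
        a0 = alpha.sum()
        if not np.isfinite(a0):
            raise OverflowError("propensity overflow")
        if a0 <= 0:
            break
        t += rng.exponential(1.0 / a0)
        if t > t_end:
            break
        i = int(np.searchsorted(np.cumsum(alpha), rng.random() * a0))
        x = x + nu[i]
        times.append(t)
        states.append(x.copy())
    return Trajectory(np.array(times), np.array(states), seed)


def _propensity_matrix(net, X):
    """Propensities for a batch of states X (nr, n) -> (nr, m)."""
    nr = X.shape[0]
    alpha = np.tile(net.k, (nr, 1))
    for j, i in zip(*np.nonzero(net.Q)):
        q = int(net.Q[j, i])
        ff = np.ones(nr)
        for d in range(q):
            ff *= np.maximum(X[:, j] - d, 0)
        alpha[:, i] *= ff
    return alpha


def sample_states(
    net: ReactionNetwork, x0, t: float, n_runs: int, seed: int
) -> np.ndarray:
    """End states of ``n_runs`` independent trajectories at time ``t``.

    One end-state sample per run (no time-series reuse), so the rows are
    i.i.d. draws from P(x, t).
    """
    if t < 0 or n_runs < 1:
        raise ValueError("need t >= 0 and n_runs >= 1")
    rng = np.random.default_rng(seed)
    X = _draw_x0(net, x0, rng, size=n_runs)
    nu = change_vectors(net).T.astype(np.int64)
    tcur = np.zeros(n_runs)
    active = np.ones(n_runs, dtype=bool)
    while active.any():
        idx = np.nonzero(active)[0]
        alpha = _propensity_matrix(net, X[idx])
        a0 = alpha.sum(axis=1)
        dead = a0 <= 0
        active[idx[dead]] = False
        if dead.all():
            break
        live = idx[~dead]
        alpha = alpha[~dead]
        a0 = a0[~dead]
        dt = rng.exponential(1.0 / a0)
        tnew = tcur[live] + dt
        fire = tnew <= t
        tcur[live[fire]] = tnew[fire]
        active[live[~fire]] = False
        if fire.any():
            af = alpha[fire]
            r = rng.random(int(fire.sum())) * a0[fire]
            cum = np.cumsum(af, axis=1)
            ri = (cum < r[:, None]).sum(axis=1)
            np.minimum(ri, net.m - 1, out=ri)
            X[live[fire]] += nu[ri]
    return X


def empirical_pmf(endstates: np.ndarray, X, net: ReactionNetwork | None = None) -> PMF:
    """Normalized histogram of species X counts with per-bin Monte-Carlo
    standard errors; the largest standard error becomes the pmf noise floor."""
    endstates = np.asarray(endstates)
    if endstates.size == 0:
        raise ValueError("empty end-state collection")
    if isinstance(X, str):
        if net is None:
            raise ValueError("species name lookup requires the network")
        X = net.index(X)
    counts = np.bincount(endstates[:, X])
    nr = endstates.shape[0]
    p = counts / nr
    stderr = np.sqrt(p * (1 - p) / nr)
    return PMF(p, noise_floor=float(stderr.max()), stderr=stderr)
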
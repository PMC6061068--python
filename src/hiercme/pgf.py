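"""Exact joint probability generating functions for hierarchic networks.

Two independently coded evaluation paths are provided and cross-validated:

* :func:`evaluate_pgf` integrates the characteristic ODEs backward in time
  (always valid; covers influx b != 0 and non-commuting J), and
* :func:`closed_form_pgf` implements the matrix-exponential closed form for
  b = 0 and commuting J, with the time integrals done by adaptive quadrature.

Both return g(s, t) = d(s^0) * influx factor, where d is the initial PGF
(deterministic powers or product-Poisson exponentials) and s^0 is the
characteristic curve traced back to time zero.  A named closed form for
decay chains (Bateman networks with emitted particles) is also included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad_vec, solve_ivp
from scipy.linalg import expm

from .hierarchy import HierarchicDecomposition, decompose_hierarchic
from .network import InitialCondition, ReactionNetwork
from .characteristics import CharacteristicSystem, build_characteristics

__all__ = [
    "PGFHandle",
    "initial_pgf",
    "evaluate_pgf",
    "evaluate_pgf_many",
    "closed_form_pgf",
    "marginal_pgf",
    "numeric_pgf",
    "bateman_pgf",
    "build_bateman_network",
]

_DET_EXPONENT_CAP = 10**6


@dataclass
class PGFHandle:
    """A joint PGF: ``evaluator(S, t)`` maps points ``S`` of shape (..., n)
    and a time ``t >= 0`` to complex values; g(1, t) = 1."""

    evaluator: callable
    ic: InitialCondition
    species: tuple
    method: str

    def __call__(self, S, t):
        return self.evaluator(S, t)


def initial_pgf(ic: InitialCondition, s0) -> np.ndarray:
    """d(s^0): product of ``s0_i^{x_i}`` (deterministic) and
    ``exp(<x>_i (s0_i - 1))`` (Poisson) factors."""
    s0 = np.asarray(s0, dtype=complex)
    if s0.shape[-1] != ic.n:
        raise ValueError("s0 must have one coordinate per species")
    out = np.ones(s0.shape[:-1], dtype=complex)
    for i, (kind, v) in enumerate(zip(ic.kinds, ic.values)):
        if kind == "det":
            x = int(v)
            if x > _DET_EXPONENT_CAP:
                raise OverflowError("deterministic initial count too large")
            if x:
                out = out * s0[..., i] ** x
        else:
            out = out * np.exp(v * (s0[..., i] - 1.0))
    return out


def _backward_characteristics(decomp, S, t, rtol, atol, cs=None):
    """Trace s^0 and the accumulated influx log-factor for a batch of points.

    ``S`` has shape (npts, n).  Returns (s0 array (npts, n), logg (npts,)).
    """
    cs = cs or build_characteristics(decomp)
    net = decomp.net
    S = np.atleast_2d(np.asarray(S, dtype=complex))
    npts = S.shape[0]
    ind, dep = list(decomp.ind_idx), list(decomp.dep_idx)
    n1 = len(ind)
    delta_dep = S[:, dep] - 1.0  # (npts, nd)
    A = decomp.A

    sysI = [i for i, r in enumerate(decomp.roles) if r == "system-I"]
    influx = [i for i, r in enumerate(decomp.roles) if r == "influx"]
    ind_pos = {j: a for a, j in enumerate(ind)}

    def s_full(u, s_ind):
        s = np.empty((npts, net.n), dtype=complex)
        s[:, ind] = s_ind
        if dep:
            # s_dep(tau) = 1 + exp(A^T u) delta  with u = t - tau
            E = expm(A * u)
            s[:, dep] = 1.0 + delta_dep @ E
        return s

    def rhs(u, y):
        y = y.reshape(npts, n1 + 1)
        s = s_full(u, y[:, :n1])
        dy = np.zeros_like(y)
        for i in sysI:
            j = int(np.nonzero(net.Q[:, i])[0][0])
            prod = np.ones(npts, dtype=complex)
            for l in np.nonzero(net.R[:, i])[0]:
                prod = prod * s[:, l] ** int(net.R[l, i])
            dy[:, ind_pos[j]] += net.k[i] * (prod - s[:, j])
        for i in influx:
            prod = np.ones(npts, dtype=complex)
            for l in np.nonzero(net.R[:, i])[0]:
                prod = prod * s[:, l] ** int(net.R[l, i])
            dy[:, n1] += net.k[i] * (prod - 1.0)
        return dy.ravel()

    y0 = np.concatenate([S[:, ind], np.zeros((npts, 1), dtype=complex)], axis=1)
    if t == 0 or (n1 == 0 and not influx):
        yT = y0
        if t == 0:
            s0 = S.copy()
            return s0, np.zeros(npts, dtype=complex)
    else:
        sol = solve_ivp(
            rhs,
            (0.0, t),
            y0.ravel(),
            method="DOP853",
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"characteristic integration failed (rtol={rtol}, atol={atol}): "
                f"{sol.message}"
            )
        yT = sol.y[:, -1].reshape(npts, n1 + 1)
    s0 = np.empty((npts, net.n), dtype=complex)
    s0[:, ind] = yT[:, :n1]
    if dep:
        s0[:, dep] = 1.0 + delta_dep @ expm(A * t)
    return s0, yT[:, n1]


def evaluate_pgf_many(
    decomp: HierarchicDecomposition,
    ic: InitialCondition,
    S,
    t: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    cs: CharacteristicSystem | None = None,
) -> np.ndarray:
    """Vectorized g(s, t) over a batch of points S of shape (npts, n)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    s0, logg = _backward_characteristics(decomp, S, t, rtol, atol, cs=cs)
    return initial_pgf(ic, s0) * np.exp(logg)


def evaluate_pgf(decomp, ic, s, t, rtol=1e-10, atol=1e-12) -> complex:
    """g(s, t) at a single point of the closed unit polydisc."""
    return complex(evaluate_pgf_many(decomp, ic, np.asarray(s)[None, :], t, rtol, atol)[0])


def numeric_pgf(decomp, ic, rtol=1e-10, atol=1e-12) -> PGFHandle:
    """PGFHandle wrapping the backward-characteristic evaluator."""
    cs = build_characteristics(decomp)

    def evaluator(S, t):
        S = np.asarray(S, dtype=complex)
        flat = S.reshape(-1, S.shape[-1])
        vals = evaluate_pgf_many(decomp, ic, flat, t, rtol, atol, cs=cs)
        return vals.reshape(S.shape[:-1])

    return PGFHandle(evaluator, ic, decomp.net.species, "numeric-characteristics")


def _quad_complex(fun, a, b, shape, epsabs, epsrel):
    """Adaptive quadrature of a complex array-valued integrand."""

    def packed(x):
        v = np.asarray(fun(x), dtype=complex).reshape(shape)
        return np.concatenate([v.real.ravel(), v.imag.ravel()])

    res, _ = quad_vec(packed, a, b, epsabs=epsabs, epsrel=epsrel)
    half = res.size // 2
    return (res[:half] + 1j * res[half:]).reshape(shape)


def closed_form_pgf(
    decomp: HierarchicDecomposition,
    cs: CharacteristicSystem,
    ic: InitialCondition,
    epsabs: float = 1e-12,
    epsrel: float = 1e-10,
) -> PGFHandle:
    """Matrix-exponential closed form, valid for b = 0 and commuting J.

    s^0_ind = exp(-int_0^t J dt') s_ind - int_0^t exp(-int_0^{t'} J dt'') f(t') dt'
    s^0_dep = 1 + exp(A^T t)(s_dep - 1), and g = d(s^0).
    """
    if decomp.b.any():
        raise ValueError("closed form requires b = 0; use evaluate_pgf instead")
    if not cs.commuting_J:
        raise ValueError("closed form requires commuting J; use evaluate_pgf instead")
    net = decomp.net
    ind, dep = list(decomp.ind_idx), list(decomp.dep_idx)
    n1 = len(ind)

    def s0_point(s, t):
        s = np.asarray(s, dtype=complex)
        sd = s[dep]
        s0 = np.empty(net.n, dtype=complex)
        if dep:
            s0[dep] = 1.0 + expm(decomp.A.T * t) @ (sd - 1.0)
        if n1:
            if t == 0:
                s0[ind] = s[ind]
            else:
                def IJ(tp):
                    return _quad_complex(
                        lambda tpp: cs.J(sd, tpp, t), 0.0, tp, (n1, n1), epsabs, epsrel
                    )

                E_t = expm(-IJ(t))
                term = _quad_complex(
                    lambda tp: expm(-IJ(tp)) @ cs.f(sd, tp, t),
                    0.0,
                    t,
                    (n1,),
                    epsabs,
                    epsrel,
                )
                s0[ind] = E_t @ s[ind] - term
        return s0

    def evaluator(S, t):
        S = np.asarray(S, dtype=complex)
        flat = S.reshape(-1, S.shape[-1])
        vals = np.array([initial_pgf(ic, s0_point(s, t)) for s in flat])
        return vals.reshape(S.shape[:-1])

    return PGFHandle(evaluator, ic, net.species, "closed-form-commuting")


def marginal_pgf(handle: PGFHandle, X: str, t: float):
    """Univariate PGF of species X: u -> g(1, ..., u, ..., 1; t)."""
    j = handle.species.index(X) if X in handle.species else None
    if j is None:
        raise KeyError(f"unknown species {X!r}")
    n = len(handle.species)

    def gu(u):
        u = np.asarray(u, dtype=complex)
        S = np.ones(u.shape + (n,), dtype=complex)
        S[..., j] = u
        return handle.evaluator(S, t)

    return gu


# ---------------------------------------------------------------------------
# Decay chains with emitted particles
# ---------------------------------------------------------------------------

def build_bateman_network(rates, particle_stoich, particle_names=None) -> ReactionNetwork:
    """Chain X_1 -> X_2 + sum_p R_{p,1} P_p, ..., X_{n-1} -> X_n + ...

    ``rates`` has length n-1; ``particle_stoich`` is an (n_particles, n-1)
    integer array of emitted-particle counts per decay step.
    """
    rates = np.asarray(rates, dtype=float)
    Rp = np.atleast_2d(np.asarray(particle_stoich, dtype=int))
    nsteps = rates.size
    npart = Rp.shape[0]
    if Rp.shape != (npart, nsteps):
        raise ValueError("particle_stoich must be (n_particles, n_steps)")
    nchain = nsteps + 1
    species = tuple(f"X{i+1}" for i in range(nchain)) + tuple(
        particle_names or (f"P{p+1}" for p in range(npart))
    )
    n = nchain + npart
    Q = np.zeros((n, nsteps), dtype=int)
    R = np.zeros((n, nsteps), dtype=int)
    for i in range(nsteps):
        Q[i, i] = 1
        R[i + 1, i] = 1
        R[nchain:, i] = Rp[:, i]
    return ReactionNetwork(species, Q, R, rates)


def bateman_pgf(rates, particle_stoich, ic: InitialCondition, particle_names=None) -> PGFHandle:
    """Explicit partial-fraction closed form for the decay-chain PGF.

    Requires pairwise-distinct rates (the stable end of the chain counts as
    rate 0); on repeated rates falls back to the numeric characteristics
    path with a warning.
    """
    rates = np.asarray(rates, dtype=float)
    Rp = np.atleast_2d(np.asarray(particle_stoich, dtype=int))
    net = build_bateman_network(rates, Rp, particle_names)
    nchain = rates.size + 1
    npart = Rp.shape[0]
    k = np.concatenate([rates, [0.0]])  # k_n = 0: the last isotope is stable
    if len(np.unique(k)) != nchain:
        warnings.warn(
            "repeated decay rates: falling back to numeric characteristics",
            RuntimeWarning,
        )
        return numeric_pgf(decompose_hierarchic(net), ic)

    def chain_matrix(sp_part, t):
        """M with s^0_chain = M s_chain; M_ij = (exp(-A^T t))_{ji}."""
        P = np.ones(nchain - 1, dtype=complex)  # particle monomial per step
        for l in range(nchain - 1):
            for p in range(npart):
                if Rp[p, l]:
                    P[l] *= sp_part[p] ** int(Rp[p, l])
        M = np.zeros((nchain, nchain), dtype=complex)
        for i in range(nchain):
            M[i, i] = np.exp(-k[i] * t)
            for j in range(i + 1, nchain):
                pref = np.prod(k[i:j] * P[i:j])
                tot = 0.0
                for l in range(i, j + 1):
                    den = 1.0
                    for r in range(i, j + 1):
                        if r != l:
                            den *= k[r] - k[l]
                    tot += np.exp(-k[l] * t) / den
                M[i, j] = pref * tot
        return M

    def evaluator(S, t):
        S = np.asarray(S, dtype=complex)
        flat = S.reshape(-1, S.shape[-1])
        out = np.empty(flat.shape[0], dtype=complex)
        for a, s in enumerate(flat):
            M = chain_matrix(s[nchain:], t)
            s0 = np.concatenate([M @ s[:nchain], s[nchain:]])
            out[a] = initial_pgf(ic, s0)
        return out.reshape(S.shape[:-1])

    return PGFHandle(evaluator, ic, net.species, "named-closed-form")
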
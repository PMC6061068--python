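"""Characteristic ODE system of the generating-function PDE.

For a first-order network the PDE for the joint probability generating
function g(s, t) is first order and is solved along characteristic curves
s(tau) obeying

    ds_j/dtau = -sum_i k_i Q_ji ( prod_l s_l^{R_li} - s_j ).

For a two-level hierarchic decomposition the dependent coordinates obey the
closed linear system ds_dep/dt = -A^T (s_dep - 1), and the independent
coordinates obey the time-dependent affine system

    ds_ind/dt' = J(s_dep, t', t) s_ind + f(s_dep, t', t)

with J_pq = sum_i Q_pi k_i (delta_pq - c_i R_qi), the inhomogeneity f
collecting the system-I reactions without independent products, and the
factors c_i the dependent product monomials evaluated along the backward
dependent characteristic.  Influx reactions enter through
d log g / dt = sum_{influx i} k_i (prod_l s_l^{R_li} - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import sympy as sp
from scipy.linalg import expm

from .hierarchy import ROLE_INFLUX, ROLE_SYSTEM_I, HierarchicDecomposition

__all__ = [
    "CharacteristicSystem",
    "CharPoly",
    "build_characteristics",
    "jacobian_charpoly",
    "eigen_depends",
]


def _rat(x: float) -> sp.Rational:
    """Decimal-exact rationalization of a float rate constant."""
    return sp.Rational(Fraction(str(float(x))))


@dataclass
class CharacteristicSystem:
    """Callable right-hand sides, Jacobian J, inhomogeneity f and factors c_i."""

    decomp: HierarchicDecomposition
    commuting_J: bool

    # -- generic characteristic right-hand sides -------------------------------
    def rhs(self, s) -> np.ndarray:
        """ds/dtau for the full coordinate vector (vanishes at s = 1)."""
        net = self.decomp.net
        s = np.asarray(s)
        out = np.zeros_like(s, dtype=complex)
        for i in range(net.m):
            educt = np.nonzero(net.Q[:, i])[0]
            if educt.size == 0:
                continue
            j = int(educt[0])
            prod = 1.0 + 0.0j
            for l in np.nonzero(net.R[:, i])[0]:
                prod = prod * s[l] ** int(net.R[l, i])
            out[j] -= net.k[i] * (prod - s[j])
        return out

    def rhs_logg(self, s) -> complex:
        """d log g / dtau from the zero-order (influx) reactions."""
        net = self.decomp.net
        s = np.asarray(s)
        total = 0.0 + 0.0j
        for i, role in enumerate(self.decomp.roles):
            if role != ROLE_INFLUX:
                continue
            prod = 1.0 + 0.0j
            for l in np.nonzero(net.R[:, i])[0]:
                prod = prod * s[l] ** int(net.R[l, i])
            total += net.k[i] * (prod - 1.0)
        return total

    # -- dependent part, solved exactly ----------------------------------------
    def s_dep_at(self, s_dep_t, tprime: float, t: float) -> np.ndarray:
        """s_dep(t') = 1 + exp(-A^T (t'-t)) (s_dep(t) - 1)."""
        A = self.decomp.A
        delta = np.asarray(s_dep_t) - 1.0
        if A.size == 0:
            return np.asarray(s_dep_t, dtype=complex)
        return 1.0 + expm(-A.T * (tprime - t)) @ delta

    def c_factors(self, s_dep_t, tprime: float, t: float) -> np.ndarray:
        """c_i = prod_{l in dep} s_l(t')^{R_li}; equals 1 at s_dep = 1."""
        net = self.decomp.net
        sd = self.s_dep_at(s_dep_t, tprime, t)
        c = np.ones(net.m, dtype=complex)
        for a, l in enumerate(self.decomp.dep_idx):
            r = net.R[l, :]
            for i in np.nonzero(r)[0]:
                c[i] *= sd[a] ** int(r[i])
        return c

    # -- affine system for the independent coordinates -------------------------
    def J(self, s_dep_t, tprime: float, t: float) -> np.ndarray:
        net, dc = self.decomp.net, self.decomp
        c = self.c_factors(s_dep_t, tprime, t)
        n1 = dc.n_ind
        J = np.zeros((n1, n1), dtype=complex)
        for p_loc, p in enumerate(dc.ind_idx):
            for i in np.nonzero(net.Q[p, :])[0]:
                ki = net.k[i]
                J[p_loc, p_loc] += ki
                for q_loc, q in enumerate(dc.ind_idx):
                    if net.R[q, i]:
                        J[p_loc, q_loc] -= ki * c[i] * net.R[q, i]
        return J

    def f(self, s_dep_t, tprime: float, t: float) -> np.ndarray:
        """Inhomogeneity from system-I reactions with no independent products."""
        net, dc = self.decomp.net, self.decomp
        c = self.c_factors(s_dep_t, tprime, t)
        out = np.zeros(dc.n_ind, dtype=complex)
        ind = set(dc.ind_idx)
        for i, role in enumerate(dc.roles):
            if role != ROLE_SYSTEM_I:
                continue
            if sum(int(net.R[q, i]) for q in ind) > 0:
                continue
            p_loc = dc.ind_idx.index(int(np.nonzero(net.Q[:, i])[0][0]))
            out[p_loc] -= net.k[i] * c[i]
        return out

    # -- symbolic layer ---------------------------------------------------------
    def J_symbolic(self, tau=None):
        """J as a sympy matrix in the dependent symbols ``s_<name>``.

        ``tau`` is the symbolic offset t' - t entering through exp(-A tau);
        ``tau=None`` evaluates at t' = t (the exponential is the identity).
        """
        net, dc = self.decomp.net, self.decomp
        s_dep = sp.Matrix([sp.Symbol(f"s_{net.species[l]}") for l in dc.dep_idx])
        if tau is None or dc.n_dep == 0:
            sd = s_dep
        else:
            A = sp.Matrix(dc.n_dep, dc.n_dep, lambda a, b: _rat(dc.A[a, b]))
            sd = sp.ones(dc.n_dep, 1) + (-A.T * tau).exp() * (s_dep - sp.ones(dc.n_dep, 1))
        c = []
        for i in range(net.m):
            ci = sp.Integer(1)
            for a, l in enumerate(dc.dep_idx):
                if net.R[l, i]:
                    ci *= sd[a] ** int(net.R[l, i])
            c.append(ci)
        n1 = dc.n_ind
        J = sp.zeros(n1, n1)
        for p_loc, p in enumerate(dc.ind_idx):
            for i in np.nonzero(net.Q[p, :])[0]:
                ki = _rat(net.k[i])
                J[p_loc, p_loc] += ki
                for q_loc, q in enumerate(dc.ind_idx):
                    if net.R[q, i]:
                        J[p_loc, q_loc] -= ki * c[i] * int(net.R[q, i])
        return J


@dataclass
class CharPoly:
    """det(lambda I - J) as an exact bivariate polynomial in (lambda, s_X)."""

    expr: sp.Expr
    lam: sp.Symbol
    s: sp.Symbol
    species: str

    def coeffs(self):
        """lambda-coefficients, highest power first (leading coefficient 1)."""
        return sp.Poly(self.expr, self.lam).all_coeffs()

    def eval_roots(self, s_value) -> np.ndarray:
        poly = sp.Poly(self.expr.subs(self.s, s_value), self.lam)
        return np.roots([complex(c) for c in poly.all_coeffs()])


def _commuting_numeric(cs: CharacteristicSystem, rng=None, tol=1e-10) -> bool:
    rng = np.random.default_rng(12345) if rng is None else rng
    dc = cs.decomp
    for _ in range(5):
        sd = rng.uniform(-1, 1, dc.n_dep) + 1j * rng.uniform(-1, 1, dc.n_dep)
        sd /= max(1.0, np.abs(sd).max())
        t = rng.uniform(0.1, 2.0)
        t1, t2 = rng.uniform(0.0, t, 2)
        J1 = cs.J(sd, t1, t)
        J2 = cs.J(sd, t2, t)
        comm = J1 @ J2 - J2 @ J1
        scale = max(1.0, np.abs(J1).max() * np.abs(J2).max())
        if np.abs(comm).max() > tol * scale:
            return False
    return True


def _commuting_symbolic(cs: CharacteristicSystem) -> bool:
    tau1, tau2 = sp.symbols("tau1 tau2", real=True)
    J1 = cs.J_symbolic(tau1)
    J2 = cs.J_symbolic(tau2)
    comm = sp.expand(J1 * J2 - J2 * J1)
    return all(sp.simplify(e) == 0 for e in comm)


def test_commuting(cs: CharacteristicSystem) -> bool:
    """Whether J(t1) and J(t2) commute: symbolically for small systems,
    numerically (5 random time pairs, tolerance 1e-10) otherwise."""
    dc = cs.decomp
    if dc.n_ind == 0:
        return True
    if dc.n_ind <= 6 and dc.n_dep <= 3:
        try:
            return _commuting_symbolic(cs)
        except Exception:  # pragma: no cover - sympy fallback
            pass
    return _commuting_numeric(cs)


# pytest should not collect the commutation predicate as a test
test_commuting.__test__ = False


def build_characteristics(decomp: HierarchicDecomposition) -> CharacteristicSystem:
    cs = CharacteristicSystem(decomp, commuting_J=True)
    cs.commuting_J = test_commuting(cs)
    return cs


def jacobian_charpoly(cs: CharacteristicSystem, X: str) -> CharPoly:
    """Exact characteristic polynomial of J with ``s_X`` symbolic and every
    other dependent coordinate set to 1 (evaluated at t' = t)."""
    dc = cs.decomp
    net = dc.net
    j = net.index(X)
    if j not in dc.dep_idx:
        raise ValueError(f"{X!r} is not a dependent species")
    J = cs.J_symbolic(tau=None)
    sX = sp.Symbol(f"s_{X}")
    subs = {
        sp.Symbol(f"s_{net.species[l]}"): sp.Integer(1)
        for l in dc.dep_idx
        if l != j
    }
    J = J.subs(subs)
    lam = sp.Symbol("lambda")
    expr = sp.expand((lam * sp.eye(dc.n_ind) - J).det())
    return CharPoly(expr, lam, sX, X)


def eigen_depends(cp: CharPoly) -> bool:
    """True iff some eigenvalue of J depends on s_X, i.e. some
    lambda-coefficient of the characteristic polynomial has positive degree
    in s_X (a structural, tolerance-free property)."""
    for coeff in cp.coeffs():
        if sp.Poly(sp.expand(coeff), cp.s).degree() > 0:
            return True
    return False
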
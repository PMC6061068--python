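"""Reaction-network representation, parsing and elementary kinetics.

A network of ``n`` species and ``m`` reactions is held as the pair of
``n x m`` non-negative integer stoichiometric matrices ``Q`` (educts) and
``R`` (products) together with the vector ``k`` of positive rate constants,
so that reaction ``i`` reads ``Q[:, i]^T S -> R[:, i]^T S`` with propensity
``alpha_i(x) = k_i * prod_j x_j! / (x_j - Q_ji)!``.

First-order networks are those with at most one educt molecule per reaction
(every column sum of ``Q`` is <= 1); monomolecular networks additionally
produce at most one molecule per reaction.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ReactionNetwork",
    "NetworkClass",
    "InitialCondition",
    "ReactionParseError",
    "parse_reactions",
    "parse_model",
    "serialize",
    "classify_network",
    "propensities",
    "change_vectors",
    "rate_equation_matrices",
    "rate_equation_mean",
]


class ReactionParseError(ValueError):
    """Raised for malformed reaction-file input; carries the line number."""


@dataclass(frozen=True)
class ReactionNetwork:
    """Immutable container for species, stoichiometry and rate constants."""

    species: tuple
    Q: np.ndarray
    R: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=int)
        R = np.asarray(self.R, dtype=int)
        k = np.asarray(self.k, dtype=float)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "k", k)
        n, m = Q.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one species and one reaction")
        if R.shape != (n, m) or k.shape != (m,):
            raise ValueError("inconsistent Q/R/k dimensions")
        if len(set(self.species)) != n or len(self.species) != n:
            raise ValueError("species identifiers must be unique and match Q rows")
        if (Q < 0).any() or (R < 0).any():
            raise ValueError("stoichiometric coefficients must be >= 0")
        if (k <= 0).any() or not np.isfinite(k).all():
            raise ValueError("rate constants must be positive and finite")

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def m(self) -> int:
        return self.Q.shape[1]

    def index(self, species: str) -> int:
        try:
            return self.species.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None


class NetworkClass(enum.Enum):
    MONOMOLECULAR = "monomolecular"
    FIRST_ORDER = "first-order"
    NOT_FIRST_ORDER = "not-first-order"

    @property
    def label(self) -> str:
        return self.value


@dataclass(frozen=True)
class InitialCondition:
    """Per-species initial distribution: deterministic count or Poisson mean.

    ``kinds[i]`` is ``"det"`` or ``"poisson"``; ``values[i]`` is the count
    (non-negative integer) or the Poisson mean (non-negative float).  Mixed
    products of deterministic and Poissonian coordinates are allowed.
    """

    kinds: tuple
    values: tuple

    def __post_init__(self):
        object.__setattr__(self, "kinds", tuple(self.kinds))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.kinds) != len(self.values):
            raise ValueError("kinds/values length mismatch")
        for kind, v in zip(self.kinds, self.values):
            if kind not in ("det", "poisson"):
                raise ValueError(f"unknown initial-condition kind {kind!r}")
            if not np.isfinite(v) or v < 0:
                raise ValueError("initial counts/means must be finite and >= 0")
            if kind == "det" and v != int(v):
                raise ValueError("deterministic initial counts must be integers")

    @classmethod
    def deterministic(cls, counts) -> "InitialCondition":
        counts = list(counts)
        return cls(("det",) * len(counts), tuple(counts))

    @classmethod
    def poisson(cls, means) -> "InitialCondition":
        means = list(means)
        return cls(("poisson",) * len(means), tuple(means))

    @classmethod
    def mixed(cls, specs) -> "InitialCondition":
        """From a sequence of ("det", x) / ("poisson", mean) pairs."""
        kinds, values = zip(*specs)
        return cls(kinds, values)

    def means(self) -> np.ndarray:
        """First moment per species (equals the count for deterministic specs)."""
        return np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.kinds)


_TERM_RE = re.compile(r"^\s*(?:(\d+)\s*\*?\s*)?([A-Za-z_][A-Za-z0-9_]*)\s*$")


def _parse_side(side: str, lineno: int):
    side = side.strip()
    if side == "0":
        return []
    terms = []
    for raw in side.split("+"):
        mobj = _TERM_RE.match(raw)
        if mobj is None:
            raise ReactionParseError(
                f"line {lineno}: cannot parse species term {raw.strip()!r}"
            )
        coeff = int(mobj.group(1)) if mobj.group(1) else 1
        terms.append((mobj.group(2), coeff))
    return terms


def parse_reactions(text: str) -> ReactionNetwork:
    """Parse reaction lines ``<lhs> -> <rhs> @ <rate>``.

    Each side is ``0`` (no species) or a ``+``-separated list of
    ``[coefficient] species``; ``#`` starts a comment.  Species are ordered
    by first appearance.  ``init`` lines are ignored here (see
    :func:`parse_model`).
    """
    species: list = []
    cols = []  # (educts, products, rate)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.startswith("init "):
            continue
        if "->" not in line or "@" not in line:
            raise ReactionParseError(f"line {lineno}: expected '<lhs> -> <rhs> @ <rate>'")
        lhs, rest = line.split("->", 1)
        rhs, rate_s = rest.rsplit("@", 1)
        try:
            rate = float(rate_s)
        except ValueError:
            raise ReactionParseError(f"line {lineno}: bad rate {rate_s.strip()!r}") from None
        if not np.isfinite(rate) or rate <= 0:
            raise ReactionParseError(f"line {lineno}: rate must be positive, got {rate}")
        educts = _parse_side(lhs, lineno)
        products = _parse_side(rhs, lineno)
        for name, _ in educts + products:
            if name not in species:
                species.append(name)
        cols.append((educts, products, rate))
    if not cols:
        raise ReactionParseError("no reactions found")
    n, m = len(species), len(cols)
    Q = np.zeros((n, m), dtype=int)
    R = np.zeros((n, m), dtype=int)
    k = np.zeros(m)
    idx = {s: i for i, s in enumerate(species)}
    for i, (educts, products, rate) in enumerate(cols):
        for name, c in educts:
            Q[idx[name], i] += c
        for name, c in products:
            R[idx[name], i] += c
        k[i] = rate
    return ReactionNetwork(tuple(species), Q, R, k)


def parse_model(text: str):
    """Parse reactions plus the optional ``init`` block.

    ``init <species> det <int>`` or ``init <species> poisson <float>`` lines
    set the initial condition; species without an ``init`` line default to a
    deterministic count of zero.  Returns ``(network, initial_condition)``.
    """
    net = parse_reactions(text)
    specs = {s: ("det", 0.0) for s in net.species}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line.startswith("init "):
            continue
        parts = line.split()
        if len(parts) != 4 or parts[2] not in ("det", "poisson"):
            raise ReactionParseError(
                f"line {lineno}: expected 'init <species> det|poisson <value>'"
            )
        _, name, kind, value_s = parts
        if name not in net.species:
            raise ReactionParseError(f"line {lineno}: unknown species {name!r}")
        try:
            value = float(value_s)
        except ValueError:
            raise ReactionParseError(f"line {lineno}: bad value {value_s!r}") from None
        specs[name] = (kind, value)
    ic = InitialCondition.mixed([specs[s] for s in net.species])
    return net, ic


def serialize(net: ReactionNetwork, ic: InitialCondition | None = None) -> str:
    """Inverse of :func:`parse_reactions` / :func:`parse_model` (exact round trip)."""

    def side(col):
        terms = [
            (f"{c} " if c != 1 else "") + s
            for s, c in zip(net.species, col)
            if c > 0
        ]
        return " + ".join(terms) if terms else "0"

    lines = [
        f"{side(net.Q[:, i])} -> {side(net.R[:, i])} @ {float(net.k[i])!r}"
        for i in range(net.m)
    ]
    if ic is not None:
        for s, kind, v in zip(net.species, ic.kinds, ic.values):
            val = int(v) if kind == "det" else repr(float(v))
            lines.append(f"init {s} {kind} {val}")
    return "\n".join(lines) + "\n"


def classify_network(net: ReactionNetwork) -> NetworkClass:
    """First-order iff every educt column sum is <= 1; monomolecular iff the
    product column sums are also <= 1."""
    qsum = net.Q.sum(axis=0)
    rsum = net.R.sum(axis=0)
    if (qsum > 1).any():
        return NetworkClass.NOT_FIRST_ORDER
    if (rsum <= 1).all():
        return NetworkClass.MONOMOLECULAR
    return NetworkClass.FIRST_ORDER


def propensities(net: ReactionNetwork, x) -> np.ndarray:
    """Mass-action propensities ``alpha_i(x) = k_i prod_j x_j!/(x_j-Q_ji)!``.

    The falling factorial is zero whenever ``x_j < Q_ji``.
    """
    x = np.asarray(x)
    if x.shape != (net.n,):
        raise ValueError(f"state must have shape ({net.n},), got {x.shape}")
    if (x < 0).any():
        raise ValueError("molecule counts must be >= 0")
    alpha = net.k.astype(float).copy()
    for j, i in zip(*np.nonzero(net.Q)):
        q = net.Q[j, i]
        ff = 1.0
        for d in range(q):
            ff *= max(x[j] - d, 0)
        alpha[i] *= ff
    return alpha


def change_vectors(net: ReactionNetwork) -> np.ndarray:
    """State-change vectors ``n_i = col_i(R - Q)`` as an ``(n, m)`` array."""
    return net.R - net.Q


def rate_equation_matrices(net: ReactionNetwork):
    """``(W, b)`` with ``d<x>/dt = W <x> + b`` for a first-order network."""
    if classify_network(net) is NetworkClass.NOT_FIRST_ORDER:
        raise ValueError("rate equations are linear only for first-order networks")
    n, m = net.n, net.m
    W = np.zeros((n, n))
    b = np.zeros(n)
    nu = change_vectors(net)
    for i in range(m):
        educt = np.nonzero(net.Q[:, i])[0]
        if educt.size == 0:
            b += net.k[i] * net.R[:, i]
        else:
            W[:, educt[0]] += net.k[i] * nu[:, i]
    return W, b


def rate_equation_mean(net: ReactionNetwork, x0, t: float) -> np.ndarray:
    """Mean molecule numbers at time ``t`` from the linear rate equations."""
    W, b = rate_equation_matrices(net)
    x0 = np.asarray(x0, dtype=float)
    E = expm(W * t)
    hom = E @ x0
    if not b.any():
        return hom
    # particular solution via the augmented matrix trick
    n = net.n
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = W
    M[:n, n] = b
    aug = expm(M * t) @ np.concatenate([x0, [1.0]])
    return aug[:n]
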
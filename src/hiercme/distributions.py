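"""Generalized distribution families and pmf modality analysis.

The dependent species of a hierarchic first-order network have marginal
distributions in two generalized families, indexed by the degree N of the
generalizing PGF:

* DCP^N, the discrete compound Poisson laws  exp(sum_{i<=N} lambda a_i (s^i - 1))
  (Poisson initial conditions; DCP^1 is Poisson), and
* KTB^N, Khatri's Type B laws  (sum_{i<=N} a_i s^i)^nu
  (deterministic initial conditions; KTB^1 is Binomial).

Both model burst-like production: the generalizing law is the burst-size
distribution, so pmf modes appear spaced by roughly the burst size.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .inversion import PMF

__all__ = [
    "DCPSpec",
    "KTBSpec",
    "ModeSet",
    "dcp_pmf",
    "ktb_pmf",
    "neyman_a_pmf",
    "find_local_maxima",
    "smooth_pmf",
]


@dataclass(frozen=True)
class DCPSpec:
    """Discrete compound Poisson: rate ``lam`` and burst-size weights
    ``alpha[i-1] = P(burst of size i)``; order N is the largest i with
    alpha_i > 0."""

    lam: float
    alpha: tuple

    def __post_init__(self):
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if any(a < 0 or a > 1 for a in self.alpha) or abs(sum(self.alpha) - 1) > 1e-12:
            raise ValueError("weights must lie in [0,1] and sum to 1")

    @classmethod
    def from_exponent(cls, a) -> "DCPSpec":
        """From exponent coefficients a_i of exp(sum a_i (s^i - 1))."""
        a = [float(x) for x in a]
        lam = sum(a)
        return cls(lam, tuple(x / lam for x in a))

    @property
    def order(self) -> int:
        nz = [i for i, a in enumerate(self.alpha, start=1) if a > 0]
        return nz[-1] if nz else 0

    def pgf(self, s):
        s = np.asarray(s, dtype=complex)
        expo = sum(
            self.lam * a * (s**i - 1) for i, a in enumerate(self.alpha, start=1)
        )
        return np.exp(expo)


@dataclass(frozen=True)
class KTBSpec:
    """Khatri Type B: ``nu`` trials, per-trial outcome weights alpha_0..alpha_N."""

    nu: int
    alpha: tuple

    def __post_init__(self):
        object.__setattr__(self, "alpha", tuple(self.alpha))
        if self.nu < 0 or self.nu != int(self.nu):
            raise ValueError("nu must be a non-negative integer")
        tot = sum(Fraction(a) if isinstance(a, Fraction) else Fraction(str(a)) for a in self.alpha)
        if tot != 1:
            raise ValueError(f"weights must sum to exactly 1, got {tot}")

    @classmethod
    def binomial_binomial(cls, nu: int, p1, n2: int, p2) -> "KTBSpec":
        """Binomial(nu, p1) generalized by Binomial(n2, p2):
        per-trial weights of (1 - p1 + p1 (1 - p2 + p2 s)^{n2})."""
        p1 = Fraction(str(p1))
        p2 = Fraction(str(p2))
        inner = [Fraction(0)] * (n2 + 1)
        from math import comb

        for i in range(n2 + 1):
            inner[i] = comb(n2, i) * p2**i * (1 - p2) ** (n2 - i)
        w = [p1 * c for c in inner]
        w[0] += 1 - p1
        return cls(nu, tuple(w))

    @property
    def order(self) -> int:
        nz = [i for i, a in enumerate(self.alpha) if a != 0]
        return nz[-1] if nz else 0

    def pgf(self, s):
        s = np.asarray(s, dtype=complex)
        inner = sum(float(a) * s**i for i, a in enumerate(self.alpha))
        return inner**self.nu


@dataclass(frozen=True)
class ModeSet:
    """Local-maximum locations of a pmf, with plateau flags."""

    locations: tuple
    plateau: tuple

    def __post_init__(self):
        if list(self.locations) != sorted(set(self.locations)):
            raise ValueError("mode locations must be strictly increasing")

    @property
    def is_unimodal(self) -> bool:
        return len(self.locations) <= 1


def dcp_pmf(spec: DCPSpec, N_trunc: int | None = None) -> PMF:
    """Compound-Poisson recursion: p_0 = e^{-lam},
    p_n = (1/n) sum_{i<=min(n,N)} i lam alpha_i p_{n-i}."""
    order = spec.order
    if N_trunc is None:
        mean = spec.lam * sum(i * a for i, a in enumerate(spec.alpha, start=1))
        var = spec.lam * sum(i * i * a for i, a in enumerate(spec.alpha, start=1))
        N_trunc = int(max(32, np.ceil(mean + 10 * np.sqrt(var) + 20)))
    p = np.zeros(N_trunc + 1)
    p[0] = np.exp(-spec.lam)
    rate = [spec.lam * a for a in spec.alpha]
    for n in range(1, N_trunc + 1):
        acc = 0.0
        for i in range(1, min(n, order) + 1):
            acc += i * rate[i - 1] * p[n - i]
        p[n] = acc / n
    return PMF(p)


def ktb_pmf(spec: KTBSpec) -> PMF:
    """Exact nu-fold convolution of the weight vector (support 0..nu*N).

    Uses exact rational arithmetic when the weights are Fractions/decimal
    strings, so the probabilities sum to exactly 1.
    """
    w = [a if isinstance(a, Fraction) else Fraction(str(a)) for a in spec.alpha]
    out = [Fraction(1)]
    for _ in range(spec.nu):
        new = [Fraction(0)] * (len(out) + len(w) - 1)
        for i, oi in enumerate(out):
            if oi:
                for j, wj in enumerate(w):
                    new[i + j] += oi * wj
        out = new
    return PMF(np.array([float(x) for x in out]), exact=tuple(out))


def neyman_a_pmf(lam: float, phi: float, N_trunc: int | None = None) -> PMF:
    """Neyman Type A (Poisson(lam) generalized by Poisson(phi)):
    mixture over m ~ Poisson(lam) of Poisson(m*phi), the m-sum truncated at
    Poisson tail mass < 1e-14."""
    if lam <= 0 or phi <= 0:
        raise ValueError("lambda and phi must be > 0")
    if N_trunc is None:
        mean, var = lam * phi, lam * phi * (1 + phi)
        N_trunc = int(max(32, np.ceil(mean + 10 * np.sqrt(var) + 20)))
    m_max = int(stats.poisson.isf(1e-14, lam)) + 1
    ns = np.arange(N_trunc + 1)
    p = np.zeros(N_trunc + 1)
    for m in range(m_max + 1):
        wm = stats.poisson.pmf(m, lam)
        p += wm * stats.poisson.pmf(ns, m * phi)
    return PMF(p)


def smooth_pmf(pmf: PMF, window: int = 1) -> PMF:
    """Moving-average blur with an odd window; window=1 is the identity.

    Used before mode counting on Monte-Carlo pmfs so that sampling noise
    does not masquerade as modes; the window should stay well below the
    burst size so real modes survive.
    """
    if window <= 1:
        return pmf
    if window % 2 == 0:
        raise ValueError("window must be odd")
    kern = np.ones(window) / window
    sm = np.convolve(pmf.p, kern, mode="same")
    nf = pmf.noise_floor / np.sqrt(window) if pmf.noise_floor else 0.0
    return PMF(sm, noise_floor=nf)


def find_local_maxima(pmf: PMF, tol: float | None = None) -> ModeSet:
    """Local maxima of the pmf: p_n >= both neighbours, strictly greater on
    at least one side (tolerance-aware); exact-tie plateaus collapse to the
    leftmost point and are flagged."""
    p = pmf.p
    if p.size == 0:
        raise ValueError("empty pmf")
    if tol is None:
        tol = max(pmf.noise_floor, 1e-12) * max(float(p.max()), 1e-300)
    n = p.size
    locs, flags = [], []
    i = 0
    while i < n:
        # maximal run of values tied within tol (plateau), anchored at p[i]
        j = i
        while j + 1 < n and abs(p[j + 1] - p[i]) <= tol:
            j += 1
        rises_left = i > 0 and p[i] > p[i - 1] + tol
        falls_right = j < n - 1 and p[j] > p[j + 1] + tol
        if i == 0 and j == n - 1:
            accept = True  # entirely flat pmf: single (plateau) mode at 0
        elif i == 0:
            accept = falls_right  # left boundary: right comparison only
        elif j == n - 1:
            accept = rises_left  # right boundary: left comparison only
        else:
            accept = rises_left and falls_right
        if accept:
            locs.append(i)
            flags.append(j > i)
        i = j + 1
    return ModeSet(tuple(locs), tuple(flags))
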
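"""PGF inversion: probability mass functions and cumulants.

The pmf is recovered from a univariate PGF by evaluating it at the M-th
roots of unity on the unit circle and applying the inverse discrete Fourier
transform (Cauchy coefficient formula); aliasing of the tail mass onto the
kept coefficients is controlled by doubling M until the result stabilizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PMF",
    "pmf_from_pgf",
    "cumulants_from_pgf",
    "choose_truncation",
    "marginal_pmf",
]


@dataclass
class PMF:
    """Truncated pmf over counts 0..N with mass-deficit bookkeeping.

    ``noise_floor`` records the largest imaginary residue (or Monte-Carlo
    standard error) carried by the probabilities; mode detection uses it as
    a comparison tolerance.
    """

    p: np.ndarray
    noise_floor: float = 0.0
    exact: tuple | None = None  # exact Fraction probabilities when available
    stderr: np.ndarray | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or self.p.size == 0:
            raise ValueError("pmf must be a non-empty 1-D array")
        clip = max(1e-12, self.noise_floor)
        low = self.p.min()
        if low < -max(1e-6, clip):
            raise ValueError(
                f"pmf has probability {low:.3e} < 0 beyond tolerance: "
                "wrong truncation or non-PGF input"
            )
        self.p = np.where((self.p < 0) & (self.p >= -clip), 0.0, self.p)
        if self.p.sum() > 1.0 + 1e-9:
            raise ValueError(f"pmf mass {self.p.sum()} exceeds 1")

    @property
    def N(self) -> int:
        return self.p.size - 1

    @property
    def deficit(self) -> float:
        return 1.0 - float(self.p.sum())

    def mean(self) -> float:
        return float(np.arange(self.p.size) @ self.p)

    def to_tsv(self) -> str:
        lines = ["count\tprobability"]
        lines += [f"{n}\t{pn!r}" for n, pn in enumerate(self.p)]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "truncation": self.N,
                "deficit": self.deficit,
                "noise_floor": self.noise_floor,
                "p": self.p.tolist(),
            }
        )


def total_variation(p: PMF | np.ndarray, q: PMF | np.ndarray) -> float:
    """0.5 * sum |p_n - q_n| over the union support."""
    pa = p.p if isinstance(p, PMF) else np.asarray(p, dtype=float)
    qa = q.p if isinstance(q, PMF) else np.asarray(q, dtype=float)
    L = max(pa.size, qa.size)
    pa = np.pad(pa, (0, L - pa.size))
    qa = np.pad(qa, (0, L - qa.size))
    return 0.5 * float(np.abs(pa - qa).sum())


def _fft_coeffs(gu, M: int):
    u = np.exp(2j * np.pi * np.arange(M) / M)
    vals = np.asarray(gu(u), dtype=complex)
    if vals.shape != (M,):
        raise RuntimeError("PGF evaluator must be vectorized over u")
    if not np.isfinite(vals).all():
        raise RuntimeError("PGF evaluation failed at a unit-circle node")
    coeffs = np.fft.fft(vals) / M
    return coeffs


def pmf_from_pgf(gu, N: int, stable_tol: float = 1e-12, max_M: int = 1 << 22) -> PMF:
    """Invert a univariate PGF into the pmf over counts 0..N.

    Doubles the number of unit-circle nodes until the kept coefficients are
    stable to ``stable_tol``, so that aliased tail mass is negligible.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    M = 1 << max(5, math.ceil(math.log2(2 * (N + 1))))
    prev = None
    while True:
        coeffs = _fft_coeffs(gu, M)
        kept = coeffs[: N + 1]
        if prev is not None and np.abs(kept - prev).max() <= stable_tol:
            break
        if 2 * M > max_M:
            break
        prev = kept
        M *= 2
    noise = float(np.abs(kept.imag).max())
    if noise > 1e-6:
        raise ValueError(f"inversion noise floor {noise:.2e} > 1e-6: input is not a PGF?")
    return PMF(kept.real.copy(), noise_floor=noise)


def cumulants_from_pgf(gu, order: int = 4, h: float = 1e-3) -> np.ndarray:
    """First ``order`` cumulants via central differences of log gu(e^xi)
    at xi = 0, Richardson-extrapolated from steps h and h/2.

    Orders 3 and 4 divide by h^3 and h^4 and would amplify double-precision
    roundoff at the default step, so they use a wider step (2e-2).
    """
    if not 1 <= order <= 4:
        raise ValueError("order must be in 1..4")

    def kappa(xi):
        val = np.asarray(gu(np.exp(np.atleast_1d(xi).astype(complex))))
        return np.log(val)

    def derivs(hh):
        pts = kappa(np.array([-2 * hh, -hh, 0.0, hh, 2 * hh]))
        km2, km1, k0, k1, k2 = pts
        d = np.empty(4, dtype=complex)
        d[0] = (k1 - km1) / (2 * hh)
        d[1] = (k1 - 2 * k0 + km1) / hh**2
        d[2] = (k2 - 2 * k1 + 2 * km1 - km2) / (2 * hh**3)
        d[3] = (k2 - 4 * k1 + 6 * k0 - 4 * km1 + km2) / hh**4
        return d

    dh, dh2 = derivs(h), derivs(h / 2)
    out = (4 * dh2 - dh) / 3
    if order > 2:
        hw = max(h, 2e-2)
        dw, dw2 = derivs(hw), derivs(hw / 2)
        out[2:] = ((4 * dw2 - dw) / 3)[2:]
    out = out[:order]
    if not np.isfinite(out).all():
        raise ValueError("non-finite cumulants")
    return out.real


def choose_truncation(gu, floor: int = 32, cap: int = 1 << 20) -> int:
    """N = ceil(mean + 10 stddev + 20), clamped to [32, 2^20]."""
    kap = cumulants_from_pgf(gu, order=2)
    mean, var = kap[0], max(kap[1], 0.0)
    N = math.ceil(mean + 10.0 * math.sqrt(var) + 20.0)
    return int(min(max(N, floor), cap))


def marginal_pmf(handle, X: str, t: float, N: int | None = None) -> PMF:
    """pmf of species X at time t from a joint PGF handle."""
    from .pgf import marginal_pgf  # local import to avoid a cycle

    gu = marginal_pgf(handle, X, t)
    if N is None:
        N = choose_truncation(gu)
    return pmf_from_pgf(gu, N)
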
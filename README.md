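# hiercme

Exact time-dependent solutions of the chemical master equation (CME) for
**hierarchic first-order reaction networks**, and an algorithmic answer to
the question every single-molecule experimentalist eventually asks of a
molecule-count histogram: *can this marginal distribution be multimodal?*

## Who this is for

Modelers of stochastic reaction networks — transcription–translation
models, splitting/catalytic reactions, nuclear decay chains — who want
exact marginal distributions and structural multimodality verdicts instead
of moment closures or simulation alone.

## The model

A network of `n` species and `m` reactions is given by educt/product
stoichiometric matrices `Q`, `R` (non-negative integers) and rate constants
`k > 0`.  *First-order* networks have at most one educt molecule per
reaction; the joint probability generating function (PGF)

    g(s, t) = Σ_x s^x P(x, t)

then satisfies a first-order PDE, solvable by the method of
characteristics.  A *two-level hierarchic* network splits into an
independent subnetwork (system I, at most one independent product per
reaction) and a dependent monomolecular subnetwork (system II).  The
characteristic ODEs are then hierarchically linear:

    ds_dep/dt  = -Aᵀ (s_dep - 1)                         (exact linear solution)
    ds_ind/dt' =  J(s_dep, t', t) s_ind + f(s_dep, t', t)  (affine, matrix exponentials)
    d log g/dt =  b · (s - 1)                             (influx reactions)

with `A` the conversion/degradation matrix of system II and `b` the influx
rates.  For product-Poisson or deterministic initial conditions the
solution is `g(s, t) = d(s⁰) ·` influx factor, where `s⁰` is the
characteristic traced back to `t = 0`.

Marginals of **independent** species are Poisson (or Binomial⊛Poisson) and
always unimodal.  Marginals of **dependent** species are discrete compound
Poisson `DCP^N` (Poisson ICs) or Khatri Type B `KTB^N` (deterministic ICs),
where `N` is the degree in `s_X` of the log-PGF exponent:

* if an eigenvalue of `J` depends on `s_X` (read off the exact
  characteristic polynomial), `N = ∞` — conditionally multimodal;
* otherwise `N` is finite, computed through a Cayley–Hamilton
  representation of the matrix exponential; `N = 1` is unconditionally
  unimodal, `N ∈ {2, 3}` conditionally multimodal by explicit
  counterexample, finite `N > 3` conditionally multimodal by conjecture
  (flagged as such).

The burst structure is visible in the pmfs: modes sit at multiples of the
burst size of the generalizing distribution.

## Worked example: a decay chain emitting particles

Three isotopes `X1 → X2 → X3`, each decay emitting one particle `Y`
(rates 3.1 and 1.0 s⁻¹; Poisson initial means 2, 0.1, 0.001; no particles
at t = 0):

```python
import numpy as np
from hiercme import *

net, ic = parse_model("""
X1 -> X2 + Y @ 3.1
X2 -> X3 + Y @ 1.0
init X1 poisson 2
init X2 poisson 0.1
init X3 poisson 0.001
init Y det 0
""")
dc = decompose_hierarchic(net)
cs = build_characteristics(dc)
print(classify_marginal(net, dc, cs, "Y", "poisson").to_json())

pmf = marginal_pmf(numeric_pgf(dc, ic), "Y", t=1.5, N=40)
print("P(Y=0..6) =", np.round(pmf.p[:7], 4))
print("modes:", find_local_maxima(pmf).locations)

emp = empirical_pmf(sample_states(net, ic, 1.5, 100_000, seed=1), "Y", net)
print("TV(SSA, analytic) =", round(total_variation(emp, pmf), 4))
```

prints

```
{"species": "Y", "part": "dependent", "family": "DCP^2", "N": 2,
 "verdict": "conditionally-multimodal", "basis": "Theorem 4/Prop. 4",
 "ic_type": "poisson"}
P(Y=0..6) = [0.1276 0.0904 0.2044 0.1296 0.1609 0.0928 0.0834]
modes: (0, 2, 4)
TV(SSA, analytic) = 0.0058
```

The particle marginal is a second-order compound Poisson (`DCP^2`):
particles are released in bursts of up to two (one per decay step), so the
exact pmf at t = 1.5 s has modes at 0, 2 and 4 — spaced by the burst size —
and 10⁵ Gillespie trajectories agree with the inverted PGF to total
variation 0.006.

The same machinery is available from the shell:

```sh
hiercme zoo list
hiercme classify -m catalysis -s Y --ic poisson
hiercme modes -m binbin_ktb2          # -> {"modes": [2, 4], ...}
hiercme compare -m bateman_fig10 -s Y -r 10000 --seed 3
```

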
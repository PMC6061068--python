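"""Two-level hierarchic decomposition of first-order reaction networks.

A first-order network is *two-level hierarchic* when its species split into
an independent part (system I, at most one independent product molecule per
reaction) and a dependent part (system II) that only undergoes monomolecular
conversion/degradation among itself, plus zero-order influx reactions.  The
characteristic ODE system of such a network is hierarchically linear and
therefore solvable by matrix exponentials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .network import NetworkClass, ReactionNetwork, classify_network

__all__ = [
    "HierarchicDecomposition",
    "NotHierarchicError",
    "NotTwoLevelHierarchicError",
    "decompose_hierarchic",
    "validate_decomposition",
    "partition_is_valid",
]

ROLE_SYSTEM_I = "system-I"
ROLE_CONVERSION = "system-II-conversion"
ROLE_DEGRADATION = "system-II-degradation"
ROLE_INFLUX = "influx"


class NotHierarchicError(ValueError):
    """The network is not hierarchically linear (e.g. autocatalytic X -> 2X)."""


class NotTwoLevelHierarchicError(NotHierarchicError):
    """No valid two-level independent/dependent partition exists."""


@dataclass(frozen=True)
class HierarchicDecomposition:
    """Partition into system I / system II with conversion matrix and influx.

    ``A`` is the ``n_dep x n_dep`` matrix of the dependent rate equations
    ``dC_dep/dt = A C_dep + influx`` (off-diagonal ``A[k, j] = alpha_{jk}``,
    diagonal the negative total outflow), and ``b`` is the length-``n``
    influx-rate vector of the zero-order reactions.
    """

    net: ReactionNetwork
    ind_idx: tuple
    dep_idx: tuple
    A: np.ndarray
    b: np.ndarray
    roles: tuple

    @property
    def n_ind(self) -> int:
        return len(self.ind_idx)

    @property
    def n_dep(self) -> int:
        return len(self.dep_idx)

    @property
    def ind_species(self):
        return tuple(self.net.species[i] for i in self.ind_idx)

    @property
    def dep_species(self):
        return tuple(self.net.species[i] for i in self.dep_idx)

    def part_of(self, species: str) -> str:
        i = self.net.index(species)
        return "independent" if i in self.ind_idx else "dependent"


def _reaction_role(net: ReactionNetwork, i: int, ind: set) -> str | None:
    """Role of reaction ``i`` under the candidate independent set, or ``None``
    if the partition is invalid for this reaction."""
    educt = np.nonzero(net.Q[:, i])[0]
    r_ind = sum(int(net.R[j, i]) for j in ind)
    if educt.size == 0:
        return ROLE_INFLUX
    e = int(educt[0])
    if e in ind:
        # system I: at most one independent product molecule
        return ROLE_SYSTEM_I if r_ind <= 1 else None
    # dependent educt: must stay monomolecular within system II
    if r_ind > 0 or net.R[:, i].sum() > 1:
        return None
    return ROLE_CONVERSION if net.R[:, i].sum() == 1 else ROLE_DEGRADATION


def partition_is_valid(net: ReactionNetwork, ind_idx) -> bool:
    ind = set(ind_idx)
    return all(_reaction_role(net, i, ind) is not None for i in range(net.m))


def decompose_hierarchic(net: ReactionNetwork) -> HierarchicDecomposition:
    """Find the canonical two-level decomposition.

    Species that never appear as educts are forced into the dependent part
    (always feasible, and the modality theorems for system II then apply to
    them); among the remaining choices the partition maximizing ``n_ind`` is
    chosen, ties broken by species order.  Raises :class:`NotHierarchicError`
    for autocatalytic reactions and :class:`NotTwoLevelHierarchicError` when
    no valid partition exists.
    """
    cls = classify_network(net)
    if cls is NetworkClass.NOT_FIRST_ORDER:
        raise NotHierarchicError("network is not first-order")
    for i in range(net.m):
        educt = np.nonzero(net.Q[:, i])[0]
        if educt.size and net.R[educt[0], i] > 1:
            raise NotHierarchicError(
                f"reaction {i} is autocatalytic "
                f"({net.species[educt[0]]} appears {net.R[educt[0], i]}x among "
                "its own products): such systems are not hierarchically linear"
            )
    ever_educt = [j for j in range(net.n) if net.Q[j, :].any()]
    # search independent sets from largest; lexicographic by species order
    best = None
    for size in range(len(ever_educt), -1, -1):
        for cand in itertools.combinations(ever_educt, size):
            if partition_is_valid(net, cand):
                best = cand
                break
        if best is not None:
            break
    if best is None:
        raise NotTwoLevelHierarchicError(
            "no valid independent/dependent partition: not two-level hierarchic"
        )
    return decompose_with(net, best)


def decompose_with(net: ReactionNetwork, ind_idx) -> HierarchicDecomposition:
    """Build the decomposition for an explicitly chosen (valid) independent
    set; useful where several partitions are valid and a non-canonical one
    is wanted (e.g. a never-educt chain species placed in system I)."""
    if not partition_is_valid(net, ind_idx):
        raise NotTwoLevelHierarchicError(
            f"independent set {tuple(ind_idx)} violates the two-level invariants"
        )
    best = set(ind_idx)
    ind_idx = tuple(sorted(best))
    dep_idx = tuple(j for j in range(net.n) if j not in best)
    ind = set(ind_idx)
    roles = tuple(_reaction_role(net, i, ind) for i in range(net.m))

    dep_local = {j: a for a, j in enumerate(dep_idx)}
    A = np.zeros((len(dep_idx), len(dep_idx)))
    b = np.zeros(net.n)
    for i, role in enumerate(roles):
        if role == ROLE_INFLUX:
            prod = np.nonzero(net.R[:, i])[0]
            if net.R[:, i].sum() > 1:
                raise NotTwoLevelHierarchicError(
                    "influx reactions must produce a single molecule"
                )
            b[prod[0]] += net.k[i]
        elif role in (ROLE_CONVERSION, ROLE_DEGRADATION):
            e = dep_local[int(np.nonzero(net.Q[:, i])[0][0])]
            A[e, e] -= net.k[i]
            if role == ROLE_CONVERSION:
                p = dep_local[int(np.nonzero(net.R[:, i])[0][0])]
                A[p, e] += net.k[i]
    return HierarchicDecomposition(net, ind_idx, dep_idx, A, b, roles)


def validate_decomposition(decomp: HierarchicDecomposition) -> None:
    """Re-check all structural invariants; raises ``AssertionError`` on failure."""
    net = decomp.net
    assert sorted(decomp.ind_idx + decomp.dep_idx) == list(range(net.n))
    ind = set(decomp.ind_idx)
    for i, role in enumerate(decomp.roles):
        expected = _reaction_role(net, i, ind)
        assert expected == role, f"reaction {i}: role {role} != {expected}"
    assert decomp.A.shape == (decomp.n_dep, decomp.n_dep)
    off = decomp.A - np.diag(np.diag(decomp.A))
    assert (off >= 0).all() and (np.diag(decomp.A) <= 0).all()
    assert (decomp.b >= 0).all()
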
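"""Parsing, classification, propensities and hierarchic decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiercme.hierarchy import (
    NotHierarchicError,
    NotTwoLevelHierarchicError,
    decompose_hierarchic,
    validate_decomposition,
)
from hiercme.network import (
    InitialCondition,
    NetworkClass,
    ReactionParseError,
    classify_network,
    parse_model,
    parse_reactions,
    propensities,
    rate_equation_mean,
    serialize,
)


class TestParsing:
    def test_catalysis_example(self):
        net = parse_reactions("X -> X + Y @ 20.0")
        assert net.species == ("X", "Y")
        assert net.Q[:, 0].tolist() == [1, 0]
        assert net.R[:, 0].tolist() == [1, 1]
        assert net.k.tolist() == [20.0]

    def test_degradation_empty_product(self):
        net = parse_reactions("X -> 0 @ 0.5")
        assert net.Q[:, 0].tolist() == [1]
        assert net.R[:, 0].tolist() == [0]

    def test_coefficient_parsing(self):
        net = parse_reactions("X -> 2 X @ 1.0")
        assert net.Q[0, 0] == 1 and net.R[0, 0] == 2

    @pytest.mark.parametrize(
        "bad",
        ["X -> Y", "X -> Y @ 0.0", "X -> Y @ -1", "-> Y @ 1", "X + -> Y @ 1"],
    )
    def test_errors(self, bad):
        with pytest.raises(ReactionParseError):
            parse_reactions(bad)

    def test_init_block_and_comments(self):
        net, ic = parse_model(
            "# two-stage\n0 -> X @ 1.2\nX -> X + Y @ 10.0  # translation\n"
            "init X poisson 2\ninit Y det 3\n"
        )
        assert ic.kinds == ("poisson", "det")
        assert ic.values == (2.0, 3.0)

    @given(
        st.integers(2, 4).flatmap(
            lambda n: st.lists(
                st.tuples(
                    st.integers(0, n - 1),
                    st.lists(st.tuples(st.integers(0, n - 1), st.integers(1, 3)), max_size=2),
                    st.floats(0.01, 100.0, allow_nan=False),
                ),
                min_size=1,
                max_size=5,
            ).map(lambda rs: (n, rs))
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_serialize_roundtrip(self, spec):
        n, rs = spec
        species = tuple(f"S{i}" for i in range(n))
        Q = np.zeros((n, len(rs)), dtype=int)
        R = np.zeros((n, len(rs)), dtype=int)
        k = np.zeros(len(rs))
        for i, (educt, prods, rate) in enumerate(rs):
            Q[educt, i] = 1
            for p, c in prods:
                R[p, i] += c
            k[i] = rate
        from hiercme.network import ReactionNetwork

        net = ReactionNetwork(species, Q, R, k)
        net2 = parse_reactions(serialize(net))
        # species re-ordered by first appearance; compare via name lookup
        perm = [net2.species.index(s) for s in net.species if s in net2.species]
        assert np.array_equal(net.Q[[net.species.index(net2.species[i]) for i in range(net2.n)]], net2.Q)
        assert np.array_equal(net.R[[net.species.index(net2.species[i]) for i in range(net2.n)]], net2.R)
        assert np.array_equal(net.k, net2.k)


class TestClassification:
    def test_splitting_is_first_order(self):
        assert classify_network(parse_reactions("X -> Y + Z @ 1.0")) is NetworkClass.FIRST_ORDER

    def test_conversions_are_monomolecular(self):
        net = parse_reactions("X -> Y @ 1.0\nY -> 0 @ 2.0\n0 -> X @ 0.3")
        assert classify_network(net) is NetworkClass.MONOMOLECULAR

    def test_two_educts_not_first_order(self):
        assert (
            classify_network(parse_reactions("X + Y -> Z @ 1.0"))
            is NetworkClass.NOT_FIRST_ORDER
        )


class TestPropensities:
    def test_first_order(self):
        net = parse_reactions("X -> X + Y @ 20.0")
        assert propensities(net, np.array([2, 5]))[0] == 40.0

    def test_influx_constant(self):
        net = parse_reactions("0 -> X @ 1.2")
        assert propensities(net, np.array([17]))[0] == 1.2

    def test_zero_educt_count(self):
        net = parse_reactions("X -> 0 @ 3.0")
        assert propensities(net, np.array([0]))[0] == 0.0


class TestDecomposition:
    def test_catalysis(self):
        net = parse_reactions("X -> X + Y @ 20.0")
        dc = decompose_hierarchic(net)
        assert dc.ind_species == ("X",) and dc.dep_species == ("Y",)
        assert not dc.A.any() and not dc.b.any()
        validate_decomposition(dc)

    def test_two_stage(self):
        net = parse_reactions(
            "0 -> X @ 1.2\nX -> 0 @ 1.2\nX -> X + Y @ 10.0\nY -> 0 @ 0.3"
        )
        dc = decompose_hierarchic(net)
        assert dc.ind_species == ("X",) and dc.dep_species == ("Y",)
        assert dc.A.tolist() == [[-0.3]]
        assert dc.b.tolist() == [1.2, 0.0]
        validate_decomposition(dc)

    def test_autocatalysis_rejected(self):
        with pytest.raises(NotHierarchicError, match="not hierarchically linear"):
            decompose_hierarchic(parse_reactions("X -> 2 X @ 1.0"))

    def test_luria_delbruck_variant_rejected(self):
        text = (
            "X -> 2 X @ 1.0\nX -> X + Y @ 0.1\nX -> 0 @ 0.2\n"
            "Y -> 2 Y @ 0.5\nY -> 0 @ 0.3"
        )
        with pytest.raises(NotHierarchicError):
            decompose_hierarchic(parse_reactions(text))

    def test_nested_catalysis_not_two_level(self):
        with pytest.raises(NotTwoLevelHierarchicError):
            decompose_hierarchic(
                parse_reactions("X -> X + Y @ 1.0\nY -> Y + Z @ 1.0")
            )

    def test_deterministic_partition(self):
        # splitting: never-educt species go to the dependent part
        dc = decompose_hierarchic(parse_reactions("X -> Y + Z @ 1.0"))
        assert dc.ind_species == ("X",)
        assert dc.dep_species == ("Y", "Z")
        validate_decomposition(dc)

    def test_monomolecular_system_I_stays_monomolecular(self):
        net = parse_reactions("X1 -> X2 @ 1.0\nX2 -> X3 @ 0.5\nX3 -> 0 @ 0.2")
        dc = decompose_hierarchic(net)
        validate_decomposition(dc)
        sub_R = net.R[np.ix_(list(dc.ind_idx), [i for i, r in enumerate(dc.roles) if r == "system-I"])]
        assert (sub_R.sum(axis=0) <= 1).all()


class TestRateEquations:
    def test_two_stage_mean(self):
        net = parse_reactions(
            "0 -> X @ 1.2\nX -> 0 @ 1.2\nX -> X + Y @ 10.0\nY -> 0 @ 0.3"
        )
        m = rate_equation_mean(net, [0.0, 0.0], 50.0)
        # stationary: <x> = 1, <y> = 10/0.3
        assert np.allclose(m, [1.0, 10.0 / 0.3], rtol=1e-6)


class TestInitialCondition:
    def test_validation(self):
        with pytest.raises(ValueError):
            InitialCondition.deterministic([-1])
        with pytest.raises(ValueError):
            InitialCondition(("det",), (1.5,))
        ic = InitialCondition.mixed([("det", 2), ("poisson", 0.4)])
        assert ic.means().tolist() == [2.0, 0.4]
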
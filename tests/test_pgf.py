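"""PGF evaluation: closed forms, numeric characteristics and cross-checks."""

import numpy as np
import pytest

from hiercme.characteristics import build_characteristics
from hiercme.hierarchy import decompose_hierarchic
from hiercme.inversion import cumulants_from_pgf, marginal_pmf, total_variation
from hiercme.network import InitialCondition, parse_reactions, rate_equation_mean
from hiercme.pgf import (
    bateman_pgf,
    build_bateman_network,
    closed_form_pgf,
    evaluate_pgf,
    initial_pgf,
    marginal_pgf,
    numeric_pgf,
)

from conftest import random_polydisc_points


def eq37(s, t, x0=2.0, y0=0.0, k=20.0):
    """Joint catalysis PGF for Poisson initial conditions."""
    sX, sY = s[..., 0], s[..., 1]
    return np.exp(x0 * (np.exp(k * t * (sY - 1)) * sX - 1) + y0 * (sY - 1))


def eq40(s, t, m=(2.0, 0.5, 0.1), k1=1.3):
    """Joint splitting PGF for Poisson initial conditions."""
    sX, sY, sZ = s[..., 0], s[..., 1], s[..., 2]
    e = np.exp(-k1 * t)
    return np.exp(
        m[0] * (e * sX - sY * sZ * (e - 1) - 1) + m[1] * (sY - 1) + m[2] * (sZ - 1)
    )


class TestInitialPGF:
    def test_deterministic_power(self):
        ic = InitialCondition.deterministic([2, 0])
        assert initial_pgf(ic, np.array([0.5, 0.3])) == pytest.approx(0.25)

    def test_poisson_normalization(self):
        ic = InitialCondition.poisson([2.0])
        assert initial_pgf(ic, np.array([1.0])) == pytest.approx(1.0)

    def test_poisson_at_zero(self):
        ic = InitialCondition.poisson([2.0])
        assert initial_pgf(ic, np.array([0.0])) == pytest.approx(np.exp(-2))


class TestCatalysis:
    def test_numeric_matches_closed_form(self, catalysis, rng):
        _, dc = catalysis
        ic = InitialCondition.poisson([2.0, 0.0])
        pts = random_polydisc_points(rng, 2, 20)
        for s in pts:
            t = rng.uniform(0.01, 0.5)
            assert abs(evaluate_pgf(dc, ic, s, t) - eq37(s, t)) < 1e-8

    def test_closed_form_path(self, catalysis, catalysis_cs):
        ic = InitialCondition.poisson([2.0, 0.0])
        h = closed_form_pgf(catalysis[1], catalysis_cs, ic)
        s = np.array([0.3 + 0.2j, 0.7 - 0.1j])
        assert abs(h(s, 0.13) - eq37(s, 0.13)) < 1e-9

    def test_deterministic_marginal_is_poisson(self, catalysis):
        # g_det(1, s_Y, t) = exp(k t (s_Y - 1))^{x_0}
        _, dc = catalysis
        ic = InitialCondition.deterministic([3, 0])
        h = numeric_pgf(dc, ic)
        gu = marginal_pgf(h, "Y", 0.1)
        u = np.array([0.2, 0.5 + 0.4j, -0.3])
        expected = np.exp(3 * 20.0 * 0.1 * (u - 1))
        assert np.abs(gu(u) - expected).max() < 1e-9


class TestSplitting:
    def test_numeric_and_closed_match_explicit_solution(self, splitting, rng):
        _, dc = splitting
        ic = InitialCondition.poisson([2.0, 0.5, 0.1])
        cs = build_characteristics(dc)
        h = closed_form_pgf(dc, cs, ic)
        pts = random_polydisc_points(rng, 3, 20)
        for s in pts:
            t = rng.uniform(0.01, 1.5)
            ref = eq40(s, t)
            assert abs(evaluate_pgf(dc, ic, s, t) - ref) < 1e-8
            assert abs(h(s, t) - ref) < 1e-8

    def test_marginals_poisson(self, splitting):
        _, dc = splitting
        ic = InitialCondition.poisson([2.0, 0.0, 0.0])
        h = numeric_pgf(dc, ic)
        t = 0.8
        mean = 2.0 * (1 - np.exp(-1.3 * t))
        gu = marginal_pgf(h, "Y", t)
        u = np.array([0.1, 0.6, -0.5 + 0.2j])
        assert np.abs(gu(u) - np.exp(mean * (u - 1))).max() < 1e-9

    def test_splitting_covariance(self, splitting):
        # mixed cumulant Cov(Y, Z) = <x1>_0 (1 - e^{-k1 t})
        _, dc = splitting
        ic = InitialCondition.poisson([2.0, 0.0, 0.0])
        t, h = 0.6, 1e-4
        k = np.zeros((2, 2))

        def kappa(a, b):
            s = np.array([1.0, np.exp(a), np.exp(b)], dtype=complex)
            return np.log(evaluate_pgf(dc, ic, s, t)).real

        cov = (kappa(h, h) - kappa(h, -h) - kappa(-h, h) + kappa(-h, -h)) / (4 * h * h)
        assert cov == pytest.approx(2.0 * (1 - np.exp(-1.3 * t)), abs=1e-6)


class TestInvariants:
    @pytest.mark.parametrize(
        "text,ic",
        [
            ("X -> X + Y @ 20.0", InitialCondition.poisson([2, 0])),
            ("X -> X + Y @ 10.1\nX -> 0 @ 0.5", InitialCondition.poisson([1, 0.001])),
            (
                "0 -> X @ 1.2\nX -> 0 @ 1.2\nX -> X + Y @ 10.0\nY -> 0 @ 0.3",
                InitialCondition.deterministic([0, 0]),
            ),
            ("X -> Y + Z @ 7.0\nY -> X @ 1.875", InitialCondition.poisson([1.875, 1.875, 0])),
        ],
    )
    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_normalization(self, text, ic, t):
        dc = decompose_hierarchic(parse_reactions(text))
        assert abs(evaluate_pgf(dc, ic, np.ones(dc.net.n), t) - 1) < 1e-9

    @pytest.mark.parametrize(
        "text,means",
        [
            ("X -> X + Y @ 20.0", [2.0, 0.0]),
            ("0 -> X @ 1.2\nX -> 0 @ 1.2\nX -> X + Y @ 10.0\nY -> 0 @ 0.3", [0.0, 0.0]),
            ("X -> Y + Z @ 7.0\nY -> X @ 1.875", [1.875, 1.875, 0.0]),
            ("X1 -> X2 + Y @ 3.1\nX2 -> X3 + Y @ 1.0", [2.0, 0.1, 0.001, 0.0]),
        ],
    )
    def test_first_cumulants_match_rate_equations(self, text, means):
        net = parse_reactions(text)
        dc = decompose_hierarchic(net)
        ic = InitialCondition.poisson(means)
        h = numeric_pgf(dc, ic)
        t = 0.7
        expected = rate_equation_mean(net, means, t)
        for i, sp_name in enumerate(net.species):
            gu = marginal_pgf(h, sp_name, t)
            mean = cumulants_from_pgf(gu, order=1)[0]
            assert mean == pytest.approx(expected[i], rel=1e-5, abs=1e-6)

    def test_monomolecular_poisson_preservation(self):
        net = parse_reactions("X1 -> X2 @ 1.0\nX2 -> X3 @ 0.5")
        dc = decompose_hierarchic(net)
        means = [2.0, 1.0, 0.5]
        ic = InitialCondition.poisson(means)
        h = numeric_pgf(dc, ic)
        t = 1.2
        m = rate_equation_mean(net, means, t)
        from scipy import stats

        for i, sp_name in enumerate(net.species):
            pmf = marginal_pmf(h, sp_name, t, N=64)
            ref = stats.poisson.pmf(np.arange(65), m[i])
            assert total_variation(pmf, ref) < 1e-8


class TestBateman:
    def test_daughter_mean_matches_rate_equations(self):
        ic = InitialCondition.poisson([1.7, 0.0, 0.0, 0.0])
        h = bateman_pgf([0.9, 0.4], np.zeros((1, 2), dtype=int), ic, ("P",))
        gu = marginal_pgf(h, "X2", 2.0)
        mean = cumulants_from_pgf(gu, order=1)[0]
        ref = 1.7 * 0.9 * (np.exp(-0.9 * 2) - np.exp(-0.4 * 2)) / (0.4 - 0.9)
        assert mean == pytest.approx(ref, rel=1e-8)

    def test_no_particles_reduces_to_monomolecular_product_poisson(self):
        ic = InitialCondition.poisson([2.0, 0.0, 0.0, 0.0])
        h = bateman_pgf([1.1, 0.6], np.zeros((1, 2), dtype=int), ic, ("P",))
        net = build_bateman_network([1.1, 0.6], np.zeros((1, 2), dtype=int), ("P",))
        t = 0.9
        m = rate_equation_mean(net, [2.0, 0, 0, 0], t)
        for i, sp_name in enumerate(("X1", "X2", "X3")):
            gu = marginal_pgf(h, sp_name, t)
            u = np.array([0.3, -0.2 + 0.5j])
            assert np.abs(gu(u) - np.exp(m[i] * (u - 1))).max() < 1e-10

    def test_agrees_with_numeric_path(self, rng):
        ic = InitialCondition.mixed(
            [("poisson", 2.0), ("poisson", 0.1), ("poisson", 0.001), ("det", 0)]
        )
        h = bateman_pgf([3.1, 1.0], [[1, 1]], ic, ("Y",))
        net = build_bateman_network([3.1, 1.0], [[1, 1]], ("Y",))
        dc = decompose_hierarchic(net)
        for s in random_polydisc_points(rng, 4, 10):
            t = rng.uniform(0.05, 2.0)
            assert abs(h(s, t) - evaluate_pgf(dc, ic, s, t)) < 1e-8

    def test_repeated_rates_fall_back(self):
        ic = InitialCondition.poisson([1.0, 0, 0, 0])
        with pytest.warns(RuntimeWarning, match="repeated decay rates"):
            h = bateman_pgf([0.7, 0.7], [[1, 1]], ic, ("Y",))
        assert abs(h(np.ones(4), 0.5) - 1) < 1e-9
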
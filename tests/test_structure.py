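"""Structure metrics: examples, closed forms, oracle equivalence, invariants."""

import numpy as np
import networkx as nx
import pytest

import persnet as pn
from persnet import TieMatrix

from conftest import (
    make_record,
    oracle_constraint,
    oracle_effective_size_binary,
    random_tie_matrix,
)


def star(k):
    return TieMatrix(np.zeros((k, k), dtype=int))


def complete(k, strength=1):
    s = np.full((k, k), strength, dtype=int)
    np.fill_diagonal(s, 0)
    return TieMatrix(s)


def nx_ego_graph(ties: TieMatrix, weighted: bool) -> nx.Graph:
    """Ego + alters graph with unit ego-alter weights, as networkx sees it."""
    G = nx.Graph()
    G.add_node(0)
    k = ties.k
    for j in range(1, k + 1):
        G.add_edge(0, j, weight=1.0)
    s = ties.strengths if weighted else ties.dichotomized()
    for i in range(k):
        for j in range(i + 1, k):
            if s[i, j] > 0:
                G.add_edge(i + 1, j + 1, weight=float(s[i, j]))
    return G


class TestBasics:
    def test_dichotomization(self):
        s = np.array([[0, 2, 0], [2, 0, 1], [0, 1, 0]])
        d = pn.dichotomized_ties(TieMatrix(s))
        assert (d == np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])).all()

    def test_network_size_counts_full_roster(self):
        assert pn.network_size(make_record(n_alters=12)) == 12
        assert pn.network_size(make_record(n_alters=0)) == 0

    @pytest.mark.parametrize(
        "ties,expected",
        [
            (star(4), 0.0),
            (complete(4), 1.0),
            (TieMatrix(np.array([[0, 1, 1, 0], [1, 0, 1, 0], [1, 1, 0, 0], [0, 0, 0, 0]])), 0.5),
        ],
    )
    def test_density_examples(self, ties, expected):
        assert pn.density(ties) == pytest.approx(expected)

    def test_density_undefined_below_two(self):
        assert pn.density(star(1)) is None

    @pytest.mark.parametrize(
        "ties,expected",
        [
            (complete(4), (3, 3.0)),
            (star(4), (0, 0.0)),
            # path a-b-c: degrees 1, 2, 1
            (TieMatrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])), (2, 4 / 3)),
        ],
    )
    def test_degree_examples(self, ties, expected):
        mx, mean = pn.degree_stats(ties)
        assert mx == expected[0]
        assert mean == pytest.approx(expected[1])


class TestConstraintClosedForms:
    def test_single_alter_fully_constrained(self):
        assert pn.burt_constraint(star(1)) == pytest.approx(100.0)

    @pytest.mark.parametrize("k", [2, 3, 4, 7, 10])
    def test_star_is_100_over_k(self, k):
        assert pn.burt_constraint(star(k)) == pytest.approx(100.0 / k, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 4, 8, 10])
    def test_complete_binary_closed_form(self, k):
        # (2k-1)^2/k^3: ego invests 1/k in each alter, each alter invests
        # 1/k in every contact, so c_ej = ((2k-1)/k^2)^2 summed over k alters
        expected = 100.0 * (2 * k - 1) ** 2 / k**3
        assert pn.burt_constraint(complete(k)) == pytest.approx(expected, abs=1e-12)
        assert pn.burt_constraint(complete(k)) == pytest.approx(
            100 * nx.constraint(nx.complete_graph(k + 1))[0], abs=1e-9
        )

    def test_empty_network_missing(self):
        assert pn.burt_constraint(star(0) if False else TieMatrix(np.zeros((0, 0), int))) is None


class TestEffectiveSize:
    @pytest.mark.parametrize(
        "ties,expected",
        [(star(5), 5.0), (complete(5), 1.0)],
    )
    def test_limits(self, ties, expected):
        assert pn.effective_size(ties) == pytest.approx(expected)

    def test_two_ties_among_four(self):
        s = np.zeros((4, 4), dtype=int)
        s[0, 1] = s[1, 0] = 1
        s[2, 3] = s[3, 2] = 1
        assert pn.effective_size(TieMatrix(s)) == pytest.approx(3.0)

    def test_burt_weighted_variant_matches_networkx(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 11))
            ties = random_tie_matrix(rng, k)
            ours = pn.effective_size(ties, method="burt")
            theirs = nx.effective_size(nx_ego_graph(ties, weighted=True), weight="weight")[0]
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestOracleEquivalence:
    """Implementation vs loop-level brute force vs networkx, random egonets."""

    def test_constraint_and_effective_size_match_oracles(self, rng):
        for _ in range(300):
            k = int(rng.integers(1, 11))
            ties = random_tie_matrix(rng, k)
            c = pn.burt_constraint(ties)
            assert c == pytest.approx(oracle_constraint(ties), abs=1e-9)
            assert c == pytest.approx(
                100 * nx.constraint(nx_ego_graph(ties, weighted=True), weight="weight")[0],
                abs=1e-9,
            )
            es = pn.effective_size(ties)
            assert es == pytest.approx(oracle_effective_size_binary(ties), abs=1e-9)
            assert es == pytest.approx(
                nx.effective_size(nx_ego_graph(ties, weighted=False))[0], abs=1e-9
            )

    def test_binary_constraint_variant_matches_oracle(self, rng):
        for _ in range(100):
            ties = random_tie_matrix(rng, int(rng.integers(1, 11)))
            assert pn.burt_constraint(ties, tie_weights="binary") == pytest.approx(
                oracle_constraint(ties, binary=True), abs=1e-9
            )


class TestInvariants:
    def test_adding_a_tie_is_monotone(self, rng):
        """A new alter-alter tie never lowers density and never raises the
        effective size.  (Constraint is deliberately not asserted: a new tie
        renormalizes every node's proportional investments and can shrink
        indirect paths, so Burt's constraint is not monotone in added ties.)
        """
        for _ in range(100):
            k = int(rng.integers(2, 11))
            ties = random_tie_matrix(rng, k)
            zeros = np.argwhere(np.triu(ties.strengths == 0, 1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            s2 = ties.strengths.copy()
            s2[i, j] = s2[j, i] = int(rng.integers(1, 3))
            t2 = TieMatrix(s2)
            assert pn.density(t2) >= pn.density(ties)
            assert pn.effective_size(t2) <= pn.effective_size(ties)

    def test_bounds_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 14))
            rec = make_record(n_alters=n, strengths=random_tie_matrix(rng, min(n, 10)).strengths)
            m = pn.compute_structure(rec)
            k = min(n, 10)
            if m.density is not None:
                assert 0.0 <= m.density <= 1.0
            assert 1.0 - 1e-12 <= m.effective_size <= k
            assert m.max_degree <= k - 1 or k == 1
            assert m.mean_degree <= m.max_degree + 1e-12


class TestComputeStructure:
    def test_full_roster_size_with_capped_ties(self):
        rec = make_record(n_alters=12, strengths=complete(10).strengths)
        m = pn.compute_structure(rec)
        assert m.network_size == 12
        assert m.density == pytest.approx(1.0)

    def test_empty_roster_all_missing_except_size(self):
        m = pn.compute_structure(make_record(n_alters=0))
        assert m.network_size == 0
        assert (m.density, m.constraint, m.effective_size, m.max_degree, m.mean_degree) == (
            None,
        ) * 5

    def test_half_density_effective_size(self):
        s = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            s[i, j] = s[j, i] = 1
        m = pn.compute_structure(make_record(n_alters=4, strengths=s))
        assert m.density == pytest.approx(0.5)
        assert m.effective_size == pytest.approx(2.5)
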
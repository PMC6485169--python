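from dataclasses import dataclass

import numpy as np
import pytest

from evodiverse.errors import InputError
from evodiverse.selection import (FrontPartition, crowding_distance, dominates,
                                  fast_nondominated_sort, pareto_count,
                                  pareto_rank, select_evo_diverse, select_mea,
                                  select_mea_pr, select_mea_prpc)

import oracles


@dataclass(frozen=True)
class Indiv:
    """Minimal individual: objective vector + total energy."""
    objectives: tuple
    total_energy: float


def make_pop(mat, totals=None):
    mat = np.asarray(mat, float)
    if totals is None:
        totals = mat.sum(axis=1)
    return [Indiv(tuple(float(x) for x in row), float(t))
            for row, t in zip(mat, totals)]


def random_population(rng, n=None, m=None):
    n = n if n is not None else int(rng.integers(4, 65))
    m = m if m is not None else int(rng.choice([2, 3]))
    # small integer grid encourages ties and duplicate vectors
    mat = rng.integers(0, 6, size=(n, m)).astype(float)
    totals = np.round(rng.normal(size=n), 3)
    return mat, totals


class TestDominates:
    def test_strictly_smaller_everywhere(self):
        assert dominates((1, 1, 1), (2, 2, 2))

    def test_equality_in_any_component_blocks_strong_dominance(self):
        assert not dominates((1, 2, 3), (1, 3, 4))

    def test_incomparable_pair(self):
        assert not dominates((1, 3), (3, 1))
        assert not dominates((3, 1), (1, 3))

    def test_dimension_mismatch(self):
        with pytest.raises(InputError):
            dominates((1, 2), (1, 2, 3))


class TestParetoRankCount:
    def test_chain(self):
        mat = [(1, 1), (2, 2), (3, 3)]
        assert list(pareto_rank(mat)) == [0, 1, 2]
        assert list(pareto_count(mat)) == [2, 1, 0]

    def test_identical_vectors_all_zero(self):
        mat = [(1.0, 2.0)] * 5
        assert list(pareto_rank(mat)) == [0] * 5
        assert list(pareto_count(mat)) == [0] * 5

    def test_sum_pr_equals_sum_pc(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mat, _ = random_population(rng)
            pr = pareto_rank(mat)
            pc = pareto_count(mat)
            opr, opc = oracles.pr_pc_oracle(mat)
            assert np.array_equal(pr, opr)
            assert np.array_equal(pc, opc)
            assert pr.sum() == pc.sum()


class TestFastNondominatedSort:
    def test_strong_dominance_keeps_weakly_dominated_in_first_front(self):
        part = fast_nondominated_sort([(1, 1), (1, 2), (2, 2)], n=3)
        assert part.fronts[0] == (0, 1)
        assert part.fronts[1] == (2,)

    def test_identical_vectors_form_single_front(self):
        part = fast_nondominated_sort([(1.0, 1.0)] * 6, n=6)
        assert part.fronts == (tuple(range(6)),)

    def test_stops_once_cumulative_size_reaches_n(self):
        mat = [(i, i) for i in range(10)]
        part = fast_nondominated_sort(mat, n=3)
        assert len(part.fronts) == 3  # singleton fronts

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_peeling_oracle_on_random_populations(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            mat, _ = random_population(rng)
            part = fast_nondominated_sort(mat, n=len(mat))
            expected = oracles.peel_fronts_oracle(mat)
            assert list(part.fronts) == expected


class TestCrowdingDistance:
    def test_fronts_of_one_or_two_are_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([(1.0, 2.0)])))
        assert np.all(np.isinf(crowding_distance([(1.0, 2.0), (3.0, 1.0)])))

    def test_single_objective_normalized_gap(self):
        d = crowding_distance([(0.0,), (5.0,), (10.0,)])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(1.0)

    def test_degenerate_objective_contributes_zero(self):
        d = crowding_distance([(1.0, 0.0), (1.0, 5.0), (1.0, 10.0)])
        assert d[1] == pytest.approx(1.0)  # only the varying objective counts

    def test_matches_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            mat = rng.normal(size=(int(rng.integers(1, 20)), 3))
            assert np.allclose(crowding_distance(mat),
                               oracles.crowding_oracle(mat))


class TestSelectors:
    def split(self, pop):
        half = len(pop) // 2
        return pop[:half], pop[half:]

    def test_all_nondominated_takes_highest_crowding(self):
        rng = np.random.default_rng(2)
        # points on an anti-diagonal: mutually non-dominated
        mat = np.array([(float(i), float(9 - i)) for i in range(10)])
        pop = make_pop(mat)
        out = select_evo_diverse(*self.split(pop), n=5)
        dist = crowding_distance(mat)
        expected = sorted(range(10), key=lambda i: (-dist[i], i))[:5]
        assert out == [pop[i] for i in expected]

    def test_exact_front_fit_returns_front_only(self):
        mat = [(0.0, 0.0)] * 4 + [(5.0, 5.0)] * 4
        pop = make_pop(mat)
        out = select_evo_diverse(pop[:4], pop[4:], n=4)
        assert out == pop[:4]

    def test_first_front_always_survives_when_it_fits(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            mat, totals = random_population(rng, n=20)
            pop = make_pop(mat, totals)
            n = 10
            out = select_evo_diverse(*self.split(pop), n=n)
            f1 = oracles.peel_fronts_oracle(mat)[0]
            if len(f1) <= n:
                assert all(pop[i] in out for i in f1)
            assert len(out) == n
            assert all(o in pop for o in out)

    def test_mea_truncation_with_stable_ties(self):
        mat = np.zeros((6, 3))
        totals = [3.0, 1.0, 2.0, 1.0, 5.0, 0.5]
        pop = make_pop(mat, totals)
        out = select_mea(pop[:3], pop[3:], n=3)
        assert out == [pop[5], pop[1], pop[3]]

    def test_mea_pr_reduces_to_mea_when_all_rank_zero(self):
        mat = np.array([(float(i), float(9 - i)) for i in range(10)])
        totals = list(range(10, 0, -1))
        pop = make_pop(mat, totals)
        assert (select_mea_pr(*self.split(pop), n=4)
                == select_mea(*self.split(pop), n=4))

    def test_mea_prpc_orders_by_pc_within_rank_tie(self):
        # three individuals at rank 0: one dominates 5, one dominates 2
        mat = [(0.0, 0.0), (0.5, 4.0), (4.0, 0.5),
               (1.0, 1.0), (2.0, 2.0), (5.0, 5.0)]
        pop = make_pop(mat, totals=[9.0] * 6)
        out = select_mea_prpc(pop[:3], pop[3:], n=2)
        assert out[0] == pop[0]  # PC 5 before PC <= 2

    @pytest.mark.parametrize("selector,oracle", [
        (select_evo_diverse, oracles.select_evo_diverse_oracle),
        (select_mea, oracles.select_mea_oracle),
        (select_mea_pr, oracles.select_mea_pr_oracle),
        (select_mea_prpc, oracles.select_mea_prpc_oracle),
    ])
    def test_matches_brute_force_oracle_on_random_populations(self, selector, oracle):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n_half = int(rng.integers(2, 17))
            mat, totals = random_population(rng, n=2 * n_half, m=3)
            pop = make_pop(mat, totals)
            out = selector(pop[:n_half], pop[n_half:], n=n_half)
            expected = oracle(mat, totals, n_half)
            assert out == [pop[i] for i in expected]


def test_front_partition_invariants():
    rng = np.random.default_rng(77)
    mat, _ = random_population(rng, n=40, m=3)
    n = 15
    part = fast_nondominated_sort(mat, n=n)
    assert isinstance(part, FrontPartition)
    flat = [i for f in part.fronts for i in f]
    assert len(flat) == len(set(flat))  # disjoint
    assert set(part.fronts[0]) == set(np.flatnonzero(part.pr == 0))
    sizes = np.cumsum([len(f) for f in part.fronts])
    assert sizes[-1] >= n
    assert all(s < n for s in sizes[:-1])
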
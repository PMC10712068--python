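"""Genome operators, objectives, NSGA-II machinery and solution selection."""

import numpy as np
import pytest

from simpd.clustering import Clustering, cluster_dataset, relative_entropy
from simpd.ga import (
    GAConfig,
    ObjectiveTargets,
    SimpdProblem,
    SolutionSet,
    crossover,
    init_population,
    mutate,
    run_simpd,
    score_and_select,
)
from simpd.nsga2 import (
    crowding_distance,
    dominates,
    environmental_selection,
    nondominated_sort,
)
from simpd.spatial import spatial_summary_from_matrix


def _brute_force_fronts(F, cv):
    n = len(F)
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(
                dominates(F[j], F[i], cv[j], cv[i]) for j in remaining if j != i
            )
        ]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


class TestNondominatedSort:
    def test_single_member(self):
        fronts = nondominated_sort(np.array([[1.0, 2.0]]))
        assert [list(f) for f in fronts] == [[0]]

    def test_simple_domination(self):
        fronts = nondominated_sort(np.array([[1.0, 1.0], [2.0, 2.0]]))
        assert [list(f) for f in fronts] == [[0], [1]]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        F = rng.integers(0, 5, size=(20, 3)).astype(float)
        cv = np.where(rng.random(20) < 0.3, rng.random(20), 0.0)
        fronts = nondominated_sort(F, cv)
        assert [sorted(f) for f in fronts] == _brute_force_fronts(F, cv)

    def test_feasible_dominates_infeasible(self):
        F = np.array([[5.0, 5.0], [0.0, 0.0]])
        cv = np.array([0.0, 1.0])
        fronts = nondominated_sort(F, cv)
        assert list(fronts[0]) == [0]

    def test_crowding_boundaries_infinite(self):
        F = np.array([[0.0, 3.0], [1.0, 2.0], [2.0, 1.0], [3.0, 0.0]])
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[3])
        assert np.isfinite(d[1]) and np.isfinite(d[2])


@pytest.fixture(scope="module")
def problem(small_dataset):
    config = GAConfig(population=20, generations=3, seed=0)
    return SimpdProblem(small_dataset, ObjectiveTargets.public(), config)


class TestGenomeOperators:
    def test_init_population_sizes_and_determinism(self, problem):
        rng1 = np.random.default_rng(42)
        pop1 = init_population(problem.clustering, problem.n, problem.quota, 10, rng1)
        assert pop1.sum(axis=1).tolist() == [problem.quota] * 10
        rng2 = np.random.default_rng(42)
        pop2 = init_population(problem.clustering, problem.n, problem.quota, 10, rng2)
        assert np.array_equal(pop1, pop2)

    def test_init_single_cluster_random_subset(self):
        cl = Clustering(np.zeros(50, dtype=int), 1)
        rng = np.random.default_rng(0)
        pop = init_population(cl, 50, 10, 5, rng)
        assert pop.sum(axis=1).tolist() == [10] * 5
        assert not np.array_equal(pop[0], pop[1])  # different random subsets

    def test_init_overshooting_cluster_truncated(self):
        cl = Clustering(np.array([0] * 50 + [1] * 30 + [2] * 20), 3)
        rng = np.random.default_rng(1)
        pop = init_population(cl, 100, 20, 20, rng)
        assert (pop.sum(axis=1) == 20).all()

    def test_mutate_swaps_ten_percent(self):
        rng = np.random.default_rng(0)
        mask = np.zeros(500, dtype=bool)
        mask[:100] = True
        out = mutate(mask, 0.1, rng)
        assert out.sum() == 100
        assert (mask & ~out).sum() == 10  # exactly 10 left the test set
        assert (~mask & out).sum() == 10

    def test_mutate_minimum_one(self):
        rng = np.random.default_rng(0)
        mask = np.zeros(25, dtype=bool)
        mask[:5] = True
        out = mutate(mask, 0.1, rng)
        assert out.sum() == 5
        assert (mask != out).sum() == 2  # one out, one in

    def test_crossover_identical_parents(self):
        rng = np.random.default_rng(0)
        mask = np.zeros(40, dtype=bool)
        mask[:8] = True
        c1, c2 = crossover(mask, mask.copy(), 8, rng)
        assert np.array_equal(c1, mask) and np.array_equal(c2, mask)

    def test_crossover_repairs_quota(self):
        rng = np.random.default_rng(3)
        a = np.zeros(40, dtype=bool)
        a[:8] = True
        b = ~a  # complementary: 32 test bits
        for _ in range(10):
            c1, c2 = crossover(a, b, 8, rng)
            assert c1.sum() == 8 and c2.sum() == 8

    def test_crossover_preserves_agreement_unless_repaired(self):
        rng = np.random.default_rng(5)
        a = np.zeros(60, dtype=bool)
        a[:12] = True
        b = np.zeros(60, dtype=bool)
        b[6:18] = True
        c1, c2 = crossover(a, b, 12, rng)
        agree_on = (a == b) & ~a  # loci both parents call train
        # repair only flips train->test when offspring are short, so shared
        # train loci can only change by repair; shared test loci likewise
        both_test = a & b
        assert (c1[both_test].sum() + (~c1[agree_on]).sum()) >= (
            both_test.sum() + agree_on.sum() - 12
        )


class TestEvaluation:
    def test_spatial_penalties_match_direct_summary(self, problem):
        rng = np.random.default_rng(7)
        mask = np.zeros(problem.n, dtype=bool)
        mask[rng.choice(problem.n, problem.quota, replace=False)] = True
        pens = problem.evaluate(mask)
        s = spatial_summary_from_matrix(
            problem.dist, np.flatnonzero(mask), np.flatnonzero(~mask)
        )
        gf = s.sum_G - s.sum_Fprime
        assert pens[-2] == pytest.approx(max(0, 10 - gf) + max(0, gf - 30))
        assert pens[-1] == pytest.approx(max(0, 70 - s.sum_G))

    def test_hinge_zero_inside_window(self):
        t = ObjectiveTargets.public()
        gf, g = 20.0, 80.0
        assert max(0, t.gf_low - gf) + max(0, gf - t.gf_high) == 0
        assert max(0, t.g_min - g) == 0
        assert max(0, t.g_min - 60.0) == 10.0

    def test_balance_penalty_public_mode(self, problem, small_dataset):
        labels = small_dataset.labels()
        mask = np.zeros(problem.n, dtype=bool)
        mask[np.argsort(~labels)[: problem.quota]] = True  # all-active test set
        pens = problem.evaluate(mask)
        fa_test = labels[mask].mean()
        fa_train = labels[~mask].mean()
        assert pens[4] == pytest.approx(abs((fa_test - fa_train) - 0.11))

    def test_violation_components(self, problem):
        mask = np.zeros(problem.n, dtype=bool)
        mask[: problem.quota] = True
        ent = relative_entropy(np.flatnonzero(mask), problem.clustering)
        expected = max(0.0, ent - 0.9)
        assert problem.violation(mask) == pytest.approx(expected)
        mask[problem.quota] = True  # size off by one
        assert problem.violation(mask) >= 1.0

    def test_even_spread_infeasible(self):
        cl = Clustering(np.array([0, 1, 2, 3] * 25), 4)
        ent = relative_entropy(range(100), cl)
        assert ent == pytest.approx(1.0)
        assert ent >= 0.9  # would violate the entropy constraint


class TestTargets:
    def test_exactly_one_balance_mode(self):
        with pytest.raises(ValueError):
            ObjectiveTargets()  # neither mode set
        with pytest.raises(ValueError):
            ObjectiveTargets(
                frac_active_train=0.4, frac_active_test=0.5, d_frac_active=0.11
            )
        assert ObjectiveTargets.public().public_mode
        t = ObjectiveTargets(frac_active_train=0.4, frac_active_test=0.5)
        assert not t.public_mode
        assert len(t.objective_names) == 8
        assert len(ObjectiveTargets.public().objective_names) == 7


class TestRun:
    def test_zero_generations_returns_initial_front(self, small_dataset):
        config = GAConfig(population=16, generations=0, seed=3)
        sol = run_simpd(small_dataset, ObjectiveTargets.public(), config)
        assert len(sol) >= 1
        assert (sol.genomes.sum(axis=1) == round(0.2 * len(small_dataset))).all()

    def test_determinism(self, small_dataset):
        config = GAConfig(population=16, generations=4, seed=9)
        s1 = run_simpd(small_dataset, ObjectiveTargets.public(), config)
        s2 = run_simpd(small_dataset, ObjectiveTargets.public(), config)
        assert np.array_equal(s1.genomes, s2.genomes)
        assert np.array_equal(s1.objectives, s2.objectives)

    def test_front_contains_no_dominated_member(self, small_dataset):
        config = GAConfig(population=16, generations=4, seed=2)
        sol = run_simpd(small_dataset, ObjectiveTargets.public(), config)
        F = sol.objectives
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j:
                    assert not dominates(F[j], F[i])

    @pytest.mark.parametrize("seed", range(3))
    def test_progress_on_spatial_objectives(self, small_dataset, seed):
        """Best window/floor penalties never regress over the run (elitism:
        per-objective extremes carry infinite crowding distance)."""
        config = GAConfig(population=24, generations=12, seed=seed)
        sol = run_simpd(small_dataset, ObjectiveTargets.public(), config)
        first = sol.generation_log[0]["min_penalties"]
        last = sol.generation_log[-1]["min_penalties"]
        assert last[-1] <= first[-1] + 1e-9
        assert last[-2] <= first[-2] + 1e-9

    def test_every_genome_meets_quota(self, small_dataset):
        config = GAConfig(population=16, generations=3, seed=5)
        sol = run_simpd(small_dataset, ObjectiveTargets.public(), config)
        assert (sol.genomes.sum(axis=1) == round(0.2 * len(small_dataset))).all()
        split = sol.split_for(0)
        split.validate(small_dataset)


class TestScoreAndSelect:
    def _solution_set(self, objectives, mode_objectives=8):
        n_sol, m = objectives.shape
        n = 50
        genomes = np.zeros((n_sol, n), dtype=bool)
        genomes[:, :10] = True
        names = tuple(f"obj{i}" for i in range(m))
        return SolutionSet(
            genomes=genomes,
            objectives=np.asarray(objectives, dtype=float),
            objective_names=names,
            dataset_ids=tuple(f"c{i}" for i in range(n)),
            config=GAConfig(population=4, generations=0, seed=0),
            targets=ObjectiveTargets.public(),
        )

    def test_perfect_solution_scores_21(self):
        F = np.ones((10, 8))
        F[0] = 0.0  # one solution meets every objective exactly
        sol = self._solution_set(F)
        scores, best, _ = score_and_select(sol)
        assert best == 0
        assert scores[0] == pytest.approx(10 + 5 + 6 * 1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        F = rng.random((12, 7))
        s1, b1, _ = score_and_select(self._solution_set(F))
        s2, b2, _ = score_and_select(self._solution_set(F * 2.0))
        assert b1 == b2
        assert np.argsort(s1).tolist() == np.argsort(s2).tolist()

    def test_matches_direct_equation(self):
        rng = np.random.default_rng(4)
        F = rng.random((10, 8)) * np.array([1, 3, 20, 10, 0.2, 0.2, 15, 25])
        sol = self._solution_set(F)
        scores, best, _ = score_and_select(sol)
        # direct evaluation of the weighted exponential score
        scale = np.percentile(F, 90, axis=0)
        w = np.array([1, 1, 1, 1, 1, 1, 10, 5], dtype=float)
        expected = np.array(
            [sum(w[j] * np.exp(-F[i, j] / scale[j]) for j in range(8)) for i in range(10)]
        )
        assert scores == pytest.approx(expected)
        assert best == int(np.argmax(expected))

    def test_constant_objective_scale_fallback(self):
        F = np.ones((5, 7))
        F[:, 3] = 0.0  # constant zero objective: scale falls back to 1
        scores, best, _ = score_and_select(self._solution_set(F))
        assert np.isfinite(scores).all()


def test_environmental_selection_prefers_first_front():
    F = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.5, 0.2]])
    cv = np.zeros(4)
    keep = environmental_selection(F, cv, 2)
    assert set(keep) == {0, 3}
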
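"""GA descriptor selection: fitness, evolution, scrambling, finalization."""

import numpy as np
import pytest

from ghstox import (
    GAConfig,
    GAResult,
    fitness,
    finalize_model,
    ga_run,
    ga_select,
    make_cv_folds,
    scrambling_comparison,
)
from ghstox.ga import GAError, GARunResult


def separable_data(n=60, p=10, seed=0):
    """Column 0 equals the class label numerically; the rest is noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 2, 3], n // 3)
    X = rng.standard_normal((n, p))
    X[:, 0] = y * 10.0
    return X, y


class TestFitness:
    def test_perfect_on_label_column(self):
        X, y = separable_data()
        genes = np.zeros(10, dtype=bool)
        genes[0] = True
        folds = make_cv_folds(len(y), 5)
        assert fitness(genes, X, y, k=1, folds=folds) == 1.0

    def test_noise_columns_near_chance(self):
        ners = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([1, 2, 3], 30)
            X = rng.standard_normal((90, 6))
            genes = np.ones(6, dtype=bool)
            folds = make_cv_folds(90, 5)
            ners.append(fitness(genes, X, y, k=1, folds=folds))
        assert abs(np.mean(ners) - 1 / 3) < 0.1

    def test_deterministic(self):
        X, y = separable_data(seed=5)
        genes = np.array([True] * 5 + [False] * 5)
        folds = make_cv_folds(len(y), 5)
        assert fitness(genes, X, y, 1, folds) == fitness(genes, X, y, 1, folds)

    def test_empty_chromosome_rejected(self):
        X, y = separable_data()
        with pytest.raises(GAError):
            fitness(np.zeros(10, dtype=bool), X, y, 1, make_cv_folds(len(y), 5))


class TestGARun:
    def test_budget_equal_to_population_means_no_evolution(self):
        X, y = separable_data()
        cfg = GAConfig(population_size=12, max_evaluations=12,
                       n_runs_real=1, n_runs_scrambled=0)
        res = ga_run(X, y, cfg, scrambled=False, run_seed=0)
        assert res.evaluations == 12
        assert res.best_fitness == max(res.trajectory)
        assert res.best_fitness == res.trajectory[-1]

    def test_equal_seeds_give_identical_trajectories(self):
        X, y = separable_data()
        cfg = GAConfig(population_size=10, max_evaluations=30)
        r1 = ga_run(X, y, cfg, scrambled=False, run_seed=7)
        r2 = ga_run(X, y, cfg, scrambled=False, run_seed=7)
        assert r1.trajectory == r2.trajectory
        assert np.array_equal(r1.best_genes, r2.best_genes)

    def test_trajectory_monotone_non_decreasing(self):
        X, y = separable_data(seed=2)
        cfg = GAConfig(population_size=10, max_evaluations=40)
        res = ga_run(X, y, cfg, scrambled=False, run_seed=3)
        assert all(b >= a for a, b in zip(res.trajectory, res.trajectory[1:]))

    def test_no_variation_operators_keep_best_constant(self):
        """With zero mutation and crossover every child is a clone (cache
        hit), so the best fitness never moves after initialization."""
        X, y = separable_data(seed=4)
        cfg = GAConfig(population_size=10, max_evaluations=50,
                       crossover_rate=0.0, mutation_rate=0.0)
        res = ga_run(X, y, cfg, scrambled=False, run_seed=1)
        assert res.evaluations == 10  # only the initial population evaluated
        assert res.best_fitness == res.trajectory[-1]

    def test_finds_planted_signal_column(self):
        X, y = separable_data(n=90, p=30, seed=6)
        cfg = GAConfig(population_size=15, max_evaluations=100)
        res = ga_run(X, y, cfg, scrambled=False, run_seed=2)
        assert res.best_fitness == 1.0
        assert res.best_genes[0]  # the label-valued column is selected

    def test_config_invariants_enforced(self):
        X, y = separable_data()
        with pytest.raises(GAError):
            ga_run(X, y, GAConfig(population_size=50, max_evaluations=10),
                   scrambled=False, run_seed=0)
        with pytest.raises(GAError):
            ga_run(X, y, GAConfig(mutation_rate=1.5), scrambled=False, run_seed=0)


class TestScrambling:
    def test_scrambled_best_fitness_near_chance(self):
        """y-scrambling destroys the descriptor/class link, so best NER over
        the run concentrates near 1/G."""
        X, y = separable_data(n=120, p=20, seed=8)
        cfg = GAConfig(population_size=10, max_evaluations=30)
        bests = [
            ga_run(X, y, cfg, scrambled=True, run_seed=s).best_fitness
            for s in range(5)
        ]
        assert abs(np.mean(bests) - 1 / 3) < 0.15

    def test_real_vs_scrambled_gap_on_separable_data(self):
        X, y = separable_data(n=90, p=15, seed=1)
        cfg = GAConfig(population_size=10, max_evaluations=40,
                       n_runs_real=3, n_runs_scrambled=3, base_seed=0)
        result = ga_select(X, y, cfg)
        comp = scrambling_comparison(result)
        # Real runs find the label column (NER 1); scrambled stay near 1/3.
        assert comp["max_gap"] > 0.4
        assert 1 <= comp["recommended_budget"] <= 40

    def test_scrambled_vs_scrambled_gap_near_zero(self):
        X, y = separable_data(n=90, p=15, seed=1)
        cfg = GAConfig(population_size=10, max_evaluations=30)
        runs = [ga_run(X, y, cfg, scrambled=True, run_seed=s) for s in range(6)]
        for r in runs[:3]:
            r.scrambled = False  # relabel: both groups are scrambled draws
        comp = scrambling_comparison(GAResult(runs=runs))
        assert abs(comp["max_gap"]) < 0.12

    def test_unequal_trajectories_aligned_to_shortest(self):
        def mk(traj, scrambled):
            return GARunResult(
                best_genes=np.array([True, False]), best_fitness=traj[-1],
                trajectory=traj, scrambled=scrambled, run_seed=0,
                evaluations=len(traj),
            )
        runs = [mk([0.4, 0.5, 0.6], False), mk([0.4, 0.5], False),
                mk([0.3, 0.3], True), mk([0.3, 0.35, 0.4], True)]
        comp = scrambling_comparison(GAResult(runs=runs))
        assert comp["aligned_to_shortest"]
        assert len(comp["mean_real"]) == 2

    def test_too_few_runs_rejected(self):
        with pytest.raises(GAError):
            scrambling_comparison(GAResult(runs=[]))


class TestFinalize:
    def _result(self, entries):
        runs = []
        for fit, genes in entries:
            g = np.array(genes, dtype=bool)
            runs.append(GARunResult(
                best_genes=g, best_fitness=fit, trajectory=[fit],
                scrambled=False, run_seed=0, evaluations=1,
            ))
        return GAResult(runs=runs)

    def test_single_run_returns_its_best(self):
        X, y = separable_data()
        res = self._result([(0.9, [True, False] + [False] * 8)])
        selected, model, summary = finalize_model(res, X, y, [f"c{i}" for i in range(10)])
        assert selected == ["c0"]
        assert model.k == summary["k"]

    def test_fitness_tie_prefers_fewer_descriptors(self):
        X, y = separable_data()
        big = [True] * 5 + [False] * 5
        small = [True, False, True] + [False] * 7
        res = self._result([(0.8, big), (0.8, small)])
        selected, _, _ = finalize_model(res, X, y, [f"c{i}" for i in range(10)])
        assert len(selected) == 2

    def test_selection_beats_full_matrix_on_planted_data(self):
        """End-to-end sanity: GA-selected subsets are at least as predictive
        in CV as the all-descriptor model on signal-bearing data."""
        wins = 0
        for seed in range(6):
            X, y = separable_data(n=90, p=25, seed=seed)
            cfg = GAConfig(population_size=10, max_evaluations=60,
                           n_runs_real=2, n_runs_scrambled=0, base_seed=seed)
            result = ga_select(X, y, cfg)
            _, _, summary = finalize_model(result, X, y, [f"c{i}" for i in range(25)])
            folds = make_cv_folds(len(y), 5)
            full = fitness(np.ones(25, dtype=bool), X, y, k=1, folds=folds)
            wins += summary["ner_cv_ga"] >= full
        assert wins >= 5

    def test_selection_frequency_shape(self):
        res = self._result([(0.5, [True, False]), (0.6, [True, True])])
        freq = res.selection_frequency()
        assert freq.tolist() == [1.0, 0.5]

    def test_result_json_round_trip(self, tmp_path):
        X, y = separable_data()
        cfg = GAConfig(population_size=8, max_evaluations=16,
                       n_runs_real=2, n_runs_scrambled=2)
        result = ga_select(X, y, cfg)
        path = tmp_path / "ga.json"
        result.save(path)
        back = GAResult.load(path)
        assert len(back.runs) == 4
        for a, b in zip(result.runs, back.runs):
            assert a.trajectory == b.trajectory
            assert np.array_equal(a.best_genes, b.best_genes)
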
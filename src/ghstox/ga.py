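"""Genetic-algorithm descriptor selection wrapped around cross-validated k-NN.

Chromosomes are binary descriptor-inclusion vectors.  Fitness is the
cross-validated non-error rate (NER) of a k-NN classifier built on the
selected columns, so selection directly optimizes the figure of merit the
final model is judged by.

The evaluation budget is calibrated by response scrambling: a batch of runs
on the real class labels is compared with a batch where the labels were
randomly permuted once per run (y-scrambling).  The evaluation count where
the real/scrambled best-fitness gap is largest marks the point beyond which
further search mostly fits noise, and is reported as the recommended budget.

GA mechanics (standard wrapper-selection operators, all exposed in
:class:`GAConfig`): steady-state population of 20, tournament selection of
size 2, uniform crossover applied with probability ``crossover_rate``,
per-gene bit-flip mutation, implicit elitism (a child only ever replaces
the current worst member, and only when strictly better).  The population
is kept small relative to the evaluation budget: initialization costs one
fitness call per member, so a 100-evaluation run with 20 members leaves 80
calls for actual selection.  "Evaluations" count distinct fitness calls; a
chromosome seen before is served from a cache without consuming budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .knn import cv_predictions, fit_knn, make_cv_folds, select_k, KNNModel
from .metrics import confusion, class_metrics


class GAError(ValueError):
    pass


@dataclass
class GAConfig:
    population_size: int = 20
    crossover_rate: float = 0.5
    mutation_rate: float = 0.01
    max_evaluations: int = 100
    max_descriptors: int = 30
    expected_initial_descriptors: int = 5
    n_runs_real: int = 20
    n_runs_scrambled: int = 20
    base_seed: int = 0
    k: int = 1
    n_folds: int = 5

    def validate(self) -> None:
        if self.max_evaluations < self.population_size:
            raise GAError("max_evaluations must be >= population_size")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise GAError(f"{name} must be in [0, 1], got {v}")
        if self.max_descriptors < 1 or self.population_size < 2:
            raise GAError("max_descriptors >= 1 and population_size >= 2 required")


@dataclass
class GARunResult:
    best_genes: np.ndarray  # bool (p,)
    best_fitness: float
    trajectory: list[float]  # best-so-far NER_cv per counted evaluation
    scrambled: bool
    run_seed: int
    evaluations: int

    def to_dict(self) -> dict:
        bits = np.packbits(self.best_genes.astype(np.uint8))
        return {
            "best_genes_hex": bits.tobytes().hex(),
            "n_genes": int(self.best_genes.size),
            "best_fitness": self.best_fitness,
            "trajectory": list(self.trajectory),
            "scrambled": self.scrambled,
            "run_seed": self.run_seed,
            "evaluations": self.evaluations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GARunResult":
        raw = np.frombuffer(bytes.fromhex(d["best_genes_hex"]), dtype=np.uint8)
        genes = np.unpackbits(raw)[: d["n_genes"]].astype(bool)
        return cls(
            best_genes=genes,
            best_fitness=d["best_fitness"],
            trajectory=list(d["trajectory"]),
            scrambled=d["scrambled"],
            run_seed=d["run_seed"],
            evaluations=d["evaluations"],
        )


@dataclass
class GAResult:
    runs: list[GARunResult] = field(default_factory=list)
    column_names: Optional[list[str]] = None

    @property
    def real_runs(self) -> list[GARunResult]:
        return [r for r in self.runs if not r.scrambled]

    @property
    def scrambled_runs(self) -> list[GARunResult]:
        return [r for r in self.runs if r.scrambled]

    def selection_frequency(self) -> np.ndarray:
        """Per-descriptor fraction of real runs whose best chromosome keeps it."""
        real = self.real_runs
        if not real:
            raise GAError("no real runs")
        return np.mean([r.best_genes for r in real], axis=0)

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "ghstox-ga/1",
            "column_names": self.column_names,
            "runs": [r.to_dict() for r in self.runs],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GAResult":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "ghstox-ga/1":
            raise GAError(f"{path}: not a recognized GA result bundle")
        return cls(
            runs=[GARunResult.from_dict(d) for d in payload["runs"]],
            column_names=payload.get("column_names"),
        )


def fitness(
    genes: np.ndarray,
    raw_values: np.ndarray,
    labels: Sequence[int],
    k: int,
    folds: np.ndarray,
    class_order: Optional[Sequence[int]] = None,
) -> float:
    """NER of pooled 5-fold-CV k-NN predictions on the selected columns.

    Deterministic given the fold assignment and k.
    """
    genes = np.asarray(genes, dtype=bool)
    if genes.sum() == 0:
        raise GAError("chromosome selects no descriptors")
    y = np.asarray(labels, dtype=int)
    if class_order is None:
        class_order = sorted(set(y.tolist()))
    preds = cv_predictions(np.asarray(raw_values)[:, genes], y, k=k, folds=folds)
    return class_metrics(confusion(y, preds, class_order)).ner


def _repair(genes: np.ndarray, max_on: int, rng: np.random.Generator) -> np.ndarray:
    """Force popcount into [1, max_on] with random bit flips."""
    genes = genes.copy()
    on = np.flatnonzero(genes)
    if on.size == 0:
        genes[rng.integers(genes.size)] = True
    elif on.size > max_on:
        off = rng.choice(on, size=on.size - max_on, replace=False)
        genes[off] = False
    return genes


def _key(genes: np.ndarray) -> bytes:
    return np.packbits(genes.astype(np.uint8)).tobytes()


def ga_run(
    raw_values: np.ndarray,
    labels: Sequence[int],
    config: GAConfig,
    scrambled: bool,
    run_seed: int,
) -> GARunResult:
    """One GA run; with ``scrambled`` the labels are permuted once at start."""
    config.validate()
    X = np.asarray(raw_values, dtype=float)
    n, p = X.shape
    if p < 2:
        raise GAError("need at least 2 descriptor columns")
    rng = np.random.default_rng(run_seed)
    y = np.asarray(labels, dtype=int)
    if scrambled:
        y = rng.permutation(y)
    class_order = sorted(set(np.asarray(labels, dtype=int).tolist()))
    folds = make_cv_folds(n, n_folds=config.n_folds)

    p_on = min(1.0, config.expected_initial_descriptors / p)
    cache: dict[bytes, float] = {}
    trajectory: list[float] = []
    best_so_far = -np.inf

    def evaluate(genes: np.ndarray) -> Optional[float]:
        """Returns fitness, counting budget only for unseen chromosomes."""
        nonlocal best_so_far
        key = _key(genes)
        if key in cache:
            return cache[key]
        if len(trajectory) >= config.max_evaluations:
            return None  # budget exhausted
        fit = fitness(genes, X, y, k=config.k, folds=folds, class_order=class_order)
        cache[key] = fit
        best_so_far = max(best_so_far, fit)
        trajectory.append(best_so_far)
        return fit

    population: list[np.ndarray] = []
    pop_fitness: list[float] = []
    for _ in range(config.population_size):
        genes = _repair(rng.random(p) < p_on, config.max_descriptors, rng)
        fit = evaluate(genes)
        if fit is None:
            break
        population.append(genes)
        pop_fitness.append(fit)

    def tournament() -> int:
        a, b = rng.integers(len(population), size=2)
        return int(a if pop_fitness[a] >= pop_fitness[b] else b)

    # Steady-state loop; the generation cap terminates runs whose children
    # are all cache hits (e.g. zero mutation and crossover).
    max_generations = 50 * config.max_evaluations
    for _ in range(max_generations):
        if len(trajectory) >= config.max_evaluations:
            break
        pa, pb = tournament(), tournament()
        child = population[pa].copy()
        if rng.random() < config.crossover_rate:
            swap = rng.random(p) < 0.5
            child[swap] = population[pb][swap]
        flip = rng.random(p) < config.mutation_rate
        child = child ^ flip
        child = _repair(child, config.max_descriptors, rng)
        fit = evaluate(child)
        if fit is None:
            break
        worst = int(np.argmin(pop_fitness))
        if fit > pop_fitness[worst]:
            population[worst] = child
            pop_fitness[worst] = fit

    best_idx = int(np.argmax(pop_fitness))
    # The population's best always equals the best evaluated chromosome:
    # a better child always replaces the worst member.
    best_genes = population[best_idx]
    best_fit = pop_fitness[best_idx]
    for key, fit in cache.items():
        if fit > best_fit:
            raw = np.frombuffer(key, dtype=np.uint8)
            best_genes = np.unpackbits(raw)[:p].astype(bool)
            best_fit = fit
    return GARunResult(
        best_genes=np.asarray(best_genes, dtype=bool),
        best_fitness=float(best_fit),
        trajectory=trajectory,
        scrambled=scrambled,
        run_seed=run_seed,
        evaluations=len(trajectory),
    )


def ga_select(
    raw_values: np.ndarray,
    labels: Sequence[int],
    config: GAConfig,
    column_names: Optional[Sequence[str]] = None,
) -> GAResult:
    """Run the full batch: ``n_runs_real`` on the true labels followed by
    ``n_runs_scrambled`` on per-run permuted labels.  Run i uses seed
    ``base_seed + i``."""
    runs: list[GARunResult] = []
    for i in range(config.n_runs_real):
        runs.append(ga_run(raw_values, labels, config, scrambled=False,
                           run_seed=config.base_seed + i))
    for i in range(config.n_runs_scrambled):
        runs.append(ga_run(raw_values, labels, config, scrambled=True,
                           run_seed=config.base_seed + config.n_runs_real + i))
    return GAResult(runs=runs,
                    column_names=list(column_names) if column_names is not None else None)


def scrambling_comparison(result: GAResult) -> dict:
    """Mean best-so-far fitness of real vs scrambled runs per evaluation.

    Trajectories of unequal length are aligned to the shortest (noted in the
    output).  The evaluation count with the largest real-minus-scrambled gap
    is the recommended budget.
    """
    real = result.real_runs
    scram = result.scrambled_runs
    if len(real) < 2 or len(scram) < 2:
        raise GAError("need at least 2 real and 2 scrambled runs")
    lengths = [len(r.trajectory) for r in real + scram]
    L = min(lengths)
    truncated = L < max(lengths)
    mean_real = np.mean([r.trajectory[:L] for r in real], axis=0)
    mean_scrambled = np.mean([r.trajectory[:L] for r in scram], axis=0)
    gap = mean_real - mean_scrambled
    best_eval = int(np.argmax(gap)) + 1
    return {
        "evaluations": list(range(1, L + 1)),
        "mean_real": mean_real.tolist(),
        "mean_scrambled": mean_scrambled.tolist(),
        "gap": gap.tolist(),
        "recommended_budget": best_eval,
        "max_gap": float(gap.max()),
        "aligned_to_shortest": truncated,
    }


def finalize_model(
    result: GAResult,
    raw_values: np.ndarray,
    labels: Sequence[int],
    column_names: Sequence[str],
    k_grid: Sequence[int] = tuple(range(1, 11)),
    n_folds: int = 5,
) -> tuple[list[str], KNNModel, dict]:
    """Pick the best real-run chromosome, re-select k, fit the final model.

    Ties on fitness prefer fewer descriptors, then the lexicographically
    smaller gene vector.  Returns (selected column names, fitted model,
    summary dict with the chosen k and per-k cross-validated NER).
    """
    real = result.real_runs
    if not real:
        raise GAError("no real runs to finalize from")

    def sort_key(r: GARunResult):
        return (-r.best_fitness, int(r.best_genes.sum()), tuple(r.best_genes.tolist()))

    best = min(real, key=sort_key)
    genes = best.best_genes
    selected = [c for c, g in zip(column_names, genes) if g]
    X_sel = np.asarray(raw_values, dtype=float)[:, genes]
    y = np.asarray(labels, dtype=int)
    grid = [k for k in k_grid if k <= len(y) - 1]
    best_k, ner_by_k = select_k(X_sel, y, k_grid=grid, n_folds=n_folds)
    model = fit_knn(X_sel, y, k=best_k, column_names=selected)
    summary = {
        "n_selected": len(selected),
        "selected": selected,
        "best_run_seed": best.run_seed,
        "ner_cv_ga": best.best_fitness,
        "k": best_k,
        "ner_cv_by_k": {str(k): v for k, v in ner_by_k.items()},
    }
    return selected, model, summary
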
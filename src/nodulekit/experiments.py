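"""Reproducible desk-scale experiments used by the test suite and the
acceptance script.

These run the package's own components at reduced problem sizes (documented
in docs/methods.md) and return plain dictionaries of measured quantities.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .cho import Bounds, CHOConfig, optimize
from .bilstm import BiLSTMClassifier
from .phantom import PhantomConfig, generate_samples
from .pipeline import evaluate, feature_table

__all__ = ["sphere_benchmark", "classification_experiment"]


def sphere_benchmark(n_seeds: int = 20, dim: int = 5, pop_size: int = 30,
                     t_max: int = 200, bound: float = 5.0,
                     seed_offset: int = 0) -> dict:
    """CHO vs equal-budget uniform random search on the sphere function.

    The objective is the (negated, so maximised) 5-D sphere; reports the
    per-seed final best fitnesses of both methods.
    """
    def objective(x):
        return -float(np.sum(x * x))

    bounds = Bounds.cube(-bound, bound, dim)
    cho_best, rs_best = [], []
    for s in range(n_seeds):
        config = CHOConfig(pop_size=pop_size, t_max=t_max, seed=seed_offset + s)
        result = optimize(objective, bounds, config)
        cho_best.append(result.best_fitness)
        rng = np.random.default_rng(100000 + seed_offset + s)
        X = rng.uniform(-bound, bound, (result.n_evaluations, dim))
        rs_best.append(float((-np.sum(X * X, axis=1)).max()))
    return {
        "cho_best": np.array(cho_best),
        "random_search_best": np.array(rs_best),
        "cho_median": float(np.median(cho_best)),
        "random_search_median": float(np.median(rs_best)),
    }


def classification_experiment(n_phantoms: int = 100, seed: int = 7,
                              test_fraction: float = 0.2,
                              cho_pop: int = 20, cho_iters: int = 50) -> dict:
    """Scaled-down end-to-end classification run on the phantom suite.

    Generates ``n_phantoms`` slices, builds the per-nodule descriptor table
    from the ground-truth annotations, trains the BiLSTM by CHO on a
    stratified 80% split and evaluates on the held-out 20%.  Returns the
    held-out accuracy, the majority-class baseline and the evaluation
    report.
    """
    config = PhantomConfig(seed=seed)
    samples = generate_samples(n_phantoms, config, seed=seed)
    X, y = feature_table(samples)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed,
    )
    model = BiLSTMClassifier(
        cho=CHOConfig(pop_size=cho_pop, t_max=cho_iters),
        random_state=seed,
    ).fit(X_tr, y_tr)
    pred = model.predict(X_te)
    report = evaluate(pred, y_te)
    counts = np.unique(y_te, return_counts=True)[1]
    baseline = float(counts.max() / counts.sum())
    return {
        "model": model,
        "report": report,
        "test_accuracy": report.accuracy,
        "majority_baseline": baseline,
        "train_best_fitness": model.best_fitness_,
        "history": model.history_,
        "n_train": len(y_tr),
        "n_test": len(y_te),
    }
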
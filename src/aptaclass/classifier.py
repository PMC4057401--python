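"""RBF-kernel soft-margin SVM with genetic-algorithm hyperparameter search.

The binary problem separates "low affinity" (label 1, round 1) from "high
affinity" (label 2, round 10) aptamers in descriptor space.  Training
solves the usual soft-margin dual with the Gaussian kernel
K(x, z) = exp(−γ‖x−z‖²) (delegated to libsvm via scikit-learn); the model
object stores support vectors, dual coefficients α_i·y_i, bias, the
per-feature [0, 1] scaling fitted on the training set, and (C, γ).

(C, γ) are tuned by a small real-coded genetic algorithm (tournament
selection, blend crossover, Gaussian mutation, elitism) with stratified
5-fold cross-validation accuracy as fitness, both parameters constrained to
[1, 1000].  A fixed (C, γ) preset is provided so the deterministic stages
can run without the stochastic search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: default (C, γ) operating point for the deterministic pipeline path
PRESET_C = 705.933
PRESET_GAMMA = 749.802


class ClassifierError(ValueError):
    pass


@dataclass
class SVMModel:
    """Trained RBF-SVM: everything needed to reproduce its decisions."""

    support_vectors: np.ndarray  # in scaled feature space
    dual_coef: np.ndarray  # α_i · y_i per support vector
    bias: float
    C: float
    gamma: float
    scale_min: np.ndarray
    scale_range: np.ndarray
    training_accuracy: float = float("nan")

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        rng = np.where(self.scale_range > 0, self.scale_range, 1.0)
        return (X - self.scale_min) / rng

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ClassifierError(
                f"feature dimension {X.shape[1]} != training dimension "
                f"{self.support_vectors.shape[1]}"
            )
        Xs = self.transform(X)
        d2 = ((Xs[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.bias

    def save(self, path: str | Path) -> None:
        payload = {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "C": self.C,
            "gamma": self.gamma,
            "scale_min": self.scale_min.tolist(),
            "scale_range": self.scale_range.tolist(),
            "training_accuracy": self.training_accuracy,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SVMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            scale_min=np.array(d["scale_min"], dtype=float),
            scale_range=np.array(d["scale_range"], dtype=float),
            training_accuracy=float(d["training_accuracy"]),
        )


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ClassifierError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ClassifierError("non-finite feature values")
    classes = set(np.unique(y).tolist())
    if not classes <= {1, 2}:
        raise ClassifierError(f"labels must be in {{1, 2}}, got {sorted(classes)}")
    if len(classes) < 2:
        raise ClassifierError("training requires both classes")
    return X, y.astype(int)


def train_svm(X, y, C: float, gamma: float, tol: float = 1e-6) -> SVMModel:
    """Train the RBF-SVM at fixed (C, γ); labels are {1, 2}.

    Features are min–max scaled to [0, 1] on the training set; the scaling
    is stored in the model and re-applied at prediction time.
    """
    if C <= 0 or gamma <= 0:
        raise ClassifierError("C and gamma must be positive")
    X, y = _check_Xy(X, y)
    if min(np.sum(y == 1), np.sum(y == 2)) < 2:
        raise ClassifierError("need at least 2 examples per class")
    smin = X.min(axis=0)
    srange = X.max(axis=0) - smin
    rng = np.where(srange > 0, srange, 1.0)
    Xs = (X - smin) / rng
    ypm = np.where(y == 2, 1, -1)
    svc = SVC(C=C, kernel="rbf", gamma=gamma, tol=tol, cache_size=64)
    svc.fit(Xs, ypm)
    model = SVMModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        gamma=gamma,
        scale_min=smin,
        scale_range=srange,
    )
    model.training_accuracy = float(np.mean(predict(model, X) == y))
    return model


def predict(model: SVMModel, X) -> np.ndarray:
    """Predicted labels in {1, 2}; the zero decision boundary maps to 1."""
    f = model.decision_function(X)
    return np.where(f > 0, 2, 1)


def cross_validate(X, y, C: float, gamma: float, folds: int = 5, seed: int = 0) -> float:
    """Mean held-out accuracy under seeded stratified k-fold CV."""
    if folds < 2:
        raise ClassifierError("folds must be >= 2")
    X, y = _check_Xy(X, y)

    def run(rs: int) -> float:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        accs = []
        for tr, te in skf.split(X, y):
            if len(set(y[tr])) < 2:
                raise ClassifierError("class absent from a fold")
            model = train_svm(X[tr], y[tr], C, gamma)
            accs.append(float(np.mean(predict(model, X[te]) == y[te])))
        return float(np.mean(accs))

    try:
        return run(seed)
    except ClassifierError:
        return run(seed + 1)  # reshuffle once, then let it raise


@dataclass
class GAConfig:
    """Real-coded GA settings for the (C, γ) search."""

    population_size: int = 20
    generations: int = 200
    c_bounds: tuple[float, float] = (1.0, 1000.0)
    gamma_bounds: tuple[float, float] = (1.0, 1000.0)
    cv_folds: int = 5
    seed: int = 0
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_sigma_frac: float = 0.05
    elitism: int = 1
    tournament_size: int = 2


@dataclass
class GAResult:
    C: float
    gamma: float
    cv_accuracy: float
    history: list[float] = field(default_factory=list)


def ga_optimize(X, y, config: GAConfig | None = None) -> GAResult:
    """Search (C, γ) by GA; fitness is CV accuracy.  Returns the best
    individual ever evaluated plus the per-generation best-so-far history
    (non-decreasing by elitism)."""
    config = config or GAConfig()
    X, y = _check_Xy(X, y)
    rng = np.random.default_rng(config.seed)
    lo = np.array([config.c_bounds[0], config.gamma_bounds[0]])
    hi = np.array([config.c_bounds[1], config.gamma_bounds[1]])
    span = hi - lo

    def fitness(ind: np.ndarray) -> float:
        return cross_validate(X, y, ind[0], ind[1], config.cv_folds, config.seed)

    pop = lo + rng.random((config.population_size, 2)) * span
    fits = np.array([fitness(ind) for ind in pop])
    best_idx = int(np.argmax(fits))
    best, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    history = [best_fit]

    for _ in range(config.generations):
        order = np.argsort(-fits)
        elite = [pop[i].copy() for i in order[: config.elitism]]
        children = list(elite)
        while len(children) < config.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size, config.tournament_size)
                parents.append(pop[max(contenders, key=lambda i: fits[i])].copy())
            p1, p2 = parents
            if rng.random() < config.crossover_rate:  # BLX-0.5 blend
                lo_g = np.minimum(p1, p2)
                hi_g = np.maximum(p1, p2)
                d = hi_g - lo_g
                child = rng.uniform(lo_g - 0.5 * d, hi_g + 0.5 * d)
            else:
                child = p1
            mutate = rng.random(2) < config.mutation_rate
            child = child + mutate * rng.normal(0, config.mutation_sigma_frac * span)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children)
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = pop[gen_best].copy(), float(fits[gen_best])
        history.append(best_fit)

    return GAResult(C=float(best[0]), gamma=float(best[1]), cv_accuracy=best_fit, history=history)
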
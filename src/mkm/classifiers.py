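"""Imbalance-aware classifier harnesses producing probability scores.

Three families, each with the imbalance accommodation fixed by convention:

* ``LR``  — logistic regression with observation weights inversely
  proportional to class frequency;
* ``NN``  — multilayer perceptron (default 10 hidden layers of width 20);
  class imbalance is handled by seeded random oversampling of the minority
  class, which is equivalent in expectation to a class-weighted loss;
* ``GBM`` — RUSBoost: AdaBoost-style boosting of depth-limited trees where
  the majority class is randomly undersampled to the minority count at every
  round (default 50 trees of depth 10).

The boosting loop is implemented here; the weak/base learners come from
scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ClassifierSpec", "fit_predict", "rusboost_round", "rusboost_fit_predict"]

_FAMILIES = ("LR", "NN", "GBM")


@dataclass(frozen=True)
class ClassifierSpec:
    """Family, seed and the few hyperparameters that matter.

    Recognized ``hyperparameters`` keys: LR — ``C`` (ridge strength; ``None``
    = unpenalized, the default), ``max_iter``; NN — ``hidden_layers``,
    ``width``, ``max_iter``; GBM — ``depth``, ``n_trees``.
    """

    family: str = "LR"
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")

    def get(self, key: str, default):
        return self.hyperparameters.get(key, default)


def _check_training_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")


def _standardize_pair(
    X: np.ndarray, Xt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both sets with training statistics; constant columns -> 0.

    Moment features can live on a ~1e-4 scale (probabilities over thousands
    of predictors), which stalls gradient-based solvers at their gradient
    tolerance. Standardizing inside the harness is an optimizer aid only:
    the decision function is unchanged in exact arithmetic.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z, Zt = (X - mu) / safe, (Xt - mu) / safe
    Z[:, sd == 0] = 0.0
    Zt[:, sd == 0] = 0.0
    return Z, Zt


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Per-observation weights inversely proportional to class frequency."""
    classes, counts = np.unique(y, return_counts=True)
    lookup = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([lookup[v] for v in y])


def _oversample_minority(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    keep = [np.flatnonzero(y == c) for c in classes]
    extra = [
        rng.choice(idx, size=target - len(idx), replace=True)
        for idx in keep
        if len(idx) < target
    ]
    idx = np.concatenate(keep + extra) if extra else np.concatenate(keep)
    rng.shuffle(idx)
    return X[idx], y[idx]


def fit_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    spec: ClassifierSpec | None = None,
) -> np.ndarray:
    """Fit the specified classifier and return positive-class test scores.

    Deterministic given ``spec.seed``; scores are probabilities in [0, 1].
    """
    spec = spec or ClassifierSpec()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels).astype(int).ravel()
    Xt = np.asarray(test_features, dtype=float)
    if X.shape[1] != Xt.shape[1]:
        raise ValueError("train and test feature counts differ")
    _check_training_labels(y)

    if spec.family == "LR":
        Z, Zt = _standardize_pair(X, Xt)
        C = spec.get("C", None)  # None -> unpenalized ("vanilla") LR
        model = LogisticRegression(
            C=np.inf if C is None else C,
            max_iter=spec.get("max_iter", 500),
            random_state=spec.seed,
        )
        model.fit(Z, y, sample_weight=_class_weights(y))
        return model.predict_proba(Zt)[:, 1]

    if spec.family == "NN":
        Z, Zt = _standardize_pair(X, Xt)
        rng = np.random.default_rng(spec.seed)
        Xb, yb = _oversample_minority(Z, y, rng)
        width = spec.get("width", 20)
        layers = spec.get("hidden_layers", 10)
        model = MLPClassifier(
            hidden_layer_sizes=(width,) * layers,
            max_iter=spec.get("max_iter", 300),
            early_stopping=len(yb) >= 100,
            random_state=spec.seed,
        )
        model.fit(Xb, yb)
        return model.predict_proba(Zt)[:, 1]

    return rusboost_fit_predict(
        X,
        y,
        Xt,
        n_trees=spec.get("n_trees", 50),
        depth=spec.get("depth", 10),
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# RUSBoost


def rusboost_round(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    seed: int = 0,
    depth: int = 10,
) -> tuple[DecisionTreeClassifier, np.ndarray, float]:
    """One boosting round: undersample, fit a tree, reweight.

    The majority class is randomly undersampled (without replacement) to the
    minority count; the depth-limited tree is fitted on the balanced sample
    with the current boosting weights. The weighted error on the *full*
    training set drives the AdaBoost update: beta = err / (1 - err), weights
    of correctly classified samples are multiplied by beta and renormalized.
    Returns (tree, updated weights, beta).
    """
    y = np.asarray(y).astype(int).ravel()
    _check_training_labels(y)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples")
    rng = np.random.default_rng(seed)
    picked = [
        idx if len(idx) == n_min else rng.choice(idx, size=n_min, replace=False)
        for idx in (np.flatnonzero(y == c) for c in classes)
    ]
    sample = np.concatenate(picked)

    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    tree = DecisionTreeClassifier(max_depth=depth, random_state=seed)
    tree.fit(X[sample], y[sample], sample_weight=w[sample])

    miss = tree.predict(X) != y
    err = float(w[miss].sum())
    beta = np.clip(err / max(1.0 - err, 1e-12), 1e-12, None)
    if err >= 0.5:
        # failed round: reset to uniform rather than amplify a bad learner
        new_w = np.full_like(w, 1.0 / len(w))
        return tree, new_w, 1.0
    new_w = w * np.where(miss, 1.0, beta)
    new_w /= new_w.sum()
    return tree, new_w, float(beta)


def rusboost_fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    Xt: np.ndarray,
    n_trees: int = 50,
    depth: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """RUSBoost ensemble scores: log(1/beta)-weighted average of tree probas."""
    y = np.asarray(y).astype(int).ravel()
    _check_training_labels(y)
    rng = np.random.default_rng(seed)
    w = np.full(len(y), 1.0 / len(y))
    scores = np.zeros(len(Xt))
    total = 0.0
    for t in range(n_trees):
        tree, w, beta = rusboost_round(X, y, w, seed=int(rng.integers(2**31)), depth=depth)
        stage = np.log(1.0 / beta) if beta < 1.0 else 0.0
        if n_trees == 1:
            return tree.predict_proba(Xt)[:, 1]
        if stage > 0:
            scores += stage * tree.predict_proba(Xt)[:, 1]
            total += stage
    if total == 0.0:
        return np.full(len(Xt), 0.5)
    return scores / total
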
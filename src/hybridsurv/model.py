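"""Imbalance-aware classification: SMOTE, balanced random forest, tuning.

The survivor class is a ~31 % minority, so the training stage combines two
rebalancing devices: SMOTE oversamples the minority class by interpolating
between minority rows and their nearest minority neighbours, and the forest
grows each tree on a bootstrap in which the majority class is down-sampled
to the minority count.  (After SMOTE the classes are already equal, so the
balanced bootstrap degenerates to an ordinary balanced resample; both stages
are kept so the pipeline composes the way the analysis describes.)

Hyperparameters are tuned by randomized search with stratified five-fold
cross-validation on the macro-averaged F1 score, with SMOTE applied inside
each training fold only so no synthetic sample ever derives from a
validation row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, ParameterSampler
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .metrics import confusion, class_metrics

__all__ = [
    "SmoteConfig",
    "smote",
    "ForestConfig",
    "SEARCH_DOMAINS",
    "BalancedRandomForest",
    "train_forest",
    "tune_hyperparameters",
    "ModelBundle",
]


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def smote(rows, labels, config: SmoteConfig | None = None):
    """Synthetic minority oversampling.

    Each synthetic sample interpolates a uniformly chosen minority row toward
    one of its k nearest minority neighbours (Euclidean) by lambda ~ U[0, 1].
    Originals are preserved verbatim; generation continues until the minority
    count reaches ``target_ratio`` times the majority count.

    Returns (rows, labels, parent_index) where ``parent_index`` maps each
    output row to the original row it copies or interpolates from (-1 marks
    the neighbour-side provenance being different; the primary parent is
    recorded), supporting leakage audits.
    """
    config = config or SmoteConfig()
    X = np.asarray(rows, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs >= 2 members")
    n_target = int(round(config.target_ratio * n_maj))
    n_new = n_target - n_min
    if n_new <= 0:
        return X.copy(), y.copy(), np.arange(len(y))

    min_idx = np.flatnonzero(y == minority)
    k = config.k_neighbors
    if n_min <= k:
        import warnings

        warnings.warn(f"minority class has {n_min} members; reducing k to {n_min - 1}")
        k = n_min - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X[min_idx])
    _, neigh = nn.kneighbors(X[min_idx])  # first neighbour is the row itself
    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    a = X[min_idx[base]]
    b = X[min_idx[neigh[base, pick]]]
    synthetic = a + lam[:, None] * (b - a)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    parents = np.concatenate([np.arange(len(y)), min_idx[base]])
    return X_out, y_out, parents


@dataclass
class ForestConfig:
    n_estimators: int = 200
    max_depth: int | None = None
    max_features: str | None = "sqrt"
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    balanced_bootstrap: bool = True
    seed: int = 0


#: Randomized-search domains for tuning.
SEARCH_DOMAINS = {
    "n_estimators": [100, 200, 300],
    "max_depth": [10, 20, None],
    "max_features": ["sqrt", "log2", None],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
}


class BalancedRandomForest:
    """Random forest whose per-tree bootstraps equalize the classes.

    Each tree draws, with replacement, ``n_min`` samples from every class
    (``n_min`` = minority count), then grows a CART tree on them.  Class
    probability is the average of per-tree leaf class frequencies.  Gini
    (mean-decrease-in-impurity) importances are averaged over trees and
    re-normalized to sum to one.
    """

    def __init__(self, config: ForestConfig | None = None, **kwargs):
        self.config = config or ForestConfig(**kwargs)
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 classes")
        n_min = counts.min()
        rng = np.random.default_rng(self.config.seed)
        self.trees_ = []
        class_idx = [np.flatnonzero(y == c) for c in self.classes_]
        for _ in range(self.config.n_estimators):
            if self.config.balanced_bootstrap:
                boot = np.concatenate(
                    [rng.choice(idx, size=n_min, replace=True) for idx in class_idx]
                )
            else:
                boot = rng.choice(len(y), size=len(y), replace=True)
            tree = DecisionTreeClassifier(
                max_depth=self.config.max_depth,
                max_features=self.config.max_features,
                min_samples_split=self.config.min_samples_split,
                min_samples_leaf=self.config.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros((len(X), len(self.classes_)))
        for tree in self.trees_:
            proba = tree.predict_proba(X)
            # map tree classes onto forest classes (a bootstrap can miss one)
            for j, c in enumerate(tree.classes_):
                out[:, np.searchsorted(self.classes_, c)] += proba[:, j]
        return out / len(self.trees_)

    def predict(self, X, threshold: float = 0.5):
        proba = self.predict_proba(X)[:, 1]
        return (proba >= threshold).astype(int)

    @property
    def feature_importances_(self) -> np.ndarray:
        imp = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        total = imp.sum()
        return imp / total if total > 0 else imp


def train_forest(rows, labels, config: ForestConfig | None = None) -> BalancedRandomForest:
    """Fit a balanced random forest; deterministic under the config seed."""
    return BalancedRandomForest(config or ForestConfig()).fit(rows, labels)


def _macro_f1(y_true, y_pred) -> float:
    return class_metrics(confusion(y_true, y_pred)).macro_f1


def _cv_macro_f1(X, y, config: ForestConfig, n_splits: int, seed: int, smote_k: int) -> float:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        Xb, yb, _ = smote(X[tr], y[tr], SmoteConfig(k_neighbors=smote_k, seed=seed + fold))
        clf = BalancedRandomForest(
            ForestConfig(**{**asdict(config), "seed": seed + 1000 + fold})
        ).fit(Xb, yb)
        scores.append(_macro_f1(y[va], clf.predict(X[va])))
    return float(np.mean(scores))


def tune_hyperparameters(
    rows,
    labels,
    search_domains: dict | None = None,
    n_candidates: int = 50,
    seed: int = 0,
    n_splits: int = 5,
    smote_k: int = 5,
):
    """Randomized hyperparameter search with fold-wise SMOTE.

    Samples ``n_candidates`` configurations uniformly from the domains,
    scores each by stratified ``n_splits``-fold CV macro-F1 (SMOTE fitted on
    the training part of every fold only) and returns
    (best ForestConfig, CV table).  Ties go to the first candidate drawn.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    domains = search_domains or SEARCH_DOMAINS
    X = np.asarray(rows, dtype=float)
    y = np.asarray(labels)
    n_total = int(np.prod([len(v) for v in domains.values()]))
    sampler = ParameterSampler(
        domains, n_iter=min(n_candidates, n_total), random_state=seed
    )
    best_cfg, best_score = None, -np.inf
    table = []
    for params in sampler:
        cfg = ForestConfig(**params, seed=seed)
        score = _cv_macro_f1(X, y, cfg, n_splits=n_splits, seed=seed, smote_k=smote_k)
        table.append({**params, "cv_macro_f1": score})
        if score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg, table


@dataclass
class ModelBundle:
    """Fitted classifier plus the decisions that produced it."""

    forest: BalancedRandomForest
    config: ForestConfig
    threshold: float = 0.5
    cv_table: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)
    seed: int = 0

    def predict_proba(self, X):
        return self.forest.predict_proba(X)

    def predict(self, X):
        return self.forest.predict(X, threshold=self.threshold)
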